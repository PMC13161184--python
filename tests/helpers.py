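"""Independent oracles used by the metric tests.

These deliberately avoid the package's own vectorised code paths: the
ED2 oracle enumerates every joint survival state of the non-focal tips
and averages the focal tip's unique PD, which is the quantity ED2 is
the closed form of under independent extinctions.
"""

from itertools import product

import numpy as np


def _paths(tree):
    """Per tip: list of (length, other_descendant_tips) along its root
    path, terminal edge first, root edge excluded."""
    arrays = tree.edge_arrays()
    tips = arrays["tips"]
    out = {}
    for i, tip in enumerate(tips):
        edges = [(arrays["tbl"][i], frozenset())]
        for length, desc in arrays["internal_edges"]:
            if i in desc:
                others = frozenset(tips[j] for j in desc if j != i)
                edges.append((length, others))
        out[tip] = edges
    return out


def ed2_enumeration(tree, pext):
    """Expected unique PD per tip by exhaustive survival enumeration."""
    tips = tree.edge_arrays()["tips"]
    paths = _paths(tree)
    expected = {}
    for tip in tips:
        others = [t for t in tips if t != tip]
        total = 0.0
        for state in product([0, 1], repeat=len(others)):
            extinct = {t for t, s in zip(others, state) if s}
            prob = 1.0
            for t, s in zip(others, state):
                prob *= pext[t] if s else 1.0 - pext[t]
            unique = sum(
                length
                for length, other_desc in paths[tip]
                if other_desc <= extinct
            )
            total += prob * unique
        expected[tip] = total
    return expected


def ols_closed_form(x, y):
    """Hand OLS: slope, intercept, r^2 from the normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    syy = ((y - y.mean()) ** 2).sum()
    slope = sxy / sxx
    return slope, y.mean() - slope * x.mean(), sxy**2 / (sxx * syy)
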