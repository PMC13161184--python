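"""Phylogenetic diversity, evolutionary distinctiveness and EDGE2.

Core quantities, all in units of the tree's branch lengths (Myr here):

* **PD** — total phylogenetic diversity, the sum of all non-root branch
  lengths.
* **ED** (fair proportion) — each branch is divided equally among its
  descendant tips; a tip's ED is the sum of its shares.  ED sums to PD
  across tips, which every computation here is tested against.  An
  equal-splits variant is available behind a flag.
* **ED2** — a tip's *expected unique* PD under independent extinction of
  all other tips: its terminal branch, plus each ancestral branch
  weighted by the probability that every other tip descending from that
  branch goes extinct,

  ``ED2_i = TBL_i + sum_j L_j * prod_{k in desc(j) \\ {i}} p_k``.

  The focal tip's own extinction probability never enters its own ED2.
* **EDGE2** — ``ED2_i * GE2_i``, where GE2_i is an extinction
  probability drawn from the taxon's Red List category pool
  (:mod:`orchidedge.risk`).  Uncertainty is carried by joint resampling:
  each draw assigns every tip a fresh GE2 value, recomputes ED2 for all
  tips under that joint assignment, and multiplies; taxa are summarised
  by the median and interquartile range of their draws and ranked by
  descending EDGE2 median.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegeneratePredictorError,
    InsufficientDataError,
    ValidationError,
)
from .io import AssessmentTable, Phylogeny
from .risk import RiskModel, _sample_category

__all__ = [
    "THREAT_WEIGHTS",
    "total_pd",
    "fair_proportion_ed",
    "equal_splits_ed",
    "ed2_scores",
    "edge2_pipeline",
    "ed_threat_regression",
    "rank_top_n",
    "edge2_histogram",
    "Edge2Result",
    "RegressionResult",
]

#: Ordinal threat weights used by the ED-threat regression.  Categories
#: outside this map (RE/EW/DD/NE/NA) are excluded from the regression.
THREAT_WEIGHTS: Mapping[str, int] = {"LC": 0, "NT": 1, "VU": 2, "EN": 3, "CR": 4}


def total_pd(tree: Phylogeny) -> float:
    """Total phylogenetic diversity: sum of non-root branch lengths."""
    arrays = tree.edge_arrays()
    return float(
        arrays["tbl"].sum() + sum(length for length, _ in arrays["internal_edges"])
    )


def fair_proportion_ed(tree: Phylogeny) -> pd.Series:
    """Fair-proportion evolutionary distinctiveness per tip.

    Each non-root branch contributes ``length / n_descendant_tips`` to
    every tip below it; the per-tip sums add up to PD exactly.
    """
    arrays = tree.edge_arrays()
    ed = arrays["tbl"].copy()
    for length, desc in arrays["internal_edges"]:
        ed[desc] += length / desc.size
    return pd.Series(ed, index=arrays["tips"], name="ED")


def equal_splits_ed(tree: Phylogeny) -> pd.Series:
    """Equal-splits distinctiveness: value halves (or splits k ways) at
    every divergence on the way down instead of by tip count."""
    root = tree.dendropy_tree.seed_node
    values: dict[str, float] = {}

    def walk(node, inherited: float) -> None:
        children = node.child_nodes()
        if not children:
            from .io import normalize_label

            raw = node.taxon.label if node.taxon is not None else node.label
            values[normalize_label(raw)] = inherited
            return
        for child in children:
            walk(child, inherited / len(children) + float(child.edge.length))

    walk(root, 0.0)
    tips = tree.tip_labels
    return pd.Series([values[t] for t in tips], index=tips, name="ED_equal_splits")


def ed2_scores(tree: Phylogeny, pext: Mapping[str, float]) -> pd.Series:
    """Expected-unique-PD distinctiveness under a fixed extinction map.

    ``pext`` maps every tip label to an extinction probability in
    (0, 1].  Leave-one-out products are formed by prefix/suffix
    multiplication, so tips with vanishing probabilities stay exact.
    """
    arrays = tree.edge_arrays()
    tips = arrays["tips"]
    missing = [t for t in tips if t not in pext]
    if missing:
        raise ValidationError(f"pext is missing tips: {missing}")
    p = np.array([float(pext[t]) for t in tips])
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("extinction probabilities must lie in (0, 1]")
    ed2 = arrays["tbl"].copy()
    for length, desc in arrays["internal_edges"]:
        sub = p[desc]
        # leave-one-out product via prefix/suffix cumulative products
        prefix = np.ones(sub.size)
        prefix[1:] = np.cumprod(sub[:-1])
        suffix = np.ones(sub.size)
        suffix[:-1] = np.cumprod(sub[::-1])[-2::-1]
        ed2[desc] += length * prefix * suffix
    return pd.Series(ed2, index=tips, name="ED2")


# ---------------------------------------------------------------------------
# EDGE2 resampling pipeline
# ---------------------------------------------------------------------------


@dataclass
class Edge2Result:
    """Per-taxon ED2/EDGE2 draw distributions and their summaries.

    ``ed2_draws`` and ``edge2_draws`` have one row per resampling draw
    and one column per taxon (in ``taxa`` order).  ``summary`` holds
    medians, IQRs (Q3 - Q1, linear interpolation) and the dense rank by
    descending EDGE2 median.
    """

    taxa: list[str]
    categories: list[str]
    ed2_draws: np.ndarray
    edge2_draws: np.ndarray
    summary: pd.DataFrame


def edge2_pipeline(
    tree: Phylogeny,
    assessments: AssessmentTable,
    scope: str = "hk",
    model: RiskModel | None = None,
    n_draws: int = 500,
    seed: int | np.random.Generator | None = None,
) -> Edge2Result:
    """Joint GE2 resampling of ED2 and EDGE2 for every tip.

    For each of ``n_draws`` iterations every tip receives a GE2 value
    sampled from its Red List category's pool; ED2 is recomputed for
    all tips under that joint assignment (a tip's own GE2 does not
    enter its own ED2) and EDGE2_i = ED2_i x GE2_i.
    """
    if n_draws < 1:
        raise ValidationError(f"n_draws must be >= 1, got {n_draws}")
    if model is None:
        model = _default_model(seed)
    arrays = tree.edge_arrays()
    tips = arrays["tips"]
    missing = [t for t in tips if t not in assessments.df.index]
    if missing:
        raise ValidationError(
            f"tips absent from the assessment table: {missing}"
        )
    categories = [assessments.category(t, scope) for t in tips]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n = len(tips)
    ge2 = np.empty((n_draws, n))
    for j, cat in enumerate(categories):
        ge2[:, j] = _sample_category(model, cat, n_draws, rng)

    tbl = arrays["tbl"]
    ed2 = np.broadcast_to(tbl, (n_draws, n)).copy()
    for length, desc in arrays["internal_edges"]:
        sub = ge2[:, desc]
        prod_all = sub.prod(axis=1)
        # pool values are bounded away from zero, so division is safe
        ed2[:, desc] += length * prod_all[:, None] / sub
    edge2 = ed2 * ge2

    summary = _summarise(tips, categories, ed2, edge2)
    return Edge2Result(
        taxa=list(tips),
        categories=categories,
        ed2_draws=ed2,
        edge2_draws=edge2,
        summary=summary,
    )


def _default_model(seed) -> RiskModel:
    from .risk import build_risk_model

    base = seed if isinstance(seed, (int, np.integer)) else None
    return build_risk_model(seed=None if base is None else int(base) ^ 0x5EED)


def _summarise(tips, categories, ed2, edge2) -> pd.DataFrame:
    q1e, mede, q3e = np.percentile(edge2, [25, 50, 75], axis=0)
    q1d, medd, q3d = np.percentile(ed2, [25, 50, 75], axis=0)
    frame = pd.DataFrame(
        {
            "taxon": tips,
            "category": categories,
            "ed2_median": medd,
            "ed2_iqr": q3d - q1d,
            "edge2_median": mede,
            "edge2_iqr": q3e - q1e,
        }
    )
    frame["rank"] = (
        frame["edge2_median"].rank(method="dense", ascending=False).astype(int)
    )
    return frame


def rank_top_n(result: Edge2Result, n: int = 50) -> pd.DataFrame:
    """Top-``n`` priority table, descending by EDGE2 median.

    Ties break by ED2 median (descending), then by taxon label.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    frame = result.summary.sort_values(
        by=["edge2_median", "ed2_median", "taxon"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return frame.head(n)


def edge2_histogram(result: Edge2Result, bins: int = 20) -> pd.DataFrame:
    """Bin counts of the EDGE2 medians (the score-distribution figure
    as a table)."""
    counts, edges = np.histogram(result.summary["edge2_median"].values, bins=bins)
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )


# ---------------------------------------------------------------------------
# ED-threat regression
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    adj_r2: float
    pvalue: float
    n: int


def ed_threat_regression(
    ed: pd.Series | Mapping[str, float],
    assessments: AssessmentTable,
    scope: str = "hk",
    weights: Mapping[str, int] = THREAT_WEIGHTS,
) -> RegressionResult:
    """OLS of ED (response) on the ordinal threat weight (predictor).

    Taxa whose category at the chosen scope is outside the weight map
    (RE, EW, DD, NE, NA) are excluded.  Returns both plain and adjusted
    r-squared; the adjusted value can be negative for weak fits.
    """
    ed = pd.Series(ed, dtype=float)
    xs, ys = [], []
    for taxon, value in ed.items():
        if taxon not in assessments.df.index:
            continue
        cat = assessments.category(taxon, scope)
        if cat in weights:
            xs.append(float(weights[cat]))
            ys.append(float(value))
    n = len(xs)
    if n < 3:
        raise InsufficientDataError(
            f"regression needs >= 3 taxa with weighted categories, got {n}"
        )
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0:
        raise DegeneratePredictorError("threat weights have zero variance")
    if np.ptp(y) == 0:
        # flat response: zero slope, no variance explained
        return RegressionResult(
            slope=0.0, intercept=float(y[0]), r2=0.0,
            adj_r2=1.0 - (n - 1) / (n - 2), pvalue=1.0, n=n,
        )
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=r2,
        adj_r2=float(adj),
        pvalue=float(fit.pvalue),
        n=n,
    )
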