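"""Published summary tallies of the Hong Kong orchid flora, as inputs.

The regional study tabulates 138 native orchid taxa.  The counts below
are the printed marginal tallies; :func:`regional_tally_table` expands
them into a deterministic per-taxon :class:`~orchidedge.io.AssessmentTable`
whose joint layout respects every published cross-tabulation used here:

* Hong Kong scope: CR 35, EN 17, VU 24, NT 8, LC 30, DD 4, RE 17
  (135 assessed of 138; 76 threatened);
* China scope: CR 5, EN 16, VU 22, NT 13, LC 70, DD 4 (130 assessed;
  43 threatened);
* habitat specificity: 91 specialists (55 threatened, 17 RE) vs 47
  generalists (21 threatened, none RE);
* mating system: 61 outcrossing (41 threatened, 7 RE), 10 selfing
  (5 threatened), 67 unknown;
* trade: 41 ornamental only, 2 medicinal only, 7 both, 88 untraded;
* habit: 54 epiphytic/lithophytic, 84 terrestrial.

Only the marginal and cross counts above are meaningful; the pairing of
counts onto individual synthetic rows is an arbitrary but fixed layout
(taxon labels are synthetic placeholders, not real species).

Published per-marker diversity means (used to check the decomposition
identity) are in :data:`MARKER_DIVERSITY_MEANS`.
"""

from __future__ import annotations

import pandas as pd

from .io import AssessmentTable

__all__ = [
    "HK_TALLIES",
    "CN_TALLIES",
    "MARKER_DIVERSITY_MEANS",
    "regional_tally_table",
]

#: Hong Kong Red List tallies (135 assessed + 3 unassessed = 138 taxa).
HK_TALLIES = {
    "CR": 35, "EN": 17, "VU": 24, "NT": 8, "LC": 30, "DD": 4, "RE": 17, "NA": 3,
}

#: China Red List tallies (130 assessed + 8 unassessed = 138 taxa).
CN_TALLIES = {
    "CR": 5, "EN": 16, "VU": 22, "NT": 13, "LC": 70, "DD": 4, "NA": 8,
}

#: Printed rounded mean diversities per marker:
#: (overall pi_total, within-species pi_within, between delta,
#: coefficient of differentiation).
MARKER_DIVERSITY_MEANS = {
    "5.8S": (0.0877, 0.0019, 0.0859, 0.9789),
    "matK": (0.0765, 0.0034, 0.0731, 0.9558),
    "trnL-F": (0.1297, 0.0070, 0.1228, 0.9462),
    "trnH-psbA": (0.0480, 0.0038, 0.0442, 0.9205),
}

_THREATENED = ("CR", "EN", "VU")


def regional_tally_table() -> AssessmentTable:
    """Expand the printed tallies into a 138-row assessment table."""
    # Hong Kong categories in a fixed block order: threatened first,
    # then RE, then the rest, so trait blocks can be laid over them.
    hk: list[str] = []
    for cat in ("CR", "EN", "VU"):
        hk += [cat] * HK_TALLIES[cat]
    hk += ["RE"] * HK_TALLIES["RE"]
    for cat in ("NT", "LC", "DD", "NA"):
        hk += [cat] * HK_TALLIES[cat]
    n = len(hk)  # 138

    cn: list[str] = []
    for cat in ("CR", "EN", "VU", "NT", "LC", "DD", "NA"):
        cn += [cat] * CN_TALLIES[cat]

    threatened_idx = list(range(76))
    re_idx = list(range(76, 93))
    other_idx = list(range(93, n))

    # specialists: 55 threatened + all 17 RE + 19 others = 91
    specialist = [False] * n
    for i in threatened_idx[:55] + re_idx + other_idx[:19]:
        specialist[i] = True

    # mating: outcrossing = 41 threatened + 7 RE + 13 others,
    # selfing = 5 threatened + 5 others, the remaining 67 unknown
    mating = [""] * n
    for i in threatened_idx[:41] + re_idx[:7] + other_idx[:13]:
        mating[i] = "2"
    for i in threatened_idx[41:46] + other_idx[13:18]:
        mating[i] = "1"

    # trade: 41 ornamental-only, 2 medicinal-only, 7 both, 88 untraded
    trade = [0] * n
    for i in range(41):
        trade[i] = 1
    for i in range(41, 43):
        trade[i] = 2
    for i in range(43, 50):
        trade[i] = 3

    # habit: 54 epiphytic/lithophytic (1), 84 terrestrial (2)
    habit = ["1"] * 54 + ["2"] * (n - 54)

    habitats = [
        "lowland_forest" if spec else "lowland_forest;montane_forest"
        for spec in specialist
    ]
    frame = pd.DataFrame(
        {
            "category_hk": hk,
            "category_cn": cn,
            "habit": [float(h) for h in habit],
            "habitats": [frozenset(h.split(";")) for h in habitats],
            "mating": [float(m) if m else float("nan") for m in mating],
            "trade": trade,
        },
        index=pd.Index([f"taxon{i + 1:03d}" for i in range(n)], name="taxon"),
    )
    return AssessmentTable(frame)
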