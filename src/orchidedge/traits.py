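"""Red List tabulations and trait-threat rank correlations.

Threat ordinals: LC=1, NT=2, VU=3, EN=4, CR=5, RE=6; DD/NE/NA are
excluded from ordinal analyses.  "Threatened" means VU, EN or CR.
Trait codes follow the regional convention:

* habit: epiphyte/lithophyte = 1, terrestrial = 2;
* habitat specificity: generalist (>= 2 habitat types) = 1,
  specialist (exactly 1 type) = 2;
* mating system: selfing = 1, outcrossing = 2;
* occurrence in trade: untraded = 0, ornamental = 1, medicinal = 2,
  both = 3.

Spearman's rank correlation is tie-corrected (Pearson on mid-ranks);
p-values come from the t approximation by default or from a seeded
permutation test.  |r_s| is labelled very weak (< 0.2), weak (< 0.4),
moderate (< 0.6) or strong (>= 0.6).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegeneratePredictorError,
    InsufficientDataError,
    ValidationError,
)
from .io import AssessmentTable

__all__ = [
    "THREAT_ORDINALS",
    "THREATENED",
    "CorrelationResult",
    "classify_habitat_specificity",
    "tabulate_red_list",
    "tabulate_trade",
    "trait_group_threat_rates",
    "spearman_correlation",
    "trait_threat_correlations",
    "strength_label",
    "round_half_away",
]

#: Ordinal coding of Red List categories for rank analyses.
THREAT_ORDINALS: Mapping[str, int] = {
    "LC": 1, "NT": 2, "VU": 3, "EN": 4, "CR": 5, "RE": 6,
}

#: Categories counted as threatened.
THREATENED = frozenset({"VU", "EN", "CR"})

#: Categories excluded from "assessed" totals.
_NOT_ASSESSED = frozenset({"NE", "NA"})


def round_half_away(value: float) -> int:
    """Integer percentage rounding, halves away from zero (55/91 -> 60%)."""
    return int(np.floor(value + 0.5)) if value >= 0 else -int(np.floor(-value + 0.5))


def strength_label(rs: float) -> str:
    a = abs(rs)
    if a < 0.2:
        return "very weak"
    if a < 0.4:
        return "weak"
    if a < 0.6:
        return "moderate"
    return "strong"


def classify_habitat_specificity(habitats: Iterable[str]) -> int:
    """1 = generalist (two or more habitat types), 2 = specialist (one)."""
    members = {h for h in habitats if h}
    if not members:
        raise ValidationError("habitat membership must be non-empty")
    return 1 if len(members) >= 2 else 2


# ---------------------------------------------------------------------------
# Tabulations
# ---------------------------------------------------------------------------


def tabulate_red_list(table: AssessmentTable, scope: str = "hk") -> dict:
    """Category counts, threatened count and integer percent at a scope.

    "Assessed" excludes NE/NA but includes DD and RE.
    """
    cats = table.categories(scope)
    counts = {c: int((cats == c).sum()) for c in THREAT_ORDINALS}
    for extra in ("EW", "DD", "NE", "NA"):
        counts[extra] = int((cats == extra).sum())
    assessed = int((~cats.isin(_NOT_ASSESSED)).sum())
    threatened = sum(counts[c] for c in THREATENED)
    percent = (
        round_half_away(100.0 * threatened / assessed) if assessed else None
    )
    return {
        "scope": scope,
        "counts": counts,
        "assessed": assessed,
        "threatened": threatened,
        "threatened_percent": percent,
    }


def tabulate_trade(table: AssessmentTable) -> dict:
    """Trade exposure by inclusion-exclusion over the 0-3 codes."""
    codes = table.df["trade"]
    bad = set(codes) - {0, 1, 2, 3}
    if bad:
        raise ValidationError(f"invalid trade codes: {sorted(bad)}")
    ornamental = int(codes.isin([1, 3]).sum())
    medicinal = int(codes.isin([2, 3]).sum())
    both = int((codes == 3).sum())
    return {
        "ornamental": ornamental,
        "medicinal": medicinal,
        "both": both,
        "traded_total": ornamental + medicinal - both,
    }


def trait_group_threat_rates(
    table: AssessmentTable,
    scope: str = "hk",
    trait: str = "habitat_specificity",
    grouping: Mapping[object, str] | None = None,
) -> pd.DataFrame:
    """Threatened fraction and regionally-extinct count per trait level.

    ``trait`` is one of ``habit``, ``habitat_specificity``, ``mating``
    or ``trade``; ``grouping`` optionally renames levels.  Taxa with a
    missing trait value are dropped.
    """
    codes = _trait_codes(table, trait)
    cats = table.categories(scope)
    rows = []
    for level in sorted({c for c in codes if not pd.isna(c)}):
        mask = codes == level
        sub = cats[mask]
        n = int(mask.sum())
        threatened = int(sub.isin(THREATENED).sum())
        rows.append(
            {
                "trait": trait,
                "level": grouping.get(level, level) if grouping else level,
                "n": n,
                "threatened": threatened,
                "threatened_percent": round_half_away(100.0 * threatened / n),
                "regionally_extinct": int((sub == "RE").sum()),
            }
        )
    return pd.DataFrame(rows)


def _trait_codes(table: AssessmentTable, trait: str) -> pd.Series:
    if trait == "habitat_specificity":
        values = []
        for habitats in table.df["habitats"]:
            values.append(
                classify_habitat_specificity(habitats) if habitats else np.nan
            )
        return pd.Series(values, index=table.df.index, dtype=float)
    if trait in ("habit", "mating", "trade"):
        return table.df[trait].astype(float)
    raise ValidationError(
        f"unknown trait '{trait}'; expected habit, habitat_specificity, "
        "mating or trade"
    )


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    trait: str
    n: int
    rs: float
    pvalue: float
    method: str
    strength: str


def spearman_correlation(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "t",
    n_permutations: int = 10_000,
    seed: int | np.random.Generator | None = None,
    trait: str = "",
) -> CorrelationResult:
    """Tie-corrected Spearman rank correlation of two ordinal vectors.

    ``method='t'`` uses the t approximation; ``method='permutation'``
    permutes ``y`` (seeded, two-sided on |r_s|).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise InsufficientDataError(
            f"Spearman correlation needs >= 3 complete pairs, got {n}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegeneratePredictorError(
            "correlation undefined: a vector has zero variance"
        )
    rs, p_t = stats.spearmanr(x, y)
    rs = float(rs)
    if method == "t":
        p = float(p_t)
    elif method == "permutation":
        if n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        rng = (
            np.random.default_rng(seed)
            if not isinstance(seed, np.random.Generator)
            else seed
        )
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        hits = 0
        target = abs(rs)
        for _ in range(n_permutations):
            perm = rng.permutation(ry)
            r = np.corrcoef(rx, perm)[0, 1]
            if abs(r) >= target - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + n_permutations)
    else:
        raise ValidationError(f"unknown p-value method '{method}'")
    return CorrelationResult(
        trait=trait, n=n, rs=rs, pvalue=p, method=method,
        strength=strength_label(rs),
    )


def trait_threat_correlations(
    table: AssessmentTable,
    scope: str = "hk",
    method: str = "t",
    n_permutations: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Spearman correlation of each of the four traits with threat.

    Threat uses the LC..RE ordinals; DD/NE/NA taxa and taxa missing a
    trait value are excluded pairwise, so each trait may use a
    different n.
    """
    cats = table.categories(scope)
    threat = cats.map(THREAT_ORDINALS).astype(float)
    rows = []
    rng = (
        np.random.default_rng(seed)
        if not isinstance(seed, np.random.Generator)
        else seed
    )
    for trait in ("habit", "habitat_specificity", "mating", "trade"):
        codes = _trait_codes(table, trait)
        try:
            result = spearman_correlation(
                threat.values, codes.values, method=method,
                n_permutations=n_permutations, seed=rng, trait=trait,
            )
            row = {
                "trait": trait, "scope": scope, "n": result.n,
                "rs": result.rs, "p": result.pvalue,
                "method": result.method, "strength": result.strength,
            }
        except (DegeneratePredictorError, InsufficientDataError):
            # e.g. a constant trait column in a small table: report the
            # trait as undefined instead of failing the whole batch
            row = {
                "trait": trait, "scope": scope,
                "n": int((np.isfinite(threat.values) & np.isfinite(codes.values.astype(float))).sum()),
                "rs": np.nan, "p": np.nan, "method": method,
                "strength": "undefined",
            }
        rows.append(row)
    return pd.DataFrame(rows)
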