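"""Extinction-probability (GE2) distributions per Red List category.

Each Red List threat category is given a pool of 50-year extinction
probabilities whose empirical median is pinned *exactly* to the
category's expected risk and whose support is the category's interval:

========  ========  =======================
category  median    support
========  ========  =======================
CR        0.97      (0.69436, 0.99999)
EN        0.485     (0.33861, 0.69435)
VU        0.2425    (0.17085, 0.33861)
NT        0.12125   (0.09337, 0.17085)
LC        0.060625  (0.00174, 0.09337)
========  ========  =======================

The medians form a halving sequence (each category carries half the
risk of the next more threatened one).  Regionally extinct (RE) and
extinct-in-the-wild (EW) taxa are treated as CR; data-deficient,
not-evaluated and unassessed taxa (DD/NE/NA) draw from the pooled
distribution across all five categories, spanning (0.00174, 0.99999).

A pool of odd size ``m`` is built as one copy of the median itself plus
``(m-1)/2`` uniform draws on each side, which pins the middle order
statistic to the expected value with zero tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "EXPECTED_MEDIANS",
    "CATEGORY_INTERVALS",
    "THREAT_CATEGORIES",
    "POOLED_RANGE",
    "category_interval",
    "build_risk_pool",
    "build_risk_model",
    "draw_ge2",
    "RiskModel",
    "Ge2Draws",
]

#: Expected 50-year extinction probability (pool median) per category.
EXPECTED_MEDIANS: Mapping[str, float] = {
    "CR": 0.97,
    "EN": 0.485,
    "VU": 0.2425,
    "NT": 0.12125,
    "LC": 0.060625,
}

#: Support interval of each category's probability pool.
CATEGORY_INTERVALS: Mapping[str, tuple[float, float]] = {
    "CR": (0.69436, 0.99999),
    "EN": (0.33861, 0.69435),
    "VU": (0.17085, 0.33861),
    "NT": (0.09337, 0.17085),
    "LC": (0.00174, 0.09337),
}

#: The five categories with their own pools, most to least threatened.
THREAT_CATEGORIES = ("CR", "EN", "VU", "NT", "LC")

#: Range spanned by the pooled all-category distribution (DD/NE/NA).
POOLED_RANGE = (0.00174, 0.99999)

_AS_CR = {"RE", "EW"}
_POOLED = {"DD", "NE", "NA"}


def category_interval(category: str) -> tuple[float, float]:
    """Support interval for a category's extinction probability.

    RE and EW map to the CR interval; DD, NE and NA span the full
    pooled range.
    """
    category = category.upper()
    if category in CATEGORY_INTERVALS:
        return CATEGORY_INTERVALS[category]
    if category in _AS_CR:
        return CATEGORY_INTERVALS["CR"]
    if category in _POOLED:
        return POOLED_RANGE
    raise ValidationError(f"unknown Red List category '{category}'")


def build_risk_pool(
    category: str,
    pool_size: int = 10001,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Build one category's probability pool with a pinned median.

    The pool holds exactly one copy of the expected median ``m``,
    ``(pool_size-1)/2`` uniform draws on ``(lower, m)`` and the same
    number on ``(m, upper)``, so its empirical median equals ``m``
    exactly for any odd ``pool_size >= 3``.
    """
    category = category.upper()
    if category in _AS_CR:
        category = "CR"
    if category not in EXPECTED_MEDIANS:
        raise ValidationError(
            f"no dedicated risk pool for category '{category}'"
        )
    if pool_size < 3 or pool_size % 2 == 0:
        raise ValidationError(
            f"pool_size must be odd and >= 3, got {pool_size}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    median = EXPECTED_MEDIANS[category]
    lower, upper = CATEGORY_INTERVALS[category]
    half = (pool_size - 1) // 2
    below = rng.uniform(lower, median, size=half)
    above = rng.uniform(median, upper, size=half)
    return np.concatenate([below, [median], above])


@dataclass
class RiskModel:
    """Per-category extinction-probability pools plus the pooled mix.

    ``pooled`` is the concatenation of the five category pools in
    CR..LC order and is what DD/NE/NA taxa sample from by default;
    ``dd_mode='uniform'`` switches them to a uniform law on the pooled
    range instead.
    """

    pools: dict[str, np.ndarray]
    dd_mode: str = "pooled"
    pooled: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.dd_mode not in ("pooled", "uniform"):
            raise ValidationError(f"dd_mode must be 'pooled' or 'uniform', got {self.dd_mode!r}")
        for cat in THREAT_CATEGORIES:
            if cat not in self.pools:
                raise ValidationError(f"risk model is missing the {cat} pool")
            pool = np.asarray(self.pools[cat], dtype=float)
            lower, upper = CATEGORY_INTERVALS[cat]
            if pool.min() < lower or pool.max() > upper:
                raise ValidationError(f"{cat} pool leaves its interval ({lower}, {upper})")
            if float(np.median(pool)) != EXPECTED_MEDIANS[cat]:
                raise ValidationError(
                    f"{cat} pool median {np.median(pool)} != expected {EXPECTED_MEDIANS[cat]}"
                )
            self.pools[cat] = pool
        self.pooled = np.concatenate([self.pools[c] for c in THREAT_CATEGORIES])

    # -- persistence -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"category": cat, "value": v}
            for cat in THREAT_CATEGORIES
            for v in self.pools[cat]
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, dd_mode: str = "pooled") -> "RiskModel":
        pools = {
            cat: grp["value"].to_numpy(dtype=float)
            for cat, grp in frame.groupby("category")
        }
        return cls(pools=pools, dd_mode=dd_mode)

    @classmethod
    def from_csv(cls, path: str | Path, dd_mode: str = "pooled") -> "RiskModel":
        return cls.from_frame(pd.read_csv(path), dd_mode=dd_mode)


def build_risk_model(
    pool_size_per_category: int | Mapping[str, int] = 10001,
    seed: int | np.random.Generator | None = None,
    dd_mode: str = "pooled",
) -> RiskModel:
    """Build all five category pools under one seed."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pools = {}
    for cat in THREAT_CATEGORIES:
        size = (
            pool_size_per_category[cat]
            if isinstance(pool_size_per_category, Mapping)
            else pool_size_per_category
        )
        pools[cat] = build_risk_pool(cat, size, rng)
    return RiskModel(pools=pools, dd_mode=dd_mode)


@dataclass
class Ge2Draws:
    """Resampled extinction probabilities for one taxon."""

    taxon: str
    category: str
    draws: np.ndarray

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if np.any((self.draws <= 0) | (self.draws >= 1)):
            raise ValidationError("GE2 draws must lie strictly inside (0, 1)")


def draw_ge2(
    model: RiskModel,
    category: str,
    n_draws: int = 500,
    seed: int | np.random.Generator | None = None,
    taxon: str = "",
) -> Ge2Draws:
    """Sample ``n_draws`` extinction probabilities for one taxon.

    Sampling is with replacement from the taxon's category pool; RE/EW
    use the CR pool, DD/NE/NA the pooled distribution (or a uniform on
    its range under ``dd_mode='uniform'``).
    """
    if n_draws < 1:
        raise ValidationError(f"n_draws must be >= 1, got {n_draws}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    draws = _sample_category(model, category, n_draws, rng)
    return Ge2Draws(taxon=taxon, category=category.upper(), draws=draws)


def _sample_category(
    model: RiskModel, category: str, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    category = category.upper()
    if category in _AS_CR:
        category = "CR"
    if category in model.pools:
        return rng.choice(model.pools[category], size=n_draws, replace=True)
    if category in _POOLED:
        if model.dd_mode == "uniform":
            return rng.uniform(*POOLED_RANGE, size=n_draws)
        return rng.choice(model.pooled, size=n_draws, replace=True)
    raise ValidationError(f"unknown Red List category '{category}'")
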