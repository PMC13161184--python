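"""Barcode discriminatory power: K2P distances and the barcoding gap.

Pairwise Kimura two-parameter distances separate transitions (P) and
transversions (Q):

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

computed after pairwise deletion of any site carrying a gap or
ambiguity code in either sequence (the spacer markers are indel rich;
complete deletion would discard most of the matrix).  A pair is flagged
*undefined* (saturated) when a log argument is non-positive; such pairs
are excluded from all summaries and counted in a diagnostics field.

Distances partition into intraspecific (same species, which requires a
species represented by at least two accessions) and interspecific sets.
Diversity decomposes as

    pi_total   = mean over all defined pairs
    pi_within  = equal-weight mean over species of the within-species
                 mean distance
    delta_between = pi_total - pi_within
    coefficient of differentiation = 1 - pi_within / pi_total

and the barcoding gap is quantified by a one-way fixed-effects ANOVA of
the pairwise distances grouped intra vs inter.

Mean *distances* (plain averages over the intra and inter pair sets)
are reported alongside the diversity decomposition; the two within-
group summaries differ in weighting (per-pair vs per-species).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, SaturationError, ValidationError
from .io import MarkerAlignment

__all__ = [
    "DistancePairSummary",
    "MarkerDistances",
    "DiversityDecomposition",
    "k2p_distance",
    "k2p_from_counts",
    "partition_distances",
    "diversity_decomposition",
    "diversity_from_means",
    "barcoding_gap_anova",
    "bootstrap_se",
]

_BASES = b"ACGT"


@dataclass
class DistancePairSummary:
    """One accession pair: usable sites, P, Q, the K2P distance and
    whether the pair is within a species."""

    accession_a: str
    accession_b: str
    usable_sites: int
    p_transitions: float
    q_transversions: float
    distance: float  # NaN when saturated
    same_species: bool
    defined: bool


@dataclass
class DiversityDecomposition:
    pi_total: float
    pi_within: float
    delta_between: float
    coefficient: float


@dataclass
class MarkerDistances:
    """All pairwise K2P distances of one marker, partitioned."""

    marker: str
    pairs: list[DistancePairSummary]
    intra: np.ndarray
    inter: np.ndarray
    species_within_means: dict[str, float]
    n_undefined: int

    def pair_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "accession_a": [p.accession_a for p in self.pairs],
                "accession_b": [p.accession_b for p in self.pairs],
                "usable_sites": [p.usable_sites for p in self.pairs],
                "P": [p.p_transitions for p in self.pairs],
                "Q": [p.q_transversions for p in self.pairs],
                "distance": [p.distance for p in self.pairs],
                "same_species": [p.same_species for p in self.pairs],
                "defined": [p.defined for p in self.pairs],
            }
        )

    def summary(self) -> pd.DataFrame:
        """Marker summary mirroring the standard barcoding table rows."""
        rows = {
            "marker": self.marker,
            "n_pairs_defined": len(self.intra) + len(self.inter),
            "n_pairs_undefined": self.n_undefined,
            "interspecific_mean_distance": _mean_or_nan(self.inter),
            "intraspecific_mean_distance": _mean_or_nan(self.intra),
            "overall_mean_distance": _mean_or_nan(
                np.concatenate([self.intra, self.inter])
            ),
        }
        try:
            decomp = diversity_decomposition(self)
            rows.update(
                {
                    "interspecific_mean_diversity": decomp.delta_between,
                    "intraspecific_mean_diversity": decomp.pi_within,
                    "overall_mean_diversity": decomp.pi_total,
                    "coefficient_of_differentiation": decomp.coefficient,
                }
            )
        except (InsufficientDataError, ValidationError):
            pass
        return pd.DataFrame([rows])


def _mean_or_nan(values: np.ndarray) -> float:
    return float(np.mean(values)) if len(values) else float("nan")


# ---------------------------------------------------------------------------
# K2P
# ---------------------------------------------------------------------------


def k2p_from_counts(usable: int, transitions: int, transversions: int) -> float:
    """K2P distance from site counts; raises on saturation."""
    if usable < 1:
        raise ValidationError("no usable sites after pairwise deletion")
    p = transitions / usable
    q = transversions / usable
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P undefined: 1-2P-Q={w1:.4g}, 1-2Q={w2:.4g}"
        )
    return -0.5 * log(w1) - 0.25 * log(w2)


def k2p_distance(
    seq1: str | bytes | np.ndarray,
    seq2: str | bytes | np.ndarray,
    min_usable_sites: int = 1,
    accession_a: str = "a",
    accession_b: str = "b",
    same_species: bool = False,
) -> DistancePairSummary:
    """K2P distance between two aligned sequences (pairwise deletion).

    Sites with a gap or any non-ACGT symbol in either sequence are
    excluded.  Saturated pairs come back with ``defined=False`` and a
    NaN distance rather than raising, so callers can tally diagnostics.
    """
    a = _encode(seq1)
    b = _encode(seq2)
    if a.size != b.size:
        raise ValidationError(
            f"aligned sequences differ in length: {a.size} vs {b.size}"
        )
    usable, transitions, transversions = _pair_counts(a, b)
    if usable < max(1, min_usable_sites):
        raise ValidationError(
            f"only {usable} usable sites after pairwise deletion "
            f"(minimum {max(1, min_usable_sites)})"
        )
    p = transitions / usable
    q = transversions / usable
    try:
        d = k2p_from_counts(usable, transitions, transversions)
        defined = True
    except SaturationError:
        d = float("nan")
        defined = False
    return DistancePairSummary(
        accession_a=accession_a,
        accession_b=accession_b,
        usable_sites=int(usable),
        p_transitions=float(p),
        q_transversions=float(q),
        distance=d,
        same_species=same_species,
        defined=defined,
    )


def _encode(seq) -> np.ndarray:
    """Map A,C,G,T -> 0..3 and everything else (gaps, ambiguities) -> 255."""
    if isinstance(seq, np.ndarray):
        raw = seq.astype("S1").reshape(-1)
    else:
        if isinstance(seq, str):
            seq = seq.encode("ascii")
        raw = np.frombuffer(seq.upper(), dtype="S1")
    codes = np.full(raw.size, 255, dtype=np.uint8)
    for value, base in enumerate(_BASES):
        codes[raw == bytes([base])] = value
    # lower-case input arrives via strings (upper() above); array input
    # from MarkerAlignment is already upper-cased at read time
    return codes


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    valid = (a != 255) & (b != 255)
    av, bv = a[valid], b[valid]
    diff = av != bv
    # A(0)<->G(2) and C(1)<->T(3) share parity: transitions
    transitions = int(np.count_nonzero(diff & ((av & 1) == (bv & 1))))
    transversions = int(np.count_nonzero(diff)) - transitions
    return int(valid.sum()), transitions, transversions


# ---------------------------------------------------------------------------
# Partition & decomposition
# ---------------------------------------------------------------------------


def partition_distances(
    aln: MarkerAlignment, min_usable_sites: int = 1
) -> MarkerDistances:
    """All pairwise K2P distances, labelled intra- vs interspecific.

    Intraspecific statistics exist only for species represented by two
    or more accessions; with none, the intra set is empty (absent, not
    zero).  Pairs failing the usable-site minimum or saturated pairs
    are excluded from both sets and counted as undefined.
    """
    n = aln.n_accessions
    if len(set(aln.species)) < 2:
        raise ValidationError("need at least 2 species to partition distances")
    codes = np.full(aln.matrix.shape, 255, dtype=np.uint8)
    for value, base in enumerate(_BASES):
        codes[aln.matrix == bytes([base])] = value
    pairs: list[DistancePairSummary] = []
    intra, inter = [], []
    within: dict[str, list[float]] = {}
    n_undefined = 0
    for i in range(n):
        for j in range(i + 1, n):
            same = aln.species[i] == aln.species[j]
            usable, ts, tv = _pair_counts(codes[i], codes[j])
            if usable < max(1, min_usable_sites):
                n_undefined += 1
                pairs.append(
                    DistancePairSummary(
                        aln.accessions[i], aln.accessions[j], int(usable),
                        float("nan"), float("nan"), float("nan"), same, False,
                    )
                )
                continue
            try:
                d = k2p_from_counts(usable, ts, tv)
                defined = True
            except SaturationError:
                d = float("nan")
                defined = False
                n_undefined += 1
            pairs.append(
                DistancePairSummary(
                    aln.accessions[i], aln.accessions[j], int(usable),
                    ts / usable, tv / usable, d, same, defined,
                )
            )
            if not defined:
                continue
            if same:
                intra.append(d)
                within.setdefault(aln.species[i], []).append(d)
            else:
                inter.append(d)
    species_means = {sp: float(np.mean(ds)) for sp, ds in within.items()}
    return MarkerDistances(
        marker=aln.marker,
        pairs=pairs,
        intra=np.asarray(intra),
        inter=np.asarray(inter),
        species_within_means=species_means,
        n_undefined=n_undefined,
    )


def diversity_from_means(pi_total: float, pi_within: float) -> DiversityDecomposition:
    """Decomposition from pre-computed mean diversities.

    Useful for checking published summary tables where only the rounded
    means are available.
    """
    if pi_total <= 0:
        raise ValidationError("coefficient undefined: total diversity is zero")
    delta = pi_total - pi_within
    return DiversityDecomposition(
        pi_total=pi_total,
        pi_within=pi_within,
        delta_between=delta,
        coefficient=1.0 - pi_within / pi_total,
    )


def diversity_decomposition(md: MarkerDistances) -> DiversityDecomposition:
    """Within/between diversity decomposition of a marker's distances."""
    defined = np.concatenate([md.intra, md.inter])
    if defined.size == 0:
        raise InsufficientDataError("no defined pairs")
    pi_total = float(np.mean(defined))
    pi_within = (
        float(np.mean(list(md.species_within_means.values())))
        if md.species_within_means
        else 0.0
    )
    return diversity_from_means(pi_total, pi_within)


# ---------------------------------------------------------------------------
# ANOVA & bootstrap
# ---------------------------------------------------------------------------


def barcoding_gap_anova(md: MarkerDistances) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of distances, intra vs inter.

    Each pairwise distance is one observation.  Degenerate layouts are
    resolved explicitly: no between-group variation gives F=0, p=1;
    between-group variation with zero within-group variance gives
    F=inf, p=0.
    """
    intra, inter = md.intra, md.inter
    if len(intra) == 0 or len(inter) == 0:
        raise InsufficientDataError(
            "barcoding-gap ANOVA needs both intra- and interspecific pairs"
        )
    n = len(intra) + len(inter)
    if n < 3:
        raise InsufficientDataError(f"ANOVA needs >= 3 observations, got {n}")
    grand = (intra.sum() + inter.sum()) / n
    ssb = len(intra) * (intra.mean() - grand) ** 2 + len(inter) * (
        inter.mean() - grand
    ) ** 2
    ssw = ((intra - intra.mean()) ** 2).sum() + ((inter - inter.mean()) ** 2).sum()
    if ssb == 0:
        return 0.0, 1.0
    if ssw == 0:
        return float("inf"), 0.0
    f_stat = (ssb / 1.0) / (ssw / (n - 2))
    p = float(stats.f.sf(f_stat, 1, n - 2))
    return float(f_stat), p


def bootstrap_se(
    aln: MarkerAlignment,
    statistic: Callable[[MarkerAlignment], float],
    replicates: int = 500,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Site-resampling bootstrap standard error of an alignment statistic.

    Aligned columns are resampled with replacement; the statistic is
    recomputed per replicate and its standard deviation returned.
    Errors if the statistic is undefined in more than half of the
    replicates.
    """
    if replicates < 2:
        raise ValidationError(f"replicates must be >= 2, got {replicates}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    length = aln.length
    values = []
    failures = 0
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        resampled = MarkerAlignment(
            marker=aln.marker,
            accessions=aln.accessions,
            species=aln.species,
            matrix=aln.matrix[:, cols],
        )
        try:
            value = float(statistic(resampled))
        except Exception:
            value = float("nan")
        if np.isfinite(value):
            values.append(value)
        else:
            failures += 1
    if failures > replicates / 2:
        raise InsufficientDataError(
            f"statistic undefined in {failures}/{replicates} bootstrap replicates"
        )
    return float(np.std(values, ddof=1))
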