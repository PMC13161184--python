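"""Synthetic inputs with the statistical structure the analysis assumes.

The generator produces a mutually consistent bundle — a dated
ultrametric tree, a two-scope assessment/trait table and one or more
multi-accession marker alignments — emulating a regional orchid flora:

* a pure-birth (Yule) tree of 134 tips rescaled to a 110 Myr root;
* Red List category frequencies matching the regional tallies
  (CR 35, EN 17, VU 24, NT 8, LC 30, DD 4, RE 17 of 135 assessed) and
  the national tallies (CR 5, EN 16, VU 22, NT 13, LC 70, DD 4 of 130);
* four coded traits with a tunable positive rank association to the
  regional threat ordinal, generated by a Gaussian-copula threshold
  model calibrated by Monte Carlo to a target Spearman rho;
* sequences evolved along the tree under the Kimura two-parameter
  substitution process, with conspecific accessions hung on short
  terminal branchlets so intraspecific divergence sits an order of
  magnitude below interspecific divergence (a clear barcoding gap).

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError, ValidationError
from .io import (
    AssessmentTable,
    MarkerAlignment,
    Phylogeny,
    write_assessments,
    write_newick,
)

__all__ = [
    "HK_CATEGORY_FREQUENCIES",
    "CN_CATEGORY_FREQUENCIES",
    "HABITAT_TYPES",
    "SimulationConfig",
    "FixtureBundle",
    "simulate_tree",
    "simulate_categories",
    "simulate_trait",
    "simulate_traits",
    "simulate_sequences",
    "make_fixture",
]

#: Regional (Hong Kong) Red List category frequencies: tallies
#: CR 35, EN 17, VU 24, NT 8, LC 30, DD 4, RE 17 out of 135 assessed.
HK_CATEGORY_FREQUENCIES: Mapping[str, float] = {
    "CR": 35 / 135, "EN": 17 / 135, "VU": 24 / 135, "NT": 8 / 135,
    "LC": 30 / 135, "DD": 4 / 135, "RE": 17 / 135,
}

#: National (China) frequencies: CR 5, EN 16, VU 22, NT 13, LC 70,
#: DD 4 out of 130 assessed (no regional extinctions at this scope).
CN_CATEGORY_FREQUENCIES: Mapping[str, float] = {
    "CR": 5 / 130, "EN": 16 / 130, "VU": 22 / 130, "NT": 13 / 130,
    "LC": 70 / 130, "DD": 4 / 130, "RE": 0.0,
}

#: The five recognised habitat types.
HABITAT_TYPES = (
    "lowland_forest", "montane_forest", "upland_grassland",
    "shrubland", "upland_cliffs",
)

#: Trait level probabilities (ascending code order) mirroring the
#: flora-wide prevalences: 54/138 epiphytic vs 84/138 terrestrial;
#: 47/138 generalist vs 91/138 specialist; 10/71 selfing vs 61/71
#: outcrossing (with mating unknown for 67/138 taxa); trade codes
#: 88/41/2/7 of 138.
_TRAIT_LEVELS: Mapping[str, tuple[tuple[int, ...], tuple[float, ...]]] = {
    "habit": ((1, 2), (54 / 138, 84 / 138)),
    "habitat_specificity": ((1, 2), (47 / 138, 91 / 138)),
    "mating": ((1, 2), (10 / 71, 61 / 71)),
    "trade": ((0, 1, 2, 3), (88 / 138, 41 / 138, 2 / 138, 7 / 138)),
}

_MATING_MISSING_RATE = 67 / 138

#: Default target Spearman association of each trait with regional
#: threat (positively oriented weak-to-moderate values of the size the
#: regional analysis reports).
DEFAULT_RHO_TARGETS: Mapping[str, float] = {
    "habit": 0.1,
    "habitat_specificity": 0.5,
    "mating": 0.35,
    "trade": 0.12,
}


@dataclass
class SimulationConfig:
    """Everything the generators need, in one place.

    Units: ``root_age`` in Myr; ``intraspecific_divergence`` is the
    expected K2P distance between two conspecific accessions
    (substitutions/site); ``interspecific_divergence`` the expected
    distance between a random heterospecific pair; ``kappa`` the
    transition/transversion rate ratio of the substitution process.
    """

    n_taxa: int = 134
    birth_rate: float = 0.1
    root_age: float = 110.0
    hk_frequencies: Mapping[str, float] = field(
        default_factory=lambda: dict(HK_CATEGORY_FREQUENCIES)
    )
    cn_frequencies: Mapping[str, float] = field(
        default_factory=lambda: dict(CN_CATEGORY_FREQUENCIES)
    )
    rho_targets: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RHO_TARGETS)
    )
    marker_length: int = 800
    kappa: float = 3.0
    interspecific_divergence: float = 0.08
    intraspecific_divergence: float = 0.003
    accessions_per_species: int = 2
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValidationError("n_taxa must be >= 2")
        if self.root_age <= 0:
            raise ValidationError("root_age must be positive")
        if self.kappa <= 0:
            raise ValidationError("kappa must be positive")
        for name, rho in self.rho_targets.items():
            if not -1 < rho < 1:
                raise ValidationError(
                    f"rho target for {name} must lie in (-1, 1), got {rho}"
                )
        for name, freqs in (("hk", self.hk_frequencies), ("cn", self.cn_frequencies)):
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"{name} category frequencies sum to {total}, expected 1"
                )


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------


def simulate_tree(config: SimulationConfig) -> Phylogeny:
    """Ultrametric pure-birth tree rescaled so root depth = root age.

    The Yule process is stopped at the ``n_taxa``-th tip; pendant edges
    are then extended by the exponential waiting time to the next
    speciation so terminal branches are strictly positive, and all
    depths are rescaled to ``root_age``.
    """
    rng = random.Random(int(config.seed))
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=0.0,
        num_extant_tips=config.n_taxa,
        rng=rng,
    )
    extra = rng.expovariate(config.n_taxa * config.birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    tree.seed_node.edge.length = None
    depth = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    factor = config.root_age / depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    width = len(str(config.n_taxa))
    for i, leaf in enumerate(
        sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label), start=1
    ):
        leaf.taxon.label = f"sp{i:0{width}d}"
    return Phylogeny(tree)


# ---------------------------------------------------------------------------
# Categories
# ---------------------------------------------------------------------------


def simulate_categories(
    tips: Sequence[str],
    frequencies: Mapping[str, float],
    seed: int | np.random.Generator | None = None,
) -> pd.Series:
    """Multinomial Red List category assignment over the given tips."""
    total = sum(frequencies.values())
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"frequencies sum to {total}, expected 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cats = list(frequencies)
    probs = np.array([frequencies[c] for c in cats])
    draws = rng.choice(len(cats), size=len(tips), p=probs)
    return pd.Series([cats[d] for d in draws], index=list(tips), name="category")


# ---------------------------------------------------------------------------
# Traits (Gaussian-copula threshold model)
# ---------------------------------------------------------------------------


def _normal_scores(ordinals: np.ndarray) -> np.ndarray:
    """Blom-type normal scores of mid-ranks, standardised."""
    ranks = stats.rankdata(ordinals)
    scores = stats.norm.ppf((ranks - 0.375) / (ordinals.size + 0.25))
    return (scores - scores.mean()) / scores.std()


def _discretize(z: np.ndarray, levels: Sequence[int], probs: Sequence[float]) -> np.ndarray:
    cuts = stats.norm.ppf(np.cumsum(probs)[:-1])
    return np.asarray(levels, dtype=float)[np.searchsorted(cuts, z)]


class _RsEvaluator:
    """Monte-Carlo map from the latent loading ``a`` to the Spearman
    correlation of the thresholded trait with the threat ordinal.

    Common random numbers (one fixed epsilon vector) make the map
    monotone in ``a`` so bisection is well posed; the tie-corrected
    Spearman is computed in O(N) from level counts instead of a full
    rank sort, since the trait takes only a handful of levels.
    """

    def __init__(self, scores, ordinals, probs, rng, samples):
        reps = max(1, samples // scores.size)
        self.scores = np.tile(scores, reps)
        self.eps = rng.standard_normal(self.scores.size)
        self.cuts = stats.norm.ppf(np.cumsum(probs)[:-1])
        self.n_levels = len(probs)
        x_rank = stats.rankdata(np.tile(ordinals, reps))
        self.x_centered = x_rank - x_rank.mean()
        self.x_norm = float(np.sqrt((self.x_centered**2).sum()))

    def __call__(self, a: float) -> float:
        z = a * self.scores + np.sqrt(1.0 - a * a) * self.eps
        idx = np.searchsorted(self.cuts, z)
        counts = np.bincount(idx, minlength=self.n_levels)
        cum = np.concatenate([[0], np.cumsum(counts)])
        midranks = cum[:-1] + (counts + 1) / 2.0
        y_rank = midranks[idx]
        y_centered = y_rank - y_rank.mean()
        y_norm = np.sqrt((y_centered**2).sum())
        if y_norm == 0:
            return 0.0
        return float(self.x_centered @ y_centered / (self.x_norm * y_norm))


def simulate_trait(
    categories: Sequence[str],
    rho: float,
    levels: Sequence[int],
    level_probs: Sequence[float],
    seed: int | np.random.Generator | None = None,
    missing_rate: float = 0.0,
    calibration_samples: int = 200_000,
) -> np.ndarray:
    """One trait column with a target Spearman association to threat.

    A latent Gaussian ``z = a*s + sqrt(1-a^2)*eps`` (``s`` the normal
    score of the taxon's threat ordinal) is thresholded into the trait's
    code set at quantiles matching ``level_probs``.  The loading ``a``
    is calibrated by Monte Carlo (common random numbers, bisection) so
    the population Spearman correlation of the discretised trait with
    the threat ordinal hits ``rho``; an unattainable target (beyond the
    thresholded maximum) raises :class:`CalibrationError`.  Taxa with
    DD/NE/NA categories receive trait values from the marginal
    distribution (they are excluded from downstream correlations
    anyway); ``missing_rate`` knocks values out completely at random.
    """
    from .traits import THREAT_ORDINALS

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    probs = np.asarray(level_probs, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValidationError("trait level probabilities must sum to 1")
    n = len(categories)
    ordinals = np.array(
        [float(THREAT_ORDINALS.get(c, np.nan)) for c in categories]
    )
    usable = np.isfinite(ordinals)
    if usable.sum() < 3:
        raise ValidationError("need >= 3 taxa with ordinal categories")

    scores = np.zeros(n)
    scores[usable] = _normal_scores(ordinals[usable])

    a = 0.0
    if rho != 0.0:
        evaluate = _RsEvaluator(
            scores[usable], ordinals[usable], probs, rng, calibration_samples
        )
        target = abs(rho)
        # rs(a) rises with the loading but can collapse near a -> 1 when
        # few distinct score values all land in one trait level, so scan
        # a grid first and bisect only within the bracketing cell
        grid = np.linspace(0.0, 0.9999, 21)
        values = np.array([evaluate(g) for g in grid])
        imax = int(np.argmax(values))
        if target > values[imax] + 0.005:
            raise CalibrationError(
                f"target |rho|={target:.3f} exceeds the maximum "
                f"{values[imax]:.3f} attainable for this trait's coding"
            )
        crossing = np.nonzero(values[: imax + 1] >= target)[0]
        idx = int(crossing[0]) if crossing.size else imax
        if idx == 0:
            a = 0.0
        else:
            lo, hi = grid[idx - 1], grid[idx]
            for _ in range(14):
                mid = 0.5 * (lo + hi)
                if evaluate(mid) < target:
                    lo = mid
                else:
                    hi = mid
            a = 0.5 * (lo + hi)
        if rho < 0:
            a = -a

    eps_n = rng.standard_normal(n)
    z = a * scores + np.sqrt(1.0 - a * a) * eps_n
    # taxa without an ordinal category draw from the plain marginal
    z[~usable] = eps_n[~usable]
    codes = _discretize(z, levels, probs)
    if missing_rate > 0:
        codes[rng.random(n) < missing_rate] = np.nan
    return codes


def simulate_traits(
    categories: Sequence[str],
    rho_targets: Mapping[str, float] | None = None,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """All four trait columns, plus habitat membership sets.

    Habitat sets are drawn consistently with the specificity code:
    specialists get one habitat type, generalists two to five.
    """
    rho_targets = dict(DEFAULT_RHO_TARGETS if rho_targets is None else rho_targets)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    columns: dict[str, np.ndarray] = {}
    for trait, (levels, probs) in _TRAIT_LEVELS.items():
        columns[trait] = simulate_trait(
            categories,
            rho_targets.get(trait, 0.0),
            levels,
            probs,
            seed=rng,
            missing_rate=_MATING_MISSING_RATE if trait == "mating" else 0.0,
        )
    habitats = []
    types = np.array(HABITAT_TYPES)
    for code in columns["habitat_specificity"]:
        if code == 2:
            habitats.append(frozenset(rng.choice(types, size=1)))
        else:
            k = int(rng.integers(2, len(types) + 1))
            habitats.append(frozenset(rng.choice(types, size=k, replace=False)))
    frame = pd.DataFrame(
        {
            "habit": columns["habit"],
            "habitats": habitats,
            "mating": columns["mating"],
            "trade": columns["trade"].astype(int),
        },
        index=list(categories.index)
        if isinstance(categories, pd.Series)
        else list(range(len(categories))),
    )
    return frame


# ---------------------------------------------------------------------------
# Sequences (Kimura two-parameter process)
# ---------------------------------------------------------------------------


def _k2p_site_probs(d: float, kappa: float) -> tuple[float, float, float]:
    """Per-site (same, transition, each transversion) probabilities for
    an edge of expected ``d`` substitutions/site at rate ratio kappa."""
    if d <= 0:
        return 1.0, 0.0, 0.0
    alpha_t = d * kappa / (kappa + 2.0)
    beta_t = d / (kappa + 2.0)
    p_ts = 0.25 + 0.25 * np.exp(-4.0 * beta_t) - 0.5 * np.exp(-2.0 * (alpha_t + beta_t))
    q_tv = 0.5 - 0.5 * np.exp(-4.0 * beta_t)
    return 1.0 - p_ts - q_tv, p_ts, q_tv / 2.0


def _evolve(seq: np.ndarray, d: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    same, ts, tv_each = _k2p_site_probs(d, kappa)
    u = rng.random(seq.size)
    out = seq.copy()
    is_ts = u < ts
    is_tv1 = (u >= ts) & (u < ts + tv_each)
    is_tv2 = (u >= ts + tv_each) & (u < ts + 2 * tv_each)
    out[is_ts] ^= 2            # A<->G, C<->T keep parity
    out[is_tv1] = (seq[is_tv1] + 1) % 4
    out[is_tv2] = (seq[is_tv2] + 3) % 4
    return out


def _mean_pairwise_path(tree: Phylogeny) -> float:
    arrays = tree.edge_arrays()
    n = len(arrays["tips"])
    total_pairs = n * (n - 1) / 2
    weight = 0.0
    for i, length in enumerate(arrays["tbl"]):
        weight += length * (n - 1)
    for length, desc in arrays["internal_edges"]:
        weight += length * desc.size * (n - desc.size)
    return weight / total_pairs


def simulate_sequences(
    tree: Phylogeny,
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
    marker: str = "marker1",
) -> MarkerAlignment:
    """Evolve a multi-accession alignment along the tree under K2P.

    The per-site substitution rate is set so the expected distance of a
    random heterospecific pair equals ``interspecific_divergence``.
    Each species then receives ``accessions_per_species`` accessions on
    independent terminal branchlets of length
    ``intraspecific_divergence / 2``, so two conspecific accessions sit
    ``intraspecific_divergence`` apart in expectation (a star within
    the species, i.e. conspecific accessions are exchangeable).
    """
    if config.accessions_per_species < 1:
        raise ValidationError("accessions_per_species must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rate = config.interspecific_divergence / _mean_pairwise_path(tree)
    length = config.marker_length
    root_seq = rng.integers(0, 4, size=length).astype(np.uint8)

    tip_seqs: dict[str, np.ndarray] = {}
    from .io import normalize_label

    def walk(node, seq):
        for child in node.child_nodes():
            d = float(child.edge.length) * rate
            child_seq = _evolve(seq, d, config.kappa, rng)
            if child.is_leaf():
                raw = child.taxon.label if child.taxon is not None else child.label
                tip_seqs[normalize_label(raw)] = child_seq
            else:
                walk(child, child_seq)

    walk(tree.dendropy_tree.seed_node, root_seq)

    accessions, species, rows = [], [], []
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    for sp in tree.tip_labels:
        base = tip_seqs[sp]
        for k in range(1, config.accessions_per_species + 1):
            acc_seq = _evolve(
                base, config.intraspecific_divergence / 2.0, config.kappa, rng
            )
            accessions.append(f"{sp}-a{k}")
            species.append(sp)
            rows.append(alphabet[acc_seq])
    return MarkerAlignment(
        marker=marker,
        accessions=accessions,
        species=species,
        matrix=np.vstack(rows),
    )


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------


@dataclass
class FixtureBundle:
    """A complete, mutually consistent synthetic input set."""

    config: SimulationConfig
    tree: Phylogeny
    assessments: AssessmentTable
    alignment: MarkerAlignment

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "tree": out / "tree.nwk",
            "assessments": out / "assessments.csv",
            "alignment": out / "marker.fasta",
            "species_map": out / "species_map.csv",
        }
        write_newick(self.tree, paths["tree"])
        write_assessments(self.assessments, paths["assessments"])
        self.alignment.to_fasta(paths["alignment"])
        self.alignment.species_map_frame().to_csv(paths["species_map"], index=False)
        return paths


def make_fixture(config: SimulationConfig | None = None) -> FixtureBundle:
    """Generate the full input bundle for one configuration.

    Regional and national categories are drawn from their respective
    frequency tables; traits are associated with the *regional* threat
    ordinal, matching the scope at which the trait analysis runs.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config)
    tips = tree.tip_labels
    hk = simulate_categories(tips, config.hk_frequencies, rng)
    cn = simulate_categories(tips, config.cn_frequencies, rng)
    traits = simulate_traits(hk, config.rho_targets, rng)
    df = pd.DataFrame(
        {
            "category_hk": hk.values,
            "category_cn": cn.values,
            "habit": traits["habit"].values,
            "habitats": traits["habitats"].values,
            "mating": traits["mating"].values,
            "trade": traits["trade"].values,
        },
        index=pd.Index(tips, name="taxon"),
    )
    assessments = AssessmentTable(df)
    alignment = simulate_sequences(tree, config, rng)
    return FixtureBundle(
        config=config, tree=tree, assessments=assessments, alignment=alignment
    )
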