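import math

import numpy as np
import pytest
from scipy import stats

from orchidedge.barcode import (
    barcoding_gap_anova,
    bootstrap_se,
    diversity_decomposition,
    diversity_from_means,
    k2p_distance,
    k2p_from_counts,
    partition_distances,
)
from orchidedge.errors import (
    InsufficientDataError,
    SaturationError,
    ValidationError,
)
from orchidedge.io import MarkerAlignment
from orchidedge.reference import MARKER_DIVERSITY_MEANS
from orchidedge.simulate import SimulationConfig, make_fixture


def make_alignment(seqs: dict[str, str], species: dict[str, str]) -> MarkerAlignment:
    accs = list(seqs)
    return MarkerAlignment(
        marker="test",
        accessions=accs,
        species=[species[a] for a in accs],
        matrix=np.vstack(
            [np.frombuffer(seqs[a].encode(), dtype="S1") for a in accs]
        ),
    )


class TestK2pDistance:
    def test_identical_sequences(self):
        pair = k2p_distance("ACGTACGT", "ACGTACGT")
        assert pair.distance == 0.0
        assert pair.usable_sites == 8

    def test_transitions_only_closed_form(self):
        # 100 sites, 10 transitions: d = -1/2 ln(1 - 0.2)
        seq1 = "A" * 100
        seq2 = "G" * 10 + "A" * 90
        pair = k2p_distance(seq1, seq2)
        assert pair.p_transitions == pytest.approx(0.10)
        assert pair.q_transversions == 0.0
        assert pair.distance == pytest.approx(-0.5 * math.log(0.8))
        assert pair.distance == pytest.approx(0.11157, abs=5e-6)

    def test_pairwise_deletion(self):
        pair = k2p_distance("ACGT", "A-GT")
        assert pair.usable_sites == 3
        assert pair.distance == 0.0

    def test_ambiguity_codes_deleted(self):
        pair = k2p_distance("ACGT", "ANGT")
        assert pair.usable_sites == 3

    def test_transversions_counted(self):
        # A->C is a transversion; mixed with one A->G transition
        pair = k2p_distance("AAAA", "CGAA")
        assert pair.p_transitions == pytest.approx(0.25)
        assert pair.q_transversions == pytest.approx(0.25)
        d = -0.5 * math.log(1 - 0.5 - 0.25) - 0.25 * math.log(1 - 0.5)
        assert pair.distance == pytest.approx(d)

    def test_saturation_flagged_not_raised(self):
        pair = k2p_distance("AAAA", "GGGG")  # P=1: 1-2P-Q < 0
        assert not pair.defined
        assert math.isnan(pair.distance)

    def test_saturation_raises_in_count_form(self):
        with pytest.raises(SaturationError):
            k2p_from_counts(4, 4, 0)

    def test_zero_usable_sites(self):
        with pytest.raises(ValidationError):
            k2p_distance("----", "AAAA")

    def test_jc_like_reduction_when_no_transversions(self):
        # with Q=0 the K2P distance collapses to -1/2 ln(1-2P)
        assert k2p_from_counts(50, 5, 0) == pytest.approx(
            -0.5 * math.log(1 - 2 * 0.1)
        )


class TestPartitionDistances:
    def test_two_species_two_accessions(self):
        aln = make_alignment(
            {
                "a1": "ACGTACGTAC",
                "a2": "ACGTACGTAT",
                "b1": "GGGTACGTAC",
                "b2": "GGGTACGTAT",
            },
            {"a1": "spA", "a2": "spA", "b1": "spB", "b2": "spB"},
        )
        md = partition_distances(aln)
        assert len(md.intra) == 2
        assert len(md.inter) == 4
        assert len(md.pairs) == 6  # C(4,2)

    def test_single_accession_per_species_has_no_intra(self):
        aln = make_alignment(
            {"a1": "ACGTACGTAC", "b1": "GGGTACGTAC"}, {"a1": "spA", "b1": "spB"}
        )
        md = partition_distances(aln)
        assert len(md.intra) == 0
        assert math.isnan(md.summary()["intraspecific_mean_distance"].iloc[0])

    def test_partition_completeness_with_undefined(self):
        aln = make_alignment(
            {"a1": "AAAA", "a2": "GGGG", "b1": "ACGT"},
            {"a1": "spA", "a2": "spA", "b1": "spB"},
        )
        md = partition_distances(aln)
        assert len(md.intra) + len(md.inter) + md.n_undefined == 3

    def test_gap_separates_scales(self, gap_fixture):
        md = gap_fixture
        assert md.intra.max() < md.inter.min()


@pytest.fixture(scope="module")
def gap_fixture():
    """Sequences on a star species tree: every interspecific pair sits
    at the same expected divergence (0.08), far above the
    intraspecific scale (0.003) — cleanly separated scales."""
    from orchidedge.io import read_newick
    from orchidedge.simulate import simulate_sequences

    star = read_newick("(" + ",".join(f"sp{i:02d}:55" for i in range(15)) + ");")
    config = SimulationConfig(
        n_taxa=15, marker_length=2000, accessions_per_species=2, seed=11
    )
    aln = simulate_sequences(star, config, seed=11)
    return partition_distances(aln)


class TestDiversityDecomposition:
    def test_zero_within_gives_coefficient_one(self):
        decomp = diversity_from_means(0.05, 0.0)
        assert decomp.coefficient == 1.0
        assert decomp.delta_between == 0.05

    def test_identity_on_simulated_data(self, gap_fixture):
        decomp = diversity_decomposition(gap_fixture)
        assert decomp.delta_between + decomp.pi_within == pytest.approx(
            decomp.pi_total, rel=1e-12
        )
        assert 0 <= decomp.coefficient <= 1

    @pytest.mark.parametrize(
        "marker, means", list(MARKER_DIVERSITY_MEANS.items())
    )
    def test_published_marker_means(self, marker, means):
        pi_total, pi_within, delta_printed, coeff_printed = means
        decomp = diversity_from_means(pi_total, pi_within)
        # delta is exact on the printed rounded inputs for trnH-psbA
        # and within one rounding unit elsewhere
        assert decomp.delta_between == pytest.approx(delta_printed, abs=1.5e-4)
        assert decomp.coefficient == pytest.approx(coeff_printed, abs=1e-3)

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            diversity_from_means(0.0, 0.0)


class TestBarcodingGapAnova:
    def test_identical_groups_f_zero(self):
        from orchidedge.barcode import MarkerDistances

        md = MarkerDistances(
            "m", [], np.array([0.01] * 5), np.array([0.01] * 5), {}, 0
        )
        f_stat, p = barcoding_gap_anova(md)
        assert f_stat == 0.0 and p == 1.0

    def test_hand_anova_and_scipy_cross_check(self):
        from orchidedge.barcode import MarkerDistances

        intra = np.array([0.001, 0.002, 0.003])
        inter = np.array([0.10, 0.11, 0.12])
        md = MarkerDistances("m", [], intra, inter, {}, 0)
        f_stat, p = barcoding_gap_anova(md)
        # hand computation: SSB = 6*(0.054)^2, SSW = 2e-6 + 2e-4
        assert f_stat == pytest.approx(0.017496 / (2.02e-4 / 4), rel=1e-6)
        ref = stats.f_oneway(intra, inter)
        assert f_stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_clear_gap_is_significant(self, gap_fixture):
        f_stat, p = barcoding_gap_anova(gap_fixture)
        assert p < 1e-6

    def test_empty_group_rejected(self):
        from orchidedge.barcode import MarkerDistances

        md = MarkerDistances("m", [], np.array([]), np.array([0.1, 0.2]), {}, 0)
        with pytest.raises(InsufficientDataError):
            barcoding_gap_anova(md)


class TestBootstrapSe:
    @staticmethod
    def _mean_total(aln):
        md = partition_distances(aln)
        return float(np.mean(np.concatenate([md.intra, md.inter])))

    def test_zero_variation_alignment(self):
        aln = make_alignment(
            {"a1": "ACGT" * 5, "b1": "ACGT" * 5}, {"a1": "spA", "b1": "spB"}
        )
        se = bootstrap_se(aln, self._mean_total, replicates=20, seed=1)
        assert se == 0.0

    def test_seed_reproducibility(self, small_bundle):
        aln = small_bundle.alignment
        a = bootstrap_se(aln, self._mean_total, replicates=30, seed=3)
        b = bootstrap_se(aln, self._mean_total, replicates=30, seed=3)
        assert a == b

    def test_se_shrinks_with_length(self):
        ses = []
        for length, seed in ((300, 21), (3000, 21)):
            config = SimulationConfig(
                n_taxa=8, marker_length=length, accessions_per_species=2, seed=seed
            )
            bundle = make_fixture(config)
            ses.append(
                bootstrap_se(bundle.alignment, self._mean_total, replicates=40, seed=5)
            )
        assert ses[1] < ses[0]
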