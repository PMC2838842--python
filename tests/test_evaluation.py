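"""Reproducibility metrics, ratio reconstruction, effect sizes, clustering."""

import numpy as np
import pandas as pd
import pytest

import twocolor as tc
from twocolor.design import ChannelKey
from twocolor.evaluation import RatioPairing
from twocolor.models import ResultTable
from twocolor.preprocess import ExpressionMatrix


def _table(p_values, probe_ids=None, model="intensity", **extra):
    p_values = np.asarray(p_values, dtype=float)
    if probe_ids is None:
        probe_ids = [f"P{i + 1:04d}" for i in range(len(p_values))]
    frame = pd.DataFrame({"p": p_values, **extra},
                         index=pd.Index(probe_ids, name="probe_id"))
    return ResultTable(frame=frame, model=model)


@pytest.fixture(scope="module")
def random_tables():
    rng = np.random.default_rng(42)
    ids = [f"P{i + 1:05d}" for i in range(1000)]
    return (_table(rng.uniform(size=1000), ids), _table(rng.uniform(size=1000), ids))


class TestPvalueReproducibility:
    def test_identical_tables_give_rho_one(self, random_tables):
        r1, _ = random_tables
        assert tc.pvalue_reproducibility(r1, r1) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, random_tables):
        r1, _ = random_tables
        transformed = _table(np.sqrt(r1.frame["p"].to_numpy()), list(r1.probe_ids))
        assert tc.pvalue_reproducibility(r1, transformed) == pytest.approx(1.0)

    def test_independent_uniform_p_values_uncorrelated(self, random_tables):
        r1, r2 = random_tables
        assert abs(tc.pvalue_reproducibility(r1, r2)) < 0.1

    def test_requires_at_least_three_probes(self):
        r = _table([0.1, 0.2])
        with pytest.raises(ValueError, match="3 probes"):
            tc.pvalue_reproducibility(r, r)

    def test_mismatched_probe_sets_rejected(self, random_tables):
        r1, _ = random_tables
        other = _table([0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="different probe sets"):
            tc.pvalue_reproducibility(r1, other)


class TestBinOverlap:
    def test_identical_rankings_give_all_ones(self, random_tables):
        r1, _ = random_tables
        bins = tc.bin_overlap(r1, r1, bin_size=100)
        assert (bins["overlap_fraction"] == 1.0).all()

    def test_reversed_rankings_two_bins(self):
        ids = [f"P{i}" for i in range(10)]
        r1 = _table(np.linspace(0.01, 0.9, 10), ids)
        r2 = _table(np.linspace(0.9, 0.01, 10), ids)
        bins = tc.bin_overlap(r1, r2, bin_size=5)
        # membership enumerated by hand: the two halves swap completely
        assert list(bins["overlap_fraction"]) == [0.0, 0.0]

    def test_trailing_partial_bin_uses_own_size(self):
        ids = [f"P{i}" for i in range(7)]
        r = _table(np.linspace(0.1, 0.7, 7), ids)
        bins = tc.bin_overlap(r, r, bin_size=5)
        assert list(bins["bin_size"]) == [5, 2]
        assert (bins["overlap_fraction"] == 1.0).all()

    def test_random_rankings_match_hypergeometric_expectation(self):
        # with n = 10 * bin_size, E[overlap fraction] = bin_size / n = 0.1
        rng = np.random.default_rng(7)
        ids = [f"P{i:05d}" for i in range(2000)]
        fractions = []
        for _ in range(30):
            r1 = _table(rng.uniform(size=2000), ids)
            r2 = _table(rng.uniform(size=2000), ids)
            fractions.append(tc.bin_overlap(r1, r2, bin_size=200)["overlap_fraction"].mean())
        assert np.mean(fractions) == pytest.approx(0.1, abs=0.02)

    def test_monotone_transform_invariance(self, random_tables):
        r1, r2 = random_tables
        r2t = _table(r2.frame["p"].to_numpy() ** 3, list(r2.probe_ids))
        pd.testing.assert_frame_equal(
            tc.bin_overlap(r1, r2, 100), tc.bin_overlap(r1, r2t, 100)
        )


class TestTopKOverlap:
    def test_identical_rankings(self, random_tables):
        r1, _ = random_tables
        curve = tc.topk_overlap_curve(r1, r1, k_min=10, k_max=500, step=10)
        assert (curve.fraction == 1.0).all()

    def test_disjoint_top_lists_give_zero(self):
        ids = [f"P{i}" for i in range(20)]
        p1 = np.concatenate([np.linspace(0.001, 0.01, 10), np.linspace(0.5, 0.9, 10)])
        p2 = np.concatenate([np.linspace(0.5, 0.9, 10), np.linspace(0.001, 0.01, 10)])
        r1, r2 = _table(p1, ids), _table(p2, ids)
        curve = tc.topk_overlap_curve(r1, r2, k_min=10, k_max=10, step=10)
        assert curve.fraction[0] == 0.0

    def test_full_length_overlap_is_one(self, random_tables):
        r1, r2 = random_tables
        curve = tc.topk_overlap_curve(r1, r2, k_min=1000, k_max=1000, step=1)
        assert curve.fraction[-1] == 1.0

    def test_matches_naive_set_intersection(self, random_tables):
        r1, r2 = random_tables
        curve = tc.topk_overlap_curve(r1, r2, k_min=10, k_max=300, step=37)
        o1, o2 = r1.ranking(), r2.ranking()
        for k, frac in zip(curve.k, curve.fraction):
            assert frac == len(set(o1[:k]) & set(o2[:k])) / k

    def test_random_rankings_expectation_k_over_n(self):
        rng = np.random.default_rng(11)
        ids = [f"P{i:05d}" for i in range(1000)]
        acc = np.zeros(10)
        reps = 40
        for _ in range(reps):
            r1 = _table(rng.uniform(size=1000), ids)
            r2 = _table(rng.uniform(size=1000), ids)
            curve = tc.topk_overlap_curve(r1, r2, k_min=100, k_max=1000, step=100)
            acc += curve.fraction
        np.testing.assert_allclose(acc / reps, np.arange(100, 1001, 100) / 1000, atol=0.03)


class TestRecallAtRatioCutoff:
    def test_identical_tables(self, random_tables):
        r1, _ = random_tables
        recall, extra = tc.recall_at_ratio_cutoff(r1, r1, k=100)
        assert recall == 1.0 and extra == 0

    def test_uniformly_smaller_intensity_p_keeps_recall_one(self, random_tables):
        r1, _ = random_tables
        r2 = _table(r1.frame["p"].to_numpy() / 10.0, list(r1.probe_ids))
        recall, extra = tc.recall_at_ratio_cutoff(r1, r2, k=100)
        assert recall == 1.0
        assert extra > 0  # looser effective cutoff admits outside probes

    def test_hand_enumerated_ten_probe_case(self):
        ids = [f"g{i}" for i in range(10)]
        p_ratio = np.array([0.01, 0.02, 0.03, 0.04, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90])
        p_int = np.array([0.005, 0.300, 0.010, 0.020, 0.015, 0.60, 0.70, 0.80, 0.90, 0.95])
        # cutoff = 4th smallest ratio p = 0.04; ratio top-4 = g0..g3;
        # of those, intensity p <= 0.04 for g0, g2, g3 -> recall 3/4;
        # outside the top-4, only g4 (0.015) < 0.04 -> extra = 1
        recall, extra = tc.recall_at_ratio_cutoff(
            _table(p_ratio, ids, model="ratio"), _table(p_int, ids), k=4
        )
        assert recall == pytest.approx(0.75)
        assert extra == 1


class TestReconstructRatios:
    def _matrix_and_design(self):
        design = tc.make_design("two-group-paired", technical_replicates=4)
        cfg = tc.SimulationConfig(seed=5, n_probes=300, topology="two-group-paired",
                                  technical_replicates=4, fraction_de=0.5,
                                  effect_sd=0.8, sigma_array=0.0, sigma_noise=0.05)
        matrix, design, _ = tc.simulate_dataset(cfg)
        return matrix, design

    def test_duplicated_channels_give_r_one(self):
        matrix, design = self._matrix_and_design()
        # reconstruct from the very channels hybridized on the direct array
        row3 = [r for r in design.rows if r.channel.array_id == "A01"]
        pairing = RatioPairing(row3[0].channel, row3[1].channel, "A01")
        out = tc.reconstruct_ratios(matrix, design, [pairing])
        assert out["pearson_r"].iloc[0] == pytest.approx(1.0)

    def test_low_noise_reconstruction_correlates(self):
        matrix, design = self._matrix_and_design()
        a2 = {r.treatment: r.channel for r in design.rows if r.channel.array_id == "A02"}
        a3 = {r.treatment: r.channel for r in design.rows if r.channel.array_id == "A03"}
        pairing = RatioPairing(a2["G1"], a3["G2"], "A01")
        out = tc.reconstruct_ratios(matrix, design, [pairing])
        assert out["pearson_r"].iloc[0] > 0.95

    def test_reconstruction_degrades_with_channel_noise(self):
        rs = []
        for sigma in (0.05, 0.3, 1.0):
            cfg = tc.SimulationConfig(seed=9, n_probes=300, topology="two-group-paired",
                                      technical_replicates=4, fraction_de=0.5,
                                      effect_sd=0.8, sigma_array=0.0, sigma_noise=sigma)
            matrix, design, _ = tc.simulate_dataset(cfg)
            a2 = {r.treatment: r.channel for r in design.rows if r.channel.array_id == "A02"}
            a3 = {r.treatment: r.channel for r in design.rows if r.channel.array_id == "A03"}
            pairing = RatioPairing(a2["G1"], a3["G2"], "A01")
            rs.append(tc.reconstruct_ratios(matrix, design, [pairing])["pearson_r"].iloc[0])
        assert rs[0] > rs[1] > rs[2]

    def test_unknown_channel_rejected(self):
        matrix, design = self._matrix_and_design()
        bad = RatioPairing(ChannelKey("A99", "Cy3"), design.rows[1].channel, "A01")
        with pytest.raises(KeyError):
            tc.reconstruct_ratios(matrix, design, [bad])


class TestEffectSizeComparison:
    def test_single_probe_two_treatments(self):
        frame = pd.DataFrame(
            {"p": [0.5, 0.6], "M[G1-G2]": [0.5, -0.3], "mean_abs_array_effect": [0.1, 0.2]},
            index=pd.Index(["p1", "p2"], name="probe_id"),
        )
        sizes, _ = tc.effect_size_comparison(ResultTable(frame=frame, model="ratio"))
        # |M| of the single treatment pair, for either sign
        assert sizes["treatment_effect_size"].tolist() == pytest.approx([0.5, 0.3])

    def test_treatment_mass_right_of_array_mass(self, paired_dataset):
        matrix, design, truth = paired_dataset
        rt = tc.fit_dataset(matrix, design, tc.ratio_spec())
        de = truth.de_mask
        sizes, kdes = tc.effect_size_comparison(rt)
        assert sizes["treatment_effect_size"][de].mean() > sizes["array_effect_size"][de].mean()
        assert set(kdes) == {"treatment", "array"}

    def test_requires_array_effect_estimates(self, paired_dataset):
        matrix, design, _ = paired_dataset
        rt = tc.fit_dataset(matrix, design, tc.intensity_spec())
        with pytest.raises(ValueError, match="array-effect"):
            tc.effect_size_comparison(rt)


class TestClusterChannels:
    def test_identical_pair_merges_first_at_height_zero(self, rng):
        base = rng.normal(8, 1, 50)
        other = rng.normal(8, 1, 50)
        m = ExpressionMatrix(
            np.array([f"P{i}" for i in range(50)], dtype=object),
            [ChannelKey("A1", "Cy3"), ChannelKey("A1", "Cy5"), ChannelKey("A2", "Cy3")],
            np.column_stack([base, base, other]),
            log2=True,
        )
        dendro = tc.cluster_channels(m)
        first_merge = dendro.linkage[0]
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}
        assert first_merge[2] == pytest.approx(0.0, abs=1e-12)

    def test_three_channel_longhand_complete_linkage(self):
        # hand-computed: corr(c1,c2) high, c3 anti-correlated with both
        v = np.array([
            [1.0, 1.1, 3.0],
            [2.0, 2.1, 2.0],
            [3.0, 2.9, 1.0],
            [4.0, 4.2, 0.5],
        ])
        m = ExpressionMatrix(
            np.array(["a", "b", "c", "d"], dtype=object),
            [ChannelKey("A1", "Cy3"), ChannelKey("A1", "Cy5"), ChannelKey("A2", "Cy3")],
            v, log2=True,
        )
        corr = np.corrcoef(v.T)
        d12, d13, d23 = 1 - corr[0, 1], 1 - corr[0, 2], 1 - corr[1, 2]
        dendro = tc.cluster_channels(m)
        assert {int(dendro.linkage[0, 0]), int(dendro.linkage[0, 1])} == {0, 1}
        assert dendro.linkage[0, 2] == pytest.approx(d12)
        assert dendro.linkage[1, 2] == pytest.approx(max(d13, d23))  # complete linkage

    def test_replicate_channels_cluster_as_siblings(self, factorial_dataset):
        # same treatment measured twice: replicate channels pair up first
        matrix, design, _ = factorial_dataset
        # restrict to unit U1, replicate set 1: two channels per treatment
        chans = [r.channel for r in design.rows
                 if r.unit == "U1" and r.replicate_set == 1]
        sub = matrix.subset_channels(chans)
        dendro = tc.cluster_channels(sub)
        treatments = [design.row_for(c).treatment for c in chans]
        # the first 4 merges must join leaves of identical treatment
        n_leaves = len(chans)
        for row in dendro.linkage[:4]:
            i, j = int(row[0]), int(row[1])
            assert i < n_leaves and j < n_leaves
            assert treatments[i] == treatments[j]

    def test_constant_channel_rejected(self):
        m = ExpressionMatrix(
            np.array(["a", "b", "c"], dtype=object),
            [ChannelKey("A1", "Cy3"), ChannelKey("A1", "Cy5"), ChannelKey("A2", "Cy3")],
            np.column_stack([[1, 2, 3], [5, 5, 5], [2, 1, 3]]).astype(float),
            log2=True,
        )
        with pytest.raises(ValueError, match="A1:Cy5"):
            tc.cluster_channels(m)

    def test_newick_output_parses(self, paired_dataset):
        matrix, _, _ = paired_dataset
        newick = tc.cluster_channels(matrix).to_newick()
        assert newick.endswith(";")
        assert newick.count("(") == newick.count(")")
        assert newick.count(",") == matrix.n_channels - 1


class TestMValueReproducibility:
    def test_identical_tables_give_r_one(self):
        rng = np.random.default_rng(3)
        ids = [f"P{i}" for i in range(100)]
        r = _table(rng.uniform(size=100), ids, **{"M[G1-G2]": rng.normal(size=100)})
        assert tc.m_value_reproducibility(r, r, "G1", "G2") == pytest.approx(1.0)

    def test_independent_null_effects_uncorrelated(self):
        rng = np.random.default_rng(4)
        ids = [f"P{i}" for i in range(2000)]
        r1 = _table(rng.uniform(size=2000), ids, **{"M[G1-G2]": rng.normal(size=2000)})
        r2 = _table(rng.uniform(size=2000), ids, **{"M[G1-G2]": rng.normal(size=2000)})
        assert abs(tc.m_value_reproducibility(r1, r2, "G1", "G2")) < 0.08

    def test_reversed_contrast_uses_negated_column(self):
        rng = np.random.default_rng(5)
        ids = [f"P{i}" for i in range(50)]
        m = rng.normal(size=50)
        r = _table(rng.uniform(size=50), ids, **{"M[G1-G2]": m})
        np.testing.assert_allclose(r.m_column("G2", "G1"), -m)

    def test_inestimable_contrast_rejected(self):
        ids = [f"P{i}" for i in range(10)]
        r = _table(np.linspace(0.1, 1, 10), ids, **{"M[G1-G2]": [np.nan] * 10})
        with pytest.raises(ValueError, match="not estimable"):
            tc.m_value_reproducibility(r, r, "G1", "G2")
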