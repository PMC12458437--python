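"""Tests of the Monte-Carlo differential-abundance engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sridiff import (
    CountTable,
    ExternalScale,
    PredictedScale,
    TSSScale,
    absolute_replicates,
    benjamini_hochberg,
    draw_compositions,
    estimate_theta,
    run_da,
    wilcoxon_rank_sum,
)
from sridiff.engine import ThetaReplicates, _rank_sum_pvalues_matrix
from sridiff.measurement import CompositionReplicates
from sridiff.scale_models import ScaleSample


def _comp(values):
    values = np.asarray(values, dtype=float)
    S, D, N = values.shape
    return CompositionReplicates(
        values=values,
        taxa=[f"t{i}" for i in range(D)],
        samples=[f"s{j}" for j in range(N)],
        prior_mass=0.5,
        n_replicates=S,
        seed=0,
    )


class TestAbsoluteReplicates:
    def test_zero_scale_is_log_composition(self):
        comp = _comp(np.full((2, 2, 3), 0.5))
        scale = ScaleSample(np.zeros((2, 3)), "tss", 0.0)
        out = absolute_replicates(comp, scale)
        assert np.array_equal(out, np.log2(comp.values))

    def test_uniform_composition_closed_form(self):
        D = 4
        comp = _comp(np.full((3, D, 2), 1.0 / D))
        scale = ScaleSample(np.full((3, 2), 7.0), "predicted", 0.0)
        out = absolute_replicates(comp, scale)
        assert np.allclose(out, 7.0 - np.log2(D))

    def test_matches_elementwise_loop_oracle(self, rng):
        vals = rng.dirichlet(np.ones(5), size=(4, 6)).transpose(0, 2, 1)
        comp = _comp(vals)
        scale = ScaleSample(rng.normal(size=(4, 6)), "external", 1.0)
        out = absolute_replicates(comp, scale)
        for s in range(4):
            for d in range(5):
                for n in range(6):
                    expected = np.log2(vals[s, d, n]) + scale.log2_scale[s, n]
                    assert out[s, d, n] == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        comp = _comp(np.full((2, 2, 3), 0.5))
        scale = ScaleSample(np.zeros((2, 4)), "tss", 0.0)
        with pytest.raises(ValueError, match="shape"):
            absolute_replicates(comp, scale)


class TestEstimateTheta:
    COND = np.array([0, 0, 1, 1])

    def test_cancellation_gives_zero_net_change(self):
        # relative abundance doubles (theta_par=1) while load halves
        # (theta_perp=-1): net theta is exactly 0
        comp_vals = np.array([[[0.25, 0.25, 0.5, 0.5], [0.75, 0.75, 0.5, 0.5]]])
        scale_vals = np.array([[0.0, 0.0, -1.0, -1.0]])
        thetas = estimate_theta(
            _comp(comp_vals), ScaleSample(scale_vals, "external", 0.0), self.COND
        )
        assert thetas.theta_par[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert thetas.theta_perp[0] == pytest.approx(-1.0, abs=1e-12)
        assert thetas.theta[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_identical_groups_give_zero(self):
        comp_vals = np.tile(np.array([0.2, 0.3, 0.5])[None, :, None], (2, 1, 4))
        scale_vals = np.full((2, 4), 3.0)
        thetas = estimate_theta(
            _comp(comp_vals), ScaleSample(scale_vals, "external", 0.0), self.COND
        )
        assert np.allclose(thetas.theta, 0.0, atol=1e-12)

    def test_hand_computed_two_per_group(self):
        # spreadsheet-style oracle on a 2-taxon, 2+2-sample instance
        p = np.array([[[0.1, 0.2, 0.4, 0.3], [0.9, 0.8, 0.6, 0.7]]])
        scale = np.array([[1.0, 2.0, 3.0, 5.0]])
        thetas = estimate_theta(
            _comp(p), ScaleSample(scale, "external", 0.0), self.COND
        )
        expected_par_t0 = (np.log2(0.4) + np.log2(0.3)) / 2 - (np.log2(0.1) + np.log2(0.2)) / 2
        expected_perp = (3.0 + 5.0) / 2 - (1.0 + 2.0) / 2
        assert thetas.theta_par[0, 0] == pytest.approx(expected_par_t0, abs=1e-12)
        assert thetas.theta_perp[0] == pytest.approx(expected_perp, abs=1e-12)
        assert thetas.theta[0, 0] == pytest.approx(expected_par_t0 + expected_perp, abs=1e-12)

    def test_decomposition_identity_random_instances(self, rng):
        # theta from the parts equals the group-mean difference computed
        # directly on log2 absolute abundances, for every replicate and taxon
        cond = np.array([0, 0, 0, 1, 1, 1, 1])
        vals = rng.dirichlet(np.ones(8), size=(10, 7)).transpose(0, 2, 1)
        comp = _comp(vals)
        for scale_vals in (
            np.zeros((10, 7)),
            rng.normal(size=(10, 7)),
            np.tile(rng.normal(size=7), (10, 1)),
        ):
            scale = ScaleSample(scale_vals, "x", 0.0)
            thetas = estimate_theta(comp, scale, cond)
            direct = absolute_replicates(comp, scale)
            theta_direct = direct[..., cond == 1].mean(-1) - direct[..., cond == 0].mean(-1)
            assert np.abs(thetas.theta - theta_direct).max() < 1e-10

    def test_empty_condition_rejected(self):
        comp = _comp(np.full((1, 2, 3), 1 / 2))
        scale = ScaleSample(np.zeros((1, 3)), "tss", 0.0)
        with pytest.raises(ValueError, match="condition"):
            estimate_theta(comp, scale, np.array([1, 1, 1]))


class TestWilcoxonRankSum:
    def test_small_example_exact(self):
        assert wilcoxon_rank_sum([1, 2], [3, 4], mode="exact") == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        assert wilcoxon_rank_sum([2.0, 2.0, 2.0], [2.0, 2.0], mode="exact") == 1.0
        assert wilcoxon_rank_sum([2.0] * 10, [2.0] * 10, mode="normal") == 1.0

    @pytest.mark.parametrize("n,m", [(3, 3), (4, 5), (5, 5), (2, 6)])
    def test_exact_matches_scipy_enumeration(self, n, m, rng):
        # tie-free data: scipy's exact Mann-Whitney is an independent oracle
        x = rng.normal(size=n)
        y = rng.normal(size=m) + 0.5
        ours = wilcoxon_rank_sum(x, y, mode="exact")
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_exact_with_ties_brute_force(self):
        # mid-rank enumeration checked against direct enumeration over splits
        from itertools import combinations

        x = np.array([1.0, 2.0, 2.0])
        y = np.array([2.0, 3.0, 4.0])
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        expect = 3 * 7 / 2.0
        obs = abs(ranks[:3].sum() - expect)
        hits = sum(
            1
            for idx in combinations(range(6), 3)
            if abs(ranks[list(idx)].sum() - expect) >= obs - 1e-9
        )
        assert wilcoxon_rank_sum(x, y, mode="exact") == pytest.approx(hits / 20)

    def test_normal_mode_matches_scipy_asymptotic(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=25) + 0.3
        ours = wilcoxon_rank_sum(x, y, mode="normal")
        ref = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        ).pvalue
        assert ours == pytest.approx(ref, rel=1e-10)

    def test_normal_mode_tie_correction_matches_scipy(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0] * 4)
        y = np.array([2.0, 3.0, 3.0, 4.0, 6.0] * 4)
        ours = wilcoxon_rank_sum(x, y, mode="normal")
        ref = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        ).pvalue
        assert ours == pytest.approx(ref, rel=1e-10)

    def test_vectorized_path_matches_scalar(self, rng):
        cond = np.array([0] * 10 + [1] * 12)
        data = rng.normal(size=(3, 5, 22))
        p = _rank_sum_pvalues_matrix(data, cond)
        for s in range(3):
            for d in range(5):
                ref = wilcoxon_rank_sum(
                    data[s, d, cond == 0], data[s, d, cond == 1], mode="normal"
                )
                assert p[s, d] == pytest.approx(ref, rel=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBenjaminiHochberg:
    def test_worked_examples(self):
        assert np.allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        assert np.allclose(
            benjamini_hochberg([0.005, 0.02, 0.1]), [0.015, 0.03, 0.1]
        )

    def test_flat_vector_fixed_point(self):
        assert np.allclose(benjamini_hochberg([0.3] * 5), 0.3)

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(benjamini_hochberg(p), ref, atol=1e-12)

    def test_2d_rows_adjusted_independently(self, rng):
        p = rng.uniform(size=(6, 15))
        out = benjamini_hochberg(p)
        for i in range(6):
            assert np.allclose(out[i], benjamini_hochberg(p[i]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    def test_properties(self, p):
        adj = benjamini_hochberg(p)
        p = np.asarray(p)
        assert np.all(adj <= 1.0) and np.all(adj >= p - 1e-15)
        # order invariance: adjusting a permutation permutes the adjustment
        perm = np.argsort(p, kind="stable")[::-1]
        assert np.allclose(benjamini_hochberg(p[perm]), adj[perm])
        # monotone: sorted inputs give sorted outputs
        assert np.all(np.diff(benjamini_hochberg(np.sort(p))) >= -1e-15)


class TestRunDA:
    def test_null_type_one_error(self, null_dataset):
        res = run_da(null_dataset.counts, TSSScale(0.0), n_replicates=128, seed=21)
        frac_sig = res.table["significant"].mean()
        assert frac_sig <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / null_dataset.counts.n_taxa)

    def test_spike_recovered_with_true_loads(self, spiked_dataset):
        model = ExternalScale(spiked_dataset.true_loads_log2.to_numpy(), gamma=0.0)
        res = run_da(spiked_dataset.counts, model, n_replicates=128, seed=22)
        spiked = spiked_dataset.truth_flags[spiked_dataset.truth_flags != "null"]
        assert len(spiked) == 1
        taxon = spiked.index[0]
        row = res.table.loc[taxon]
        assert row["significant"]
        expected_dir = "+" if spiked.iloc[0] == "up" else "-"
        assert row["direction"] == expected_dir

    def test_constant_predictions_equal_tss(self, null_dataset):
        n = null_dataset.counts.n_samples
        res_pred = run_da(
            null_dataset.counts, PredictedScale(np.full(n, 5.0)), n_replicates=32, seed=7
        )
        res_tss = run_da(null_dataset.counts, TSSScale(0.0), n_replicates=32, seed=7)
        for col in ("theta", "theta_par", "theta_perp", "p_adj"):
            assert np.allclose(res_pred.table[col], res_tss.table[col], atol=1e-12)

    def test_determinism(self, tiny_counts):
        a = run_da(tiny_counts, TSSScale(1.0), n_replicates=16, seed=3)
        b = run_da(tiny_counts, TSSScale(1.0), n_replicates=16, seed=3)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_tss_gamma_limit(self, null_dataset):
        res_eps = run_da(null_dataset.counts, TSSScale(1e-8), n_replicates=64, seed=9)
        res_zero = run_da(null_dataset.counts, TSSScale(0.0), n_replicates=64, seed=9)
        assert np.allclose(res_eps.table["theta"], res_zero.table["theta"], atol=1e-6)
        assert np.allclose(res_eps.table["p_adj"], res_zero.table["p_adj"], atol=1e-6)

    def test_decomposition_identity_in_result(self, tiny_counts):
        for model in (TSSScale(1.0), ExternalScale(np.arange(6.0), gamma=0.5)):
            res = run_da(tiny_counts, model, n_replicates=32, seed=4)
            assert np.abs(
                res.table["theta"] - res.table["theta_par"] - res.table["theta_perp"]
            ).max() < 1e-10

    def test_significance_matches_alpha_contract(self, tiny_counts):
        res = run_da(tiny_counts, TSSScale(0.0), n_replicates=16, seed=1, alpha=0.4)
        tab = res.table
        assert ((tab["p_adj"] >= 0) & (tab["p_adj"] <= 1)).all()
        assert (tab["significant"] == (tab["p_adj"] < 0.4)).all()

    def test_compositional_invariance_of_tss_calls(self, spiked_dataset):
        # scaling every count leaves proportions unchanged; the TSS caller's
        # top hit and its call must be stable
        model = TSSScale(0.0)
        res1 = run_da(spiked_dataset.counts, model, n_replicates=64, seed=5)
        scaled = CountTable(
            counts=spiked_dataset.counts.counts * 3,
            condition=spiked_dataset.counts.condition,
        )
        res2 = run_da(scaled, model, n_replicates=64, seed=5)
        assert res1.table["p_adj"].idxmin() == res2.table["p_adj"].idxmin()
        corr = np.corrcoef(res1.table["p_adj"], res2.table["p_adj"])[0, 1]
        assert corr > 0.9

    def test_raw_average_mode(self, tiny_counts):
        res = run_da(
            tiny_counts, TSSScale(0.0), n_replicates=16, seed=1, p_average="raw"
        )
        assert ((res.table["p_adj"] >= 0) & (res.table["p_adj"] <= 1)).all()

    def test_single_taxon_rejected(self):
        counts = pd.DataFrame([[5, 6, 7, 8]], index=["A"], columns=list("wxyz"))
        table = CountTable(counts=counts, condition=pd.Series([0, 0, 1, 1], index=list("wxyz")))
        with pytest.raises(ValueError, match="2 taxa"):
            run_da(table, TSSScale(0.0), n_replicates=4)
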