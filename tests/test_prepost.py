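"""Paired pre/post statistics: t/dz, bootstrap, LOO, panel FDR, Spearman."""

import math

import numpy as np
import pytest
from scipy import stats

from medmr.exceptions import DegenerateVarianceError, DomainError, EmptyInputError
from medmr.prepost import (
    PairedFeatureTable,
    PairedPanelModel,
    SeizureOutcome,
    analyze_panel,
    bootstrap_dz_ci,
    fold_changes,
    loo_sensitivity,
    paired_test,
    response_correlation,
    seizure_control_rate,
)
from medmr.synthetic import MetabolomeSpec, simulate_paired_metabolome


class TestPairedTest:
    def test_hand_computed_example(self):
        """d = (1,2,3): mean 2, sd 1, so t = 2*sqrt(3) and dz = 2."""
        t, p, dz = paired_test([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * np.sqrt(3))
        assert dz == pytest.approx(2.0)

    def test_matches_scipy_on_random_pairs(self, rng):
        for _ in range(20):
            pre = rng.normal(10, 2, 12)
            post = pre + rng.normal(0.5, 1, 12)
            t, p, dz = paired_test(pre, post)
            ref = stats.ttest_rel(post, pre)
            assert t == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_identical_vectors_degenerate_with_mean_reported(self):
        with pytest.raises(DegenerateVarianceError) as exc:
            paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert exc.value.mean_diff == 0.0

    def test_antisymmetric_in_direction(self, rng):
        pre = rng.normal(10, 2, 9)
        post = pre + rng.normal(1, 1, 9)
        t1, p1, dz1 = paired_test(pre, post)
        t2, p2, dz2 = paired_test(post, pre)
        assert t2 == pytest.approx(-t1) and dz2 == pytest.approx(-dz1)
        assert p2 == pytest.approx(p1)

    def test_type_one_error_calibrated(self, rng):
        """Null rejection rate at alpha=0.05 lies in [0.04, 0.06] (5,000 reps)."""
        reps = 5000
        n = 9
        pre = rng.normal(10, 2, (reps, n))
        post = pre + rng.normal(0, 1, (reps, n))
        d = post - pre
        t = d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(n))
        rate = float((2 * stats.t.sf(np.abs(t), n - 1) < 0.05).mean())
        assert 0.04 <= rate <= 0.06
        # spot check the vectorized null against the implementation
        t0, p0, _ = paired_test(pre[0], post[0])
        assert t0 == pytest.approx(t[0])


class TestBootstrap:
    def test_seed_reproducibility(self, rng):
        pre = rng.normal(10, 2, 9)
        post = pre + rng.normal(1, 1, 9)
        a = bootstrap_dz_ci(pre, post, seed=42)
        b = bootstrap_dz_ci(pre, post, seed=42)
        assert (a.low, a.high) == (b.low, b.high)

    def test_constant_difference_zero_width(self):
        pre = np.array([1.0, 2.0, 3.0])
        post = pre + 0.5
        # every replicate is degenerate (sd = 0): flagged, width collapses
        ci = bootstrap_dz_ci(pre, post, seed=1)
        assert ci.low == ci.high
        assert ci.unreliable

    def test_subject_order_invariance(self, rng):
        pre = rng.normal(10, 2, 9)
        post = pre + rng.normal(1, 1, 9)
        perm = rng.permutation(9)
        a = bootstrap_dz_ci(pre, post, seed=3)
        b = bootstrap_dz_ci(pre[perm], post[perm], seed=3)
        assert (a.low, a.high) == (b.low, b.high)

    def test_interval_brackets_point_estimate(self, rng):
        pre = rng.normal(10, 2, 30)
        post = pre + rng.normal(1, 1, 30)
        _, _, dz = paired_test(pre, post)
        ci = bootstrap_dz_ci(pre, post, seed=5)
        assert ci.low < dz < ci.high


class TestFoldChange:
    def test_doubling(self):
        fc, lfc = fold_changes([1, 2, 3], [2, 4, 6])
        assert fc == pytest.approx(2.0) and lfc == pytest.approx(1.0)

    def test_no_change(self):
        fc, lfc = fold_changes([1, 2, 3], [1, 2, 3])
        assert fc == pytest.approx(1.0) and lfc == pytest.approx(0.0)

    def test_matches_independent_recomputation(self, rng):
        pre = rng.uniform(1, 5, 9)
        post = rng.uniform(1, 5, 9)
        fc, lfc = fold_changes(pre, post)
        assert fc == pytest.approx(np.mean(post) / np.mean(pre), rel=1e-12)
        assert lfc == pytest.approx(np.log2(fc), rel=1e-12)

    def test_zero_pre_mean_rejected(self):
        with pytest.raises(DomainError):
            fold_changes([0, 0, 0], [1, 2, 3])


class TestLOO:
    def test_nine_subjects_nine_refits(self, rng):
        pre = rng.normal(10, 2, 9)
        post = pre + rng.normal(1, 1, 9)
        out = loo_sensitivity(pre, post)
        assert out["n_refits"] == 9
        assert out["loo_p_min"] <= out["loo_p_max"]
        assert out["loo_dz_min"] <= out["loo_dz_max"]

    def test_outlier_removal_hits_range_extreme(self, rng):
        pre = np.full(9, 10.0)
        post = pre + np.r_[np.full(8, 1.0) + rng.normal(0, 0.05, 8), -5.0]
        out = loo_sensitivity(pre, post)
        # dropping the planted outlier gives the strongest (smallest-p) refit
        mask = np.arange(9) != 8
        _, p_wo, _ = paired_test(pre[mask], post[mask])
        assert out["loo_p_min"] == pytest.approx(p_wo)

    def test_constant_differences_all_refits_degenerate(self):
        pre = np.array([1.0, 2.0, 3.0, 4.0])
        out = loo_sensitivity(pre, pre + 1.0)
        assert out["n_degenerate"] == 4 and out["loo_p_min"] is None


class TestAnalyzePanel:
    def _table(self, rng, n=9, planted=None):
        spec = MetabolomeSpec(n_subjects=n, n_features=40, seed=int(rng.integers(2**31)))
        table, _, truth = simulate_paired_metabolome(spec)
        return table, truth

    def test_largest_effect_gets_smallest_q(self, rng):
        table, truth = self._table(rng)
        panel = truth["panel"]
        results = analyze_panel(table, panel=panel, seed=1)
        best = min(results, key=lambda r: r.qval)
        # top planted feature should usually win; assert it is among the top 2
        ranked = sorted(results, key=lambda r: r.qval)[:2]
        assert truth["top_feature"] in {r.feature_id for r in ranked}

    def test_single_feature_panel_q_equals_p(self, rng):
        table, truth = self._table(rng)
        (res,) = analyze_panel(table, panel=[truth["panel"][0]], seed=1)
        assert res.qval == pytest.approx(res.pval)

    def test_out_of_panel_features_do_not_change_q(self, rng):
        table, truth = self._table(rng)
        panel = truth["panel"]
        q_panel = {r.feature_id: r.qval for r in analyze_panel(table, panel=panel, seed=1)}
        q_all = {r.feature_id: r.qval for r in analyze_panel(table, panel=None, seed=1)}
        # panel-scoped q-values are computed over the panel only, so they must
        # be reproducible regardless of what other features exist in the table
        q_panel2 = {r.feature_id: r.qval for r in analyze_panel(table, panel=panel, seed=1)}
        assert q_panel == q_panel2
        assert any(q_all[f] != q_panel[f] for f in panel)  # scoping matters

    def test_subject_and_feature_order_invariance(self, rng):
        table, truth = self._table(rng)
        perm = rng.permutation(len(table.subject_ids))
        shuffled = PairedFeatureTable(
            [table.subject_ids[i] for i in perm], table.feature_ids,
            table.pre[perm], table.post[perm], table.panel_labels,
        )
        panel = list(truth["panel"])
        a = analyze_panel(table, panel=panel, seed=9)
        b = analyze_panel(shuffled, panel=list(reversed(panel)), seed=9)
        for ra, rb in zip(a, b):
            assert ra.feature_id == rb.feature_id
            assert ra.pval == pytest.approx(rb.pval, rel=1e-12)
            assert ra.qval == pytest.approx(rb.qval, rel=1e-12)
            if ra.dz_ci_low is not None:
                assert ra.dz_ci_low == pytest.approx(rb.dz_ci_low, rel=1e-12)

    def test_empty_panel_rejected(self, rng):
        table, _ = self._table(rng)
        with pytest.raises(EmptyInputError):
            analyze_panel(table, panel=[])

    def test_model_results_frame(self, rng):
        table, truth = self._table(rng)
        res = PairedPanelModel(table).fit(panel=truth["panel"], seed=2)
        df = res.to_frame()
        assert len(df) == len(truth["panel"])
        assert "qval" in df.columns and res.summary()


class TestSeizure:
    @pytest.mark.parametrize("pre,post,expect", [(10, 5, 50.0), (4, 0, 100.0), (4, 6, -50.0)])
    def test_control_rate_formula(self, pre, post, expect):
        assert seizure_control_rate(pre, post) == pytest.approx(expect)

    def test_scale_invariance(self):
        assert seizure_control_rate(8, 2) == seizure_control_rate(80, 20)

    def test_zero_pre_rejected(self):
        with pytest.raises(DomainError):
            seizure_control_rate(0, 1)

    def test_outcome_record_carries_rate(self):
        o = SeizureOutcome("S1", 10, 2.5)
        assert o.control_rate == pytest.approx(75.0)


class TestSpearman:
    def test_monotone_pairs(self):
        up = response_correlation([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert up.rho == pytest.approx(1.0)
        down = response_correlation([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert down.rho == pytest.approx(-1.0)

    def test_exact_p_matches_enumeration_oracle(self, rng):
        """For n <= 7 the p-value equals brute force over all permutations
        using scipy's rho as an independent statistic."""
        import itertools

        for _ in range(5):
            n = 6
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            res = response_correlation(x, y)
            assert res.method == "exact"
            rho_obs = stats.spearmanr(x, y).statistic
            assert res.rho == pytest.approx(rho_obs, rel=1e-12)
            count = sum(
                abs(stats.spearmanr(x, np.asarray(y)[list(perm)]).statistic) >= abs(rho_obs) - 1e-12
                for perm in itertools.permutations(range(n))
            )
            assert res.pval == pytest.approx(count / math.factorial(n))

    def test_n9_uses_seeded_permutation(self, rng):
        x = rng.normal(size=9)
        y = rng.normal(size=9)
        a = response_correlation(x, y, seed=1, n_perm=20000)
        b = response_correlation(x, y, seed=1, n_perm=20000)
        assert a.method == "permutation" and a.pval == b.pval
        assert a.exploratory

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            response_correlation([1, 1, 1, 1], [1, 2, 3, 4])

    def test_coupled_simulation_recovers_rank_correlation(self):
        spec = MetabolomeSpec(response_coupling=1.0, seed=5)
        table, seizures, truth = simulate_paired_metabolome(spec)
        pre, post = table.column(truth["top_feature"])
        rates = [s.control_rate for s in seizures]
        res = response_correlation(np.log(post / pre), rates, seed=0)
        assert res.rho == pytest.approx(1.0)
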