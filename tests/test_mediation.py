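"""Mediation decomposition identities, screening logic, step-2 exclusion."""

import numpy as np
import pytest

from medmr.gwas_io import TraitSummary
from medmr.instruments import InstrumentSet, LDMatrix, select_instruments
from medmr.mediation import (
    ScreenConfig,
    decompose,
    forward_screen,
    mediation_scan,
    reverse_filter,
    step2_instruments,
)
from medmr.mr import Z95
from medmr.synthetic import ChainSpec, simulate_chain

from conftest import make_trait, make_variant


class TestDecompose:
    def test_zero_beta2_means_no_mediation(self):
        r = decompose(0.3, 0.05, 0.0, 0.05, 0.4, 0.05)
        assert r.mediated_effect == 0.0
        assert r.direct_effect == 0.4

    def test_product_and_proportion_arithmetic(self):
        """Consistency fixture: b1=0.3, b2=0.19, total=0.396 give a mediated
        effect of 0.057 and a proportion of 14.4% (3 s.f.)."""
        r = decompose(0.3, 0.01, 0.19, 0.01, 0.396, 0.02)
        assert r.mediated_effect == pytest.approx(0.057)
        assert float(f"{100 * r.proportion:.3g}") == 14.4

    def test_exact_decomposition_identity(self, rng):
        for _ in range(100):
            b1, b2, bt = rng.normal(0, 0.5, 3)
            r = decompose(b1, 0.05, b2, 0.05, bt, 0.05)
            # exact in real arithmetic; one rounding of bt - b1*b2 in floats
            assert r.direct_effect + r.mediated_effect == pytest.approx(bt, abs=1e-15)
            assert r.mediated_effect == b1 * b2
            assert np.sign(r.mediated_effect) == np.sign(b1) * np.sign(b2)

    def test_sobel_se_formula(self):
        r = decompose(0.3, 0.04, 0.2, 0.05, 0.5, 0.05)
        assert r.mediated_se == pytest.approx(np.sqrt(0.3**2 * 0.05**2 + 0.2**2 * 0.04**2))
        assert r.mediated_ci_low == pytest.approx(r.mediated_effect - Z95 * r.mediated_se)

    def test_proportion_scale_invariance(self):
        r1 = decompose(0.3, 0.02, 0.19, 0.02, 0.396, 0.02)
        c = 2.5
        r2 = decompose(0.3 * c, 0.02, 0.19, 0.02, 0.396 * c, 0.02)
        # rescaling one mediator leg and the total by c leaves the proportion fixed
        assert r2.proportion == pytest.approx(r1.proportion)

    def test_zero_total_flags_undefined_proportion(self):
        r = decompose(0.3, 0.05, 0.2, 0.05, 0.0, 0.05)
        assert r.proportion is None

    def test_weak_total_flags_unreliable_ci(self):
        r = decompose(0.3, 0.01, 0.2, 0.01, 0.1, 0.05)
        assert r.proportion_ci_unreliable

    def test_bootstrap_deterministic_under_seed(self):
        a = decompose(0.3, 0.05, 0.2, 0.05, 0.4, 0.05, ci_method="bootstrap", seed=7)
        b = decompose(0.3, 0.05, 0.2, 0.05, 0.4, 0.05, ci_method="bootstrap", seed=7)
        assert (a.mediated_ci_low, a.mediated_ci_high) == (b.mediated_ci_low, b.mediated_ci_high)
        assert a.mediated_ci_low < a.mediated_effect < a.mediated_ci_high

    def test_delta_ci_coverage_on_random_triples(self, rng):
        """Delta CI covers the true product ~95% of the time when the
        component z-statistics are comfortably away from zero."""
        hits = 0
        n = 2000
        for _ in range(n):
            b1t, b2t = 0.5, 0.4
            se1, se2 = 0.05, 0.05
            b1 = rng.normal(b1t, se1)
            b2 = rng.normal(b2t, se2)
            r = decompose(b1, se1, b2, se2, b1t * b2t + 0.2, 0.05)
            hits += r.mediated_ci_low <= b1t * b2t <= r.mediated_ci_high
        assert 0.93 <= hits / n <= 0.97


def _chain_cfg():
    return ScreenConfig()


class TestScreens:
    def test_zero_instrument_exposure_skipped(self, identity_ld):
        empty = make_trait([make_variant(pval=0.9)], "null_exposure")
        out = make_trait([make_variant(pval=0.9)], "outcome")
        (sr,) = forward_screen([empty], out, identity_ld(["rs1"]), _chain_cfg())
        assert sr.skip_reason is not None and not sr.passes_forward

    def test_strong_effect_passes_forward(self):
        spec = ChainSpec(n_individuals=6000, m_snps=40, n_ld_blocks=20, seed=11)
        exp, _, out, ld, _ = simulate_chain(spec)
        (sr,) = forward_screen([exp], out, ld, _chain_cfg())
        assert sr.passes_forward and sr.forward.pval < 1e-6

    def test_reverse_filter_keeps_unidirectional_chain(self):
        hits = 0
        reps = 12
        for seed in range(reps):
            spec = ChainSpec(n_individuals=6000, m_snps=60, n_ld_blocks=30,
                             beta_direct=0.1, beta1=0.25, beta2=0.2, seed=seed)
            exp, _, out, ld, _ = simulate_chain(spec)
            scr = forward_screen([exp], out, ld, _chain_cfg())
            scr = reverse_filter(scr, [exp], out, ld, _chain_cfg())
            hits += scr[0].passes_reverse
        assert hits >= 0.9 * reps

    def test_reverse_filter_rejects_feedback_chain(self):
        hits = 0
        reps = 12
        for seed in range(reps):
            spec = ChainSpec(n_individuals=6000, m_snps=60, n_ld_blocks=30,
                             beta_direct=0.1, beta1=0.25, beta2=0.2,
                             reverse_beta=0.25, seed=100 + seed)
            exp, _, out, ld, _ = simulate_chain(spec)
            scr = forward_screen([exp], out, ld, _chain_cfg())
            scr[0].passes_forward = True  # isolate the reverse test
            scr = reverse_filter(scr, [exp], out, ld, _chain_cfg())
            hits += not scr[0].passes_reverse
        assert hits >= 0.9 * reps

    def test_reverse_filter_noop_without_forward_passes(self, identity_ld):
        empty = make_trait([make_variant(pval=0.9)], "null_exposure")
        out = make_trait([make_variant(pval=0.9)], "outcome")
        scr = forward_screen([empty], out, identity_ld(["rs1"]), _chain_cfg())
        before = [vars(s).copy() for s in scr]
        after = reverse_filter(scr, [empty], out, identity_ld(["rs1"]), _chain_cfg())
        assert [vars(s) for s in after] == before


class TestStep2Instruments:
    def _traits(self):
        med = make_trait([
            make_variant(vid="rs1", pos=1000, pval=1e-9),
            make_variant(vid="rs2", pos=2000, pval=1e-8),
            make_variant(vid="rs3", chrom="2", pos=1000, pval=1e-8),
        ], "mediator")
        return med

    def test_disjoint_sets_unchanged(self):
        med = self._traits()
        ld = LDMatrix.identity(["rs1", "rs2", "rs3", "rs9"])
        step1 = InstrumentSet("microbe", [(make_variant(vid="rs9", chrom="3", pos=500), 0.01, 25.0)])
        out = step2_instruments(med, step1, ld, ScreenConfig(clump_r2=0.5))
        assert set(out.variant_ids()) == {"rs1", "rs2", "rs3"}

    def test_shared_id_removed(self):
        med = self._traits()
        ld = LDMatrix.identity(["rs1", "rs2", "rs3"])
        step1 = InstrumentSet("microbe", [(make_variant(vid="rs1", pos=1000), 0.01, 25.0)])
        out = step2_instruments(med, step1, ld, ScreenConfig(clump_r2=0.5))
        assert "rs1" not in out.variant_ids()

    def test_ld_linked_removed_matches_bruteforce(self, rng):
        """Random LD overlap: result equals an explicit exclusion oracle."""
        for rep in range(20):
            ids = [f"rs{j}" for j in range(1, 9)]
            a = rng.uniform(0, 1, (8, 8))
            r2 = np.clip((a + a.T) / 2, 0, 1) * (rng.random((8, 8)) < 0.5)
            r2 = np.clip((r2 + r2.T) / 2, 0, 1)
            np.fill_diagonal(r2, 1.0)
            ld = LDMatrix(ids, r2)
            med = make_trait(
                [make_variant(vid=i, pos=1000 * k, pval=1e-9) for k, i in enumerate(ids[:5])],
                "mediator",
            )
            step1 = InstrumentSet("microbe", [
                (make_variant(vid=i, pos=1000 * (5 + k)), 0.01, 25.0) for k, i in enumerate(ids[5:])
            ])
            cfg = ScreenConfig(clump_r2=0.3, window_kb=10000)
            got = set(step2_instruments(med, step1, ld, cfg).variant_ids())
            base = select_instruments(med, ld, cfg.p_max, cfg.clump_r2, cfg.window_kb, cfg.f_min)
            want = set()
            for v in base.records():
                conflict = any(
                    s.chrom == v.chrom
                    and abs(s.pos - v.pos) <= cfg.window_kb * 1000
                    and ld.get(v.variant_id, s.variant_id, default=0.0) >= cfg.clump_r2
                    for s in step1.records()
                ) or v.variant_id in set(step1.variant_ids())
                if not conflict:
                    want.add(v.variant_id)
            assert got == want


class TestMediationScan:
    def test_empty_mediator_list_empty_result(self):
        spec = ChainSpec(n_individuals=4000, m_snps=30, n_ld_blocks=10, seed=5)
        exp, _, out, ld, _ = simulate_chain(spec)
        res, skips = mediation_scan([exp], [], out, ld)
        assert res == [] and skips == []

    def test_planted_chain_recovers_proportion(self):
        spec = ChainSpec(seed=42)  # defaults: b1=0.3, b2=0.19, direct=0.34
        exp, med, out, ld, truth = simulate_chain(spec)
        res, _ = mediation_scan([exp], [med], out, ld)
        assert len(res) == 1
        r = res[0]
        assert r.significant
        assert r.proportion == pytest.approx(truth.proportion, abs=0.05)
        assert r.mediated_effect == pytest.approx(truth.beta1 * truth.beta2, abs=0.03)

    def test_no_mediation_chain_rarely_flags(self):
        flags = 0
        reps = 20
        for seed in range(reps):
            spec = ChainSpec(n_individuals=4000, m_snps=40, n_ld_blocks=20,
                             beta1=0.0, beta2=0.0, beta_direct=0.3, seed=500 + seed)
            exp, med, out, ld, _ = simulate_chain(spec)
            res, _ = mediation_scan([exp], [med], out, ld)
            flags += any(r.significant for r in res)
        assert flags <= 4  # ~5% nominal rate; legs also gate at p<0.05
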