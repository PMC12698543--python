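"""Two-step mediation MR: screen, bidirectionality filter, decomposition.

The causal chain is microbe (exposure) -> metabolite (mediator) -> disease
(outcome).  The procedure:

1. Forward screen: IVW microbe->outcome at alpha 0.05, retained only when
   the sensitivity diagnostics are clean (Egger-intercept p > 0.05 and
   Cochran-Q p > 0.05).
2. Reverse filter: MR with the disease as exposure and the microbe as
   outcome; microbes with reverse p < 0.05 (evidence of bidirectional
   causation) are excluded from mediation.
3. Two-step mediation: beta1 = IVW(microbe -> mediator); beta2 =
   IVW(mediator -> outcome) on mediator instruments purged of anything
   identical to, or in LD with, the step-1 instruments; beta_total =
   IVW(microbe -> outcome) on the full microbe instrument set.
4. Decomposition uses the product-of-coefficients convention: mediated
   effect = beta1 * beta2, direct effect = beta_total - mediated, proportion
   mediated = mediated / beta_total (may be negative; never truncated).
   The mediated-effect SE is first-order delta (Sobel); a percentile
   bootstrap over independent normal draws of (beta1, beta2, beta_total) is
   available as an alternative CI.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import InsufficientInstrumentsError
from .gwas_io import TraitSummary, harmonize, kept_pairs
from .instruments import InstrumentSet, LDMatrix, select_instruments
from .mr import Z95, MRAnalysisResult, MREstimate, SensitivityReport, mr_analysis

logger = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    """Thresholds for instrument selection and the screening funnel."""

    p_max: float = 1e-5
    clump_r2: float = 0.001
    window_kb: float = 10000.0
    f_min: float = 10.0
    palindrome_eaf_limit: float = 0.42
    ivw_model: str = "multiplicative_random"
    alpha_forward: float = 0.05
    alpha_pleiotropy: float = 0.05
    alpha_heterogeneity: float = 0.05
    alpha_reverse: float = 0.05
    alpha_mediator: float = 0.05
    ci_method: str = "delta"  # delta | bootstrap
    n_boot: int = 10000

    def mr_kwargs(self) -> dict:
        return dict(
            p_max=self.p_max,
            clump_r2=self.clump_r2,
            window_kb=self.window_kb,
            f_min=self.f_min,
            palindrome_eaf_limit=self.palindrome_eaf_limit,
            ivw_model=self.ivw_model,
        )


@dataclass
class ScreenResult:
    """Forward (and optionally reverse) MR verdict for one exposure."""

    exposure_id: str
    outcome_id: str
    forward: MREstimate | None
    sensitivity: SensitivityReport | None
    reverse: MREstimate | None = None
    passes_forward: bool = False
    passes_reverse: bool = True  # true until a reverse test says otherwise
    skip_reason: str | None = None

    @property
    def is_mediation_candidate(self) -> bool:
        return self.passes_forward and self.passes_reverse


def _passes_forward(est: MREstimate, sens: SensitivityReport, cfg: ScreenConfig) -> bool:
    """Forward significance with clean diagnostics.

    A diagnostic that cannot be computed (too few instruments) cannot
    reject, so it does not veto the pass.
    """
    if est.pval >= cfg.alpha_forward:
        return False
    if sens.egger_intercept_pval is not None and sens.egger_intercept_pval <= cfg.alpha_pleiotropy:
        return False
    if sens.q_pval_ivw is not None and sens.q_pval_ivw <= cfg.alpha_heterogeneity:
        return False
    return True


def forward_screen(
    exposures: list[TraitSummary],
    outcome: TraitSummary,
    ld: LDMatrix,
    config: ScreenConfig | None = None,
) -> list[ScreenResult]:
    """Run exposure->outcome MR for every exposure and set pass flags."""
    cfg = config or ScreenConfig()
    out: list[ScreenResult] = []
    for exp in exposures:
        res: MRAnalysisResult = mr_analysis(exp, outcome, ld, **cfg.mr_kwargs())
        if res.skipped:
            out.append(
                ScreenResult(exp.trait_id, outcome.trait_id, None, None, skip_reason=res.skip_reason)
            )
            logger.info("screen %s -> %s skipped: %s", exp.trait_id, outcome.trait_id, res.skip_reason)
            continue
        est = res.results.primary
        sens = res.results.sensitivity
        sr = ScreenResult(exp.trait_id, outcome.trait_id, est, sens)
        sr.passes_forward = _passes_forward(est, sens, cfg)
        out.append(sr)
    return out


def reverse_filter(
    screen: list[ScreenResult],
    exposures: list[TraitSummary],
    outcome_as_exposure: TraitSummary,
    ld: LDMatrix,
    config: ScreenConfig | None = None,
) -> list[ScreenResult]:
    """Reverse-MR each forward-passing exposure; flag bidirectional ones.

    The outcome trait (full summary statistics) plays the exposure role and
    each microbe the outcome role.  ``passes_reverse`` is true when the
    reverse estimate is non-significant (p >= alpha_reverse) or could not be
    computed (no reverse instruments reach the microbe's panel).
    """
    cfg = config or ScreenConfig()
    by_id = {t.trait_id: t for t in exposures}
    for sr in screen:
        if not sr.passes_forward:
            continue
        microbe = by_id.get(sr.exposure_id)
        if microbe is None:
            continue
        res = mr_analysis(outcome_as_exposure, microbe, ld, **cfg.mr_kwargs())
        if res.skipped:
            sr.reverse = None
            sr.passes_reverse = True
            continue
        sr.reverse = res.results.primary
        sr.passes_reverse = sr.reverse.pval >= cfg.alpha_reverse
    return screen


def step2_instruments(
    mediator: TraitSummary,
    step1: InstrumentSet,
    ld: LDMatrix,
    config: ScreenConfig | None = None,
) -> InstrumentSet:
    """Mediator instruments purged of anything correlated with step 1.

    A mediator SNP is removed when it (a) shares a variant_id with a step-1
    instrument, or (b) lies within the clump window of one on the same
    chromosome with LD r^2 >= clump_r2 (pairs absent from the LD matrix are
    treated as unlinked here, since the two instrument panels may come from
    different sources).
    """
    cfg = config or ScreenConfig()
    sel = select_instruments(
        mediator, ld, p_max=cfg.p_max, clump_r2=cfg.clump_r2, window_kb=cfg.window_kb, f_min=cfg.f_min
    )
    step1_ids = set(step1.variant_ids())
    step1_recs = step1.records()
    window_bp = cfg.window_kb * 1000.0
    out = InstrumentSet(
        exposure_id=mediator.trait_id,
        p_max=cfg.p_max,
        clump_r2=cfg.clump_r2,
        clump_window_kb=cfg.window_kb,
        f_min=cfg.f_min,
    )
    for v, r2x, f in sel.snps:
        if v.variant_id in step1_ids:
            continue
        linked = False
        for s in step1_recs:
            if s.chrom != v.chrom or abs(s.pos - v.pos) > window_bp:
                continue
            r2 = ld.get(v.variant_id, s.variant_id, default=0.0)
            if r2 >= cfg.clump_r2:
                linked = True
                break
        if not linked:
            out.snps.append((v, r2x, f))
    if not out.snps:
        logger.warning("mediator %s: no instruments left after step-1 exclusion", mediator.trait_id)
    return out


@dataclass
class MediationResult:
    """One microbe -> mediator -> outcome decomposition (a results row).

    Exact identities: ``mediated_effect = beta1 * beta2`` and
    ``direct_effect + mediated_effect = beta_total``.  ``proportion`` may be
    negative and is ``None`` when the total effect is zero.
    """

    microbe_id: str
    mediator_id: str
    outcome_id: str
    beta1: float
    se1: float
    beta2: float
    se2: float
    beta_total: float
    se_total: float
    mediated_effect: float = field(init=False)
    mediated_se: float = 0.0
    mediated_ci_low: float = 0.0
    mediated_ci_high: float = 0.0
    mediated_pval: float = 1.0
    direct_effect: float = field(init=False)
    proportion: float | None = field(init=False)
    proportion_ci_low: float | None = None
    proportion_ci_high: float | None = None
    ci_method: str = "delta"
    proportion_ci_unreliable: bool = False
    significant: bool = False
    n_snp1: int = 0
    n_snp2: int = 0
    n_snp_total: int = 0

    def __post_init__(self):
        self.mediated_effect = self.beta1 * self.beta2
        self.direct_effect = self.beta_total - self.mediated_effect
        self.proportion = self.mediated_effect / self.beta_total if self.beta_total != 0 else None

    def summary(self) -> str:
        prop = "undefined" if self.proportion is None else (
            f"{100 * self.proportion:.1f}% ({100 * self.proportion_ci_low:.2f}%, "
            f"{100 * self.proportion_ci_high:.2f}%)"
        )
        return (
            f"Mediation {self.microbe_id} -> {self.mediator_id} -> {self.outcome_id}\n"
            f"  beta1 (microbe->mediator): {self.beta1:.4f} (se {self.se1:.4f})\n"
            f"  beta2 (mediator->outcome): {self.beta2:.4f} (se {self.se2:.4f})\n"
            f"  beta_total:                {self.beta_total:.4f} (se {self.se_total:.4f})\n"
            f"  mediated effect:           {self.mediated_effect:.4f} "
            f"({self.mediated_ci_low:.4f}, {self.mediated_ci_high:.4f}), p = {self.mediated_pval:.3g}\n"
            f"  direct effect:             {self.direct_effect:.4f}\n"
            f"  proportion mediated:       {prop}  [{self.ci_method} CI]"
        )


def decompose(
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
    beta_total: float,
    se_total: float,
    ci_method: str = "delta",
    n_boot: int = 10000,
    seed: int | None = None,
    microbe_id: str = "microbe",
    mediator_id: str = "mediator",
    outcome_id: str = "outcome",
) -> MediationResult:
    """Product-of-coefficients decomposition with delta or bootstrap CIs.

    Delta method: se(beta1*beta2) = sqrt(beta1^2 se2^2 + beta2^2 se1^2)
    (Sobel); the proportion CI treats the product and the total as
    independent.  The bootstrap draws (beta1, beta2, beta_total) from
    independent normals and takes percentile intervals; the mediated p-value
    is always the Sobel normal test so that significance is deterministic.
    """
    res = MediationResult(
        microbe_id, mediator_id, outcome_id, beta1, se1, beta2, se2, beta_total, se_total,
        ci_method=ci_method,
    )
    med = res.mediated_effect
    med_se = math.sqrt(beta1**2 * se2**2 + beta2**2 * se1**2)
    res.mediated_se = med_se
    res.mediated_pval = float(2.0 * stats.norm.sf(abs(med / med_se))) if med_se > 0 else 1.0

    if ci_method == "delta":
        res.mediated_ci_low = med - Z95 * med_se
        res.mediated_ci_high = med + Z95 * med_se
        if beta_total != 0:
            t2 = beta_total**2
            # t2**2 can underflow to zero for near-denormal totals; treat
            # such totals as effectively zero for the CI and flag them.
            if t2 > 0 and t2**2 > 0:
                var_prop = med_se**2 / t2 + med**2 * se_total**2 / t2**2
                sp = math.sqrt(var_prop) if math.isfinite(var_prop) else math.inf
                res.proportion_ci_low = res.proportion - Z95 * sp
                res.proportion_ci_high = res.proportion + Z95 * sp
            else:
                res.proportion_ci_unreliable = True
            if abs(beta_total) < 10 * se_total:
                res.proportion_ci_unreliable = True
                logger.warning(
                    "%s->%s->%s: |beta_total| < 10*se_total; delta-method proportion CI unreliable",
                    microbe_id, mediator_id, outcome_id,
                )
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        b1 = rng.normal(beta1, se1, n_boot)
        b2 = rng.normal(beta2, se2, n_boot)
        bt = rng.normal(beta_total, se_total, n_boot)
        meds = b1 * b2
        res.mediated_ci_low, res.mediated_ci_high = np.percentile(meds, [2.5, 97.5])
        props = meds / bt
        res.proportion_ci_low, res.proportion_ci_high = np.percentile(props, [2.5, 97.5])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    res.significant = res.mediated_pval < 0.05
    return res


@dataclass
class MediationSkip:
    microbe_id: str
    mediator_id: str
    reason: str


def mediation_scan(
    microbes: list[TraitSummary],
    mediators: list[TraitSummary],
    outcome: TraitSummary,
    ld: LDMatrix,
    config: ScreenConfig | None = None,
    seed: int | None = None,
) -> tuple[list[MediationResult], list[MediationSkip]]:
    """Two-step mediation over every (microbe, mediator) combination.

    Callers pass microbes that already survived the forward and reverse
    screens and mediators already associated with the same outcome.  Rows
    with any zero-instrument leg, or a non-significant microbe->mediator
    step (p >= alpha_mediator), are skipped with a reason.
    """
    cfg = config or ScreenConfig()
    results: list[MediationResult] = []
    skips: list[MediationSkip] = []
    for microbe in microbes:
        step1 = select_instruments(
            microbe, ld, p_max=cfg.p_max, clump_r2=cfg.clump_r2, window_kb=cfg.window_kb, f_min=cfg.f_min
        )
        if len(step1) == 0:
            for mediator in mediators:
                skips.append(MediationSkip(microbe.trait_id, mediator.trait_id, "no microbe instruments"))
            continue
        sub = TraitSummary(microbe.trait_id, microbe.trait_label, microbe.trait_type, microbe.source)
        for v in step1.records():
            sub.records[v.variant_id] = v

        # beta_total: microbe -> outcome on the full step-1 instrument set.
        total_pairs = kept_pairs(harmonize(sub, outcome, cfg.palindrome_eaf_limit))
        if not total_pairs:
            for mediator in mediators:
                skips.append(MediationSkip(microbe.trait_id, mediator.trait_id, "no total-effect instruments"))
            continue
        from .mr import MRModel

        total_fit = MRModel(total_pairs, microbe.trait_id, outcome.trait_id).fit(ivw_model=cfg.ivw_model)
        est_total = total_fit.primary

        for mediator in mediators:
            # Step 1: microbe -> mediator.
            pairs1 = kept_pairs(harmonize(sub, mediator, cfg.palindrome_eaf_limit))
            if not pairs1:
                skips.append(MediationSkip(microbe.trait_id, mediator.trait_id, "no step-1 instruments"))
                continue
            est1 = MRModel(pairs1, microbe.trait_id, mediator.trait_id).fit(ivw_model=cfg.ivw_model).primary
            if est1.pval >= cfg.alpha_mediator:
                skips.append(
                    MediationSkip(microbe.trait_id, mediator.trait_id, "microbe->mediator not significant")
                )
                continue
            # Step 2: mediator -> outcome on purged instruments.
            step2 = step2_instruments(mediator, step1, ld, cfg)
            if len(step2) == 0:
                skips.append(MediationSkip(microbe.trait_id, mediator.trait_id, "no step-2 instruments"))
                continue
            sub2 = TraitSummary(mediator.trait_id, mediator.trait_label, mediator.trait_type, mediator.source)
            for v in step2.records():
                sub2.records[v.variant_id] = v
            pairs2 = kept_pairs(harmonize(sub2, outcome, cfg.palindrome_eaf_limit))
            if not pairs2:
                skips.append(MediationSkip(microbe.trait_id, mediator.trait_id, "no harmonized step-2 instruments"))
                continue
            est2 = MRModel(pairs2, mediator.trait_id, outcome.trait_id).fit(ivw_model=cfg.ivw_model).primary

            res = decompose(
                est1.beta, est1.se, est2.beta, est2.se, est_total.beta, est_total.se,
                ci_method=cfg.ci_method, n_boot=cfg.n_boot, seed=seed,
                microbe_id=microbe.trait_id, mediator_id=mediator.trait_id, outcome_id=outcome.trait_id,
            )
            res.n_snp1 = est1.n_snp
            res.n_snp2 = est2.n_snp
            res.n_snp_total = est_total.n_snp
            results.append(res)
    return results, skips
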