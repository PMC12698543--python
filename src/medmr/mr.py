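"""Two-sample MR estimators on harmonized instrument-level data.

Implements the Wald ratio, inverse-variance-weighted (IVW) regression,
MR-Egger regression, Cochran's Q heterogeneity and the Egger-intercept
pleiotropy test, plus odds-ratio reporting for binary outcomes.

The IVW estimate is the zero-intercept weighted regression of outcome betas
on exposure betas with weights 1/se_out^2,

    beta_IVW = sum(w bx by) / sum(w bx^2),

with a fixed-effect SE 1/sqrt(sum(w bx^2)) or, by default, a multiplicative
random-effects SE scaled by max(1, sqrt(Q/(k-1))) — robust to mild
heterogeneity and identical to fixed effects when Q <= df.  IVW p-values use
the normal distribution.  MR-Egger fits a free intercept after orienting
every instrument to a non-negative exposure beta; its slope and intercept
are tested with plain weighted-least-squares t statistics on k - 2 degrees
of freedom (residual scale estimated, not floored), which is exactly
calibrated under the null.

Model-object entry point: ``MRModel(pairs).fit()`` returns an
:class:`MRResults` carrying every applicable estimate, the sensitivity
report and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateDesignError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
)
from .gwas_io import HarmonizedPair, TraitSummary, harmonize, kept_pairs
from .instruments import LDMatrix, select_instruments

#: 95% two-sided normal multiplier used for all reported confidence bounds.
Z95 = 1.959964


@dataclass
class MREstimate:
    """One exposure->outcome causal estimate.

    ``beta`` is on the outcome scale (log-OR for binary outcomes); ``or_``
    and the CI bounds are exp-transformed with the fixed 1.959964 multiplier.
    """

    method: str  # wald | ivw | egger
    beta: float
    se: float
    pval: float
    n_snp: int
    or_: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self):
        self.or_ = math.exp(self.beta)
        self.ci_low = math.exp(self.beta - Z95 * self.se)
        self.ci_high = math.exp(self.beta + Z95 * self.se)


@dataclass
class EggerFit:
    """MR-Egger slope estimate plus the intercept (pleiotropy) test."""

    estimate: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float

    def __iter__(self):
        return iter((self.estimate, self.intercept, self.intercept_se, self.intercept_pval))


@dataclass
class SensitivityReport:
    """Heterogeneity (Cochran's Q, IVW and Egger) and pleiotropy diagnostics."""

    q_ivw: float | None = None
    q_df_ivw: int | None = None
    q_pval_ivw: float | None = None
    q_egger: float | None = None
    q_df_egger: int | None = None
    q_pval_egger: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None


def _arrays(pairs: Sequence[HarmonizedPair]):
    pairs = kept_pairs(pairs)
    bx = np.array([p.beta_exp for p in pairs], dtype=float)
    by = np.array([p.beta_out for p in pairs], dtype=float)
    sx = np.array([p.se_exp for p in pairs], dtype=float)
    sy = np.array([p.se_out for p in pairs], dtype=float)
    return bx, by, sx, sy


def wald_ratio(pair: HarmonizedPair) -> MREstimate:
    """Single-instrument ratio estimate beta_out/beta_exp.

    First-order SE se_out/|beta_exp|; the exposure-side uncertainty is
    ignored, which is accurate when se_exp/|beta_exp| is small.
    """
    if pair.beta_exp == 0:
        raise UndefinedRatioError(f"{pair.variant_id}: beta_exp = 0, Wald ratio undefined")
    beta = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    pval = 2.0 * stats.norm.sf(abs(beta / se))
    return MREstimate(method="wald", beta=beta, se=se, pval=float(pval), n_snp=1)


def ivw(pairs: Sequence[HarmonizedPair], model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate over >= 2 instruments.

    ``model`` is ``fixed`` or ``multiplicative_random`` (SE scale floored at
    1, so it never beats fixed effects).  One instrument delegates to
    :func:`wald_ratio`.
    """
    kept = kept_pairs(pairs)
    if len(kept) == 1:
        return wald_ratio(kept[0])
    if len(kept) == 0:
        raise InsufficientInstrumentsError("IVW needs at least one instrument")
    bx, by, _, sy = _arrays(kept)
    if np.all(bx == 0):
        raise DegenerateDesignError("all exposure betas are zero")
    w = 1.0 / sy**2
    swx2 = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by) / swx2)
    se = swx2**-0.5
    k = len(kept)
    if model == "multiplicative_random":
        q = float(np.sum(w * (by - beta * bx) ** 2))
        se *= max(1.0, math.sqrt(q / (k - 1)))
    elif model != "fixed":
        raise ValueError(f"unknown IVW model {model!r}")
    pval = 2.0 * stats.norm.sf(abs(beta / se))
    return MREstimate(method="ivw", beta=beta, se=se, pval=float(pval), n_snp=k)


def egger(pairs: Sequence[HarmonizedPair]) -> EggerFit:
    """MR-Egger weighted regression with a free intercept.

    Instruments are first oriented so every exposure beta is non-negative
    (the InSIDE convention, making the intercept the average directional
    pleiotropy).  Slope and intercept are tested against t with k - 2 df.
    """
    kept = kept_pairs(pairs)
    k = len(kept)
    if k < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 instruments, got {k}")
    bx, by, _, sy = _arrays(kept)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx = bx * sign
    by = by * sign
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    # Weighted least squares via the normal equations on sqrt(w)-scaled data.
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = by * sw
    xtx = Xw.T @ Xw
    coef = np.linalg.solve(xtx, Xw.T @ yw)
    resid = yw - Xw @ coef
    df = k - 2
    sigma2 = float(resid @ resid) / df
    cov = np.linalg.inv(xtx) * sigma2
    intercept, slope = coef
    se_int, se_slope = np.sqrt(np.diag(cov))
    p_slope = 2.0 * stats.t.sf(abs(slope / se_slope), df)
    p_int = 2.0 * stats.t.sf(abs(intercept / se_int), df)
    est = MREstimate(method="egger", beta=float(slope), se=float(se_slope), pval=float(p_slope), n_snp=k)
    return EggerFit(est, float(intercept), float(se_int), float(p_int))


def cochran_q(pairs: Sequence[HarmonizedPair], fit: MREstimate | EggerFit) -> tuple[float, int, float]:
    """Cochran's Q around a fitted causal line.

    Q = sum w_j (by_j - fitted_j)^2 with w_j = 1/se_out_j^2; df = k - 1 for
    zero-intercept fits (wald/ivw) and k - 2 for Egger; p from the
    chi-square upper tail.
    """
    kept = kept_pairs(pairs)
    bx, by, _, sy = _arrays(kept)
    w = 1.0 / sy**2
    if isinstance(fit, EggerFit):
        sign = np.where(bx < 0, -1.0, 1.0)
        fitted = (fit.intercept + fit.estimate.beta * (bx * sign)) * sign
        df = len(kept) - 2
    else:
        fitted = fit.beta * bx
        df = len(kept) - 1
    q = float(np.sum(w * (by - fitted) ** 2))
    pval = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    return q, df, pval


def sensitivity_report(pairs: Sequence[HarmonizedPair], ivw_fit: MREstimate | None = None) -> SensitivityReport:
    """Q (IVW and Egger) and Egger-intercept diagnostics for one instrument set."""
    rep = SensitivityReport()
    kept = kept_pairs(pairs)
    if len(kept) >= 2:
        fit = ivw_fit if ivw_fit is not None else ivw(kept)
        rep.q_ivw, rep.q_df_ivw, rep.q_pval_ivw = cochran_q(kept, fit)
    if len(kept) >= 3:
        efit = egger(kept)
        rep.q_egger, rep.q_df_egger, rep.q_pval_egger = cochran_q(kept, efit)
        rep.egger_intercept = efit.intercept
        rep.egger_intercept_se = efit.intercept_se
        rep.egger_intercept_pval = efit.intercept_pval
    return rep


class MRModel:
    """Instrument-level two-sample MR model.

    Parameters
    ----------
    pairs : sequence of HarmonizedPair
        Harmonized exposure/outcome estimates; dropped pairs are ignored.
    exposure_id, outcome_id : str, optional
        Labels carried into results and summaries.
    """

    def __init__(self, pairs: Iterable[HarmonizedPair], exposure_id: str = "exposure", outcome_id: str = "outcome"):
        self.pairs = kept_pairs(list(pairs))
        self.exposure_id = exposure_id
        self.outcome_id = outcome_id

    @classmethod
    def from_traits(
        cls,
        exposure: TraitSummary,
        outcome: TraitSummary,
        ld: LDMatrix,
        p_max: float = 1e-5,
        clump_r2: float = 0.001,
        window_kb: float = 10000.0,
        f_min: float = 10.0,
        palindrome_eaf_limit: float = 0.42,
    ) -> "MRModel":
        """Select instruments on the exposure, harmonize against the outcome."""
        iv = select_instruments(exposure, ld, p_max=p_max, clump_r2=clump_r2, window_kb=window_kb, f_min=f_min)
        sub = TraitSummary(exposure.trait_id, exposure.trait_label, exposure.trait_type, exposure.source)
        for v in iv.records():
            sub.records[v.variant_id] = v
        pairs = harmonize(sub, outcome, palindrome_eaf_limit=palindrome_eaf_limit)
        return cls(pairs, exposure_id=exposure.trait_id, outcome_id=outcome.trait_id)

    @property
    def n_snp(self) -> int:
        return len(self.pairs)

    def fit(self, ivw_model: str = "multiplicative_random") -> "MRResults":
        """Compute all applicable estimators plus the sensitivity report."""
        if self.n_snp == 0:
            raise InsufficientInstrumentsError("no instruments after harmonization")
        estimates: dict[str, MREstimate] = {}
        egger_fit = None
        if self.n_snp == 1:
            estimates["wald"] = wald_ratio(self.pairs[0])
        else:
            estimates["ivw"] = ivw(self.pairs, model=ivw_model)
            if self.n_snp >= 3:
                egger_fit = egger(self.pairs)
                estimates["egger"] = egger_fit.estimate
        sens = sensitivity_report(self.pairs, ivw_fit=estimates.get("ivw"))
        return MRResults(self, estimates, sens, egger_fit)


class MRResults:
    """Fit results for an :class:`MRModel`: estimates, diagnostics, summary."""

    def __init__(self, model: MRModel, estimates: dict[str, MREstimate], sensitivity: SensitivityReport, egger_fit: EggerFit | None):
        self.model = model
        self.estimates = estimates
        self.sensitivity = sensitivity
        self.egger_fit = egger_fit

    @property
    def primary(self) -> MREstimate:
        """The headline estimate: IVW when available, else the Wald ratio."""
        return self.estimates.get("ivw") or self.estimates["wald"]

    def summary(self) -> str:
        lines = [
            f"MR results: {self.model.exposure_id} -> {self.model.outcome_id}  (n_snp = {self.model.n_snp})",
            f"{'method':<8}{'b':>10}{'se':>10}{'pval':>12}{'OR':>10}{'95% CI':>22}",
        ]
        for name, e in self.estimates.items():
            lines.append(
                f"{name:<8}{e.beta:>10.4f}{e.se:>10.4f}{e.pval:>12.3e}{e.or_:>10.4f}"
                f"{'(' + format(e.ci_low, '.4f') + ', ' + format(e.ci_high, '.4f') + ')':>22}"
            )
        s = self.sensitivity
        if s.q_ivw is not None:
            lines.append(f"Cochran Q (IVW):   {s.q_ivw:.3f} on {s.q_df_ivw} df, p = {s.q_pval_ivw:.3g}")
        if s.q_egger is not None:
            lines.append(f"Cochran Q (Egger): {s.q_egger:.3f} on {s.q_df_egger} df, p = {s.q_pval_egger:.3g}")
        if s.egger_intercept is not None:
            lines.append(
                f"Egger intercept:   {s.egger_intercept:.4f} (se {s.egger_intercept_se:.4f}), "
                f"p = {s.egger_intercept_pval:.3g}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of instrument effects with the fitted IVW/Egger lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        bx, by, sx, sy = _arrays(self.model.pairs)
        ax.errorbar(bx, by, xerr=Z95 * sx, yerr=Z95 * sy, fmt="o", ms=4, lw=0.8, alpha=0.7)
        xs = np.linspace(min(0.0, bx.min()), bx.max(), 50)
        if "ivw" in self.estimates:
            ax.plot(xs, self.estimates["ivw"].beta * xs, label="IVW")
        if self.egger_fit is not None:
            ax.plot(xs, self.egger_fit.intercept + self.egger_fit.estimate.beta * xs, "--", label="MR-Egger")
        ax.set_xlabel(f"SNP effect on {self.model.exposure_id}")
        ax.set_ylabel(f"SNP effect on {self.model.outcome_id}")
        ax.legend()
        return ax


@dataclass
class MRAnalysisResult:
    """Outcome of :func:`mr_analysis` on one exposure/outcome pair.

    Either ``results`` is set, or ``skip_reason`` explains why the pair
    produced no estimate (e.g. no surviving instruments).
    """

    exposure_id: str
    outcome_id: str
    results: MRResults | None = None
    skip_reason: str | None = None
    n_candidates: int = 0
    n_instruments: int = 0
    n_harmonized: int = 0

    @property
    def skipped(self) -> bool:
        return self.results is None


def mr_analysis(
    exposure: TraitSummary,
    outcome: TraitSummary,
    ld: LDMatrix,
    p_max: float = 1e-5,
    clump_r2: float = 0.001,
    window_kb: float = 10000.0,
    f_min: float = 10.0,
    palindrome_eaf_limit: float = 0.42,
    ivw_model: str = "multiplicative_random",
) -> MRAnalysisResult:
    """Full single-pair analysis: select instruments, harmonize, estimate.

    Never raises on an empty instrument set; the returned record carries the
    skip reason and the funnel counts at every stage instead.
    """
    iv = select_instruments(exposure, ld, p_max=p_max, clump_r2=clump_r2, window_kb=window_kb, f_min=f_min)
    out = MRAnalysisResult(exposure.trait_id, outcome.trait_id, n_candidates=len(exposure), n_instruments=len(iv))
    if len(iv) == 0:
        out.skip_reason = "no instruments survive selection"
        return out
    sub = TraitSummary(exposure.trait_id, exposure.trait_label, exposure.trait_type, exposure.source)
    for v in iv.records():
        sub.records[v.variant_id] = v
    pairs = kept_pairs(harmonize(sub, outcome, palindrome_eaf_limit=palindrome_eaf_limit))
    out.n_harmonized = len(pairs)
    if not pairs:
        out.skip_reason = "no instruments shared with outcome after harmonization"
        return out
    out.results = MRModel(pairs, exposure.trait_id, outcome.trait_id).fit(ivw_model=ivw_model)
    return out
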