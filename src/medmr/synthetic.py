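"""Synthetic inputs with known ground truth for the whole pipeline.

Two generators:

* :func:`simulate_chain` builds a genotype -> exposure -> mediator -> outcome
  causal chain and summarizes it to GWAS summary statistics.  Genotypes are
  Binomial(2, maf) with Gaussian-copula LD inside blocks (independent
  blocks), exposure and mediator each get their own causal SNPs, the
  outcome can be continuous or binary (per-SNP logistic fits on the log-OR
  scale, as in biobank case/control endpoints), and optional per-SNP direct
  pleiotropic effects.  Each trait's summary statistics come from its own
  independently drawn cohort, mirroring non-overlapping two-sample MR.

* :func:`simulate_paired_metabolome` emulates the clinical arm: a small
  paired pre/post abundance table with planted per-feature effects of known
  standardized size (log scale) and a seizure-control response whose rank
  correlation with the strongest feature's change is controlled.

Both are deterministic given their seed (bit-identical outputs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .exceptions import DomainError
from .gwas_io import TraitSummary, VariantAssociation
from .instruments import LDMatrix
from .prepost import PairedFeatureTable, SeizureOutcome

_BLOCK_SPACING_BP = 15_000_000  # adjacent blocks sit outside the 10 Mb clump window
_SNP_SPACING_BP = 5_000


@dataclass
class ChainSpec:
    """Parameters of one synthetic causal chain.

    ``beta1`` (exposure -> mediator), ``beta2`` (mediator -> outcome) and
    ``beta_direct`` (exposure -> outcome) act on unit-variance traits, so
    for a continuous outcome the true total effect is
    ``beta_direct + beta1*beta2`` and the true proportion mediated
    ``beta1*beta2 / total``.  Exposure, mediator and outcome causal SNPs
    live in disjoint LD blocks (fractions ``exposure_block_frac`` and
    ``mediator_block_frac`` of blocks carry the exposure and mediator
    signals; the remainder carry disease-specific loci with total
    heritability ``outcome_h2``, which is what gives reverse MR its own
    valid instruments).  ``reverse_beta`` routes the outcome's genetic
    liability back into the exposure, emulating disease -> microbe
    feedback for bidirectionality tests.
    """

    n_individuals: int = 20_000
    m_snps: int = 150
    n_ld_blocks: int = 30
    within_block_r: float = 0.3
    maf_range: tuple[float, float] = (0.1, 0.4)
    beta1: float = 0.3
    beta2: float = 0.19
    beta_direct: float = 0.34
    pleiotropy_sd: float = 0.0
    inside_violation: bool = False
    outcome_type: str = "continuous"  # continuous | binary
    prevalence: float = 0.05
    exposure_h2: float = 0.25
    mediator_h2: float = 0.25
    outcome_h2: float = 0.2
    exposure_block_frac: float = 0.4
    mediator_block_frac: float = 0.4
    reverse_beta: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.within_block_r < 1):
            raise DomainError("within_block_r must be in [0, 1)")
        if self.outcome_type not in ("continuous", "binary"):
            raise DomainError("outcome_type must be continuous|binary")
        if self.outcome_type == "binary" and not (0 < self.prevalence < 1):
            raise DomainError(f"infeasible prevalence {self.prevalence}")
        if self.n_ld_blocks > self.m_snps:
            raise DomainError("need at least one SNP per LD block")
        if not (0 < self.maf_range[0] <= self.maf_range[1] < 0.5 + 1e-12):
            raise DomainError("maf_range must satisfy 0 < lo <= hi <= 0.5")


@dataclass
class MetabolomeSpec:
    """Parameters of one synthetic paired pre/post metabolome.

    ``effect_sizes_dz`` are the planted standardized effects of the panel
    features on the log scale (log post/pre ~ Normal(dz*sigma, sigma) with
    sigma = ``feature_noise_sd``); ``response_coupling`` is the latent
    correlation between the top panel feature's change and the
    seizure-control response.
    """

    n_subjects: int = 9
    n_features: int = 200
    panel_size: int = 7
    effect_sizes_dz: tuple[float, ...] | None = None
    feature_noise_sd: float = 0.4
    baseline_log_sd: float = 0.6
    response_coupling: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.effect_sizes_dz is None:
            graded = (2.0, 1.6, 1.3, 1.1, 0.9, 0.7, 0.5)
            self.effect_sizes_dz = tuple(graded[i % len(graded)] for i in range(self.panel_size))
        if len(self.effect_sizes_dz) != self.panel_size:
            raise DomainError("effect_sizes_dz must have panel_size entries")
        if self.panel_size > self.n_features:
            raise DomainError("panel_size must be <= n_features")
        if not (-1 <= self.response_coupling <= 1):
            raise DomainError("response_coupling must lie in [-1, 1]")


@dataclass
class ChainTruth:
    """Ground truth carried alongside simulated summary statistics."""

    beta1: float
    beta2: float
    beta_direct: float
    total: float
    proportion: float | None
    exposure_snp_ids: list[str] = field(default_factory=list)
    mediator_snp_ids: list[str] = field(default_factory=list)
    outcome_snp_ids: list[str] = field(default_factory=list)
    reverse_beta: float = 0.0
    mafs: dict[str, float] = field(default_factory=dict)


def _block_sizes(m: int, n_blocks: int) -> list[int]:
    base = m // n_blocks
    sizes = [base] * n_blocks
    for i in range(m - base * n_blocks):
        sizes[i] += 1
    return sizes


def _draw_genotypes(rng, n: int, sizes: list[int], mafs: np.ndarray, r: float) -> np.ndarray:
    """Binomial(2, maf) genotypes with within-block Gaussian-copula LD."""
    cols = []
    start = 0
    sr = np.sqrt(r)
    so = np.sqrt(1.0 - r)
    for s in sizes:
        thr = stats.norm.ppf(mafs[start : start + s])  # (s,)
        g = np.zeros((n, s))
        for _ in range(2):  # two gametes
            common = rng.standard_normal((n, 1))
            z = sr * common + so * rng.standard_normal((n, s))
            g += z < thr
        cols.append(g)
        start += s
    return np.concatenate(cols, axis=1)


def _linear_sumstats(G: np.ndarray, y: np.ndarray):
    n, m = G.shape
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    ssg = (Gc**2).sum(axis=0)
    ssg = np.where(ssg == 0, np.nan, ssg)
    sxy = Gc.T @ yc
    beta = sxy / ssg
    ssy = float(yc @ yc)
    resid_var = np.maximum(ssy - beta * sxy, 0.0) / (n - 2)
    se = np.sqrt(resid_var / ssg)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pval = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return beta, se, pval


def _logistic_sumstats(G: np.ndarray, y: np.ndarray, max_iter: int = 25):
    """Per-SNP logistic regressions (intercept + genotype), vectorized IRLS."""
    n, m = G.shape
    b0 = np.full(m, float(np.log(y.mean() / (1 - y.mean()))))
    b1 = np.zeros(m)
    yv = y[:, None]
    for _ in range(max_iter):
        eta = b0[None, :] + G * b1[None, :]
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        r = yv - mu
        s0 = r.sum(axis=0)
        s1 = (r * G).sum(axis=0)
        i00 = w.sum(axis=0)
        i01 = (w * G).sum(axis=0)
        i11 = (w * G * G).sum(axis=0)
        det = i00 * i11 - i01**2
        det = np.where(det <= 0, np.nan, det)
        d0 = (i11 * s0 - i01 * s1) / det
        d1 = (i00 * s1 - i01 * s0) / det
        b0 += d0
        b1 += d1
        if np.nanmax(np.abs(np.concatenate([d0, d1]))) < 1e-10:
            break
    eta = b0[None, :] + G * b1[None, :]
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    i00 = w.sum(axis=0)
    i01 = (w * G).sum(axis=0)
    i11 = (w * G * G).sum(axis=0)
    det = i00 * i11 - i01**2
    se = np.sqrt(i00 / det)
    z = b1 / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    return b1, se, pval


def _to_trait(trait_id, label, trait_type, beta, se, pval, eaf, n, chroms, positions, ids, n_case=None, n_control=None) -> TraitSummary:
    ts = TraitSummary(trait_id, label, trait_type, source="synthetic")
    for j, vid in enumerate(ids):
        if not np.isfinite(beta[j]) or not np.isfinite(se[j]) or se[j] <= 0:
            continue
        ts.records[vid] = VariantAssociation(
            variant_id=vid,
            chrom=chroms[j],
            pos=int(positions[j]),
            effect_allele="A",
            other_allele="G",
            eaf=float(eaf[j]),
            beta=float(beta[j]),
            se=float(se[j]),
            pval=float(max(min(pval[j], 1.0), 5e-324)),
            n=int(n),
            n_case=n_case,
            n_control=n_control,
        )
    return ts


def simulate_chain(spec: ChainSpec) -> tuple[TraitSummary, TraitSummary, TraitSummary, LDMatrix, ChainTruth]:
    """Simulate one causal chain and summarize it as three GWAS.

    Returns (exposure, mediator, outcome) trait summaries, an empirical LD
    matrix from the exposure cohort, and the :class:`ChainTruth`.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_struct, rng_exp, rng_med, rng_out = (np.random.default_rng(s) for s in ss.spawn(4))

    m = spec.m_snps
    sizes = _block_sizes(m, spec.n_ld_blocks)
    mafs = rng_struct.uniform(spec.maf_range[0], spec.maf_range[1], size=m)
    ids = [f"rs{j + 1}" for j in range(m)]
    chroms = ["1"] * m
    positions = np.empty(m, dtype=int)
    block_of = np.empty(m, dtype=int)
    start = 0
    for b, s in enumerate(sizes):
        for k in range(s):
            positions[start + k] = 1 + b * _BLOCK_SPACING_BP + k * _SNP_SPACING_BP
            block_of[start + k] = b
        start += s

    nb = spec.n_ld_blocks
    n_exp_blocks = min(max(1, round(spec.exposure_block_frac * nb)), nb)
    n_med_blocks = min(max(0, round(spec.mediator_block_frac * nb)), nb - n_exp_blocks)
    block_starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    exp_idx = block_starts[:n_exp_blocks]
    med_idx = block_starts[n_exp_blocks : n_exp_blocks + n_med_blocks]
    out_idx = block_starts[n_exp_blocks + n_med_blocks :]

    var_g = 2.0 * mafs * (1.0 - mafs)
    a = np.zeros(m)
    if spec.exposure_h2 > 0 and len(exp_idx):
        a[exp_idx] = np.sqrt(spec.exposure_h2 / len(exp_idx) / var_g[exp_idx])
    c = np.zeros(m)
    if spec.mediator_h2 > 0 and len(med_idx):
        c[med_idx] = np.sqrt(spec.mediator_h2 / len(med_idx) / var_g[med_idx])
    e = np.zeros(m)
    if spec.outcome_h2 > 0 and len(out_idx):
        e[out_idx] = np.sqrt(spec.outcome_h2 / len(out_idx) / var_g[out_idx])
    d = np.zeros(m)
    if spec.pleiotropy_sd > 0:
        d = rng_struct.normal(0.0, spec.pleiotropy_sd, size=m)
        if spec.inside_violation:
            # Pleiotropy correlated with instrument strength breaks InSIDE.
            d += 0.5 * spec.pleiotropy_sd * a / max(a.max(), 1e-12)

    sd_x = np.sqrt(max(1.0 - spec.exposure_h2 - spec.reverse_beta**2 * spec.outcome_h2, 0.05))
    var_m_gen = spec.beta1**2 + spec.mediator_h2
    sd_m = np.sqrt(max(1.0 - var_m_gen, 0.05))
    cov_xm = spec.beta1
    var_y_gen = spec.beta_direct**2 + spec.beta2**2 + 2 * spec.beta_direct * spec.beta2 * cov_xm + spec.outcome_h2
    sd_y = np.sqrt(max(1.0 - var_y_gen, 0.05))

    def phenotypes(rng, n):
        G = _draw_genotypes(rng, n, sizes, mafs, spec.within_block_r)
        # Disease-specific genetic liability; with reverse_beta it feeds back
        # into the exposure (disease -> microbe), giving a bidirectional pair.
        liab = G @ e
        X = G @ a + spec.reverse_beta * liab + sd_x * rng.standard_normal(n)
        M = spec.beta1 * X + G @ c + sd_m * rng.standard_normal(n)
        eta = spec.beta_direct * X + spec.beta2 * M + G @ d + liab
        if spec.outcome_type == "binary":
            alpha = brentq(
                lambda al: (1.0 / (1.0 + np.exp(-(al + eta)))).mean() - spec.prevalence, -30, 30
            )
            p = 1.0 / (1.0 + np.exp(-(alpha + eta)))
            Y = (rng.random(n) < p).astype(float)
        else:
            Y = eta + sd_y * rng.standard_normal(n)
        return G, X, M, Y

    n = spec.n_individuals

    G_e, X_e, _, _ = phenotypes(rng_exp, n)
    beta, se, pval = _linear_sumstats(G_e, X_e)
    eaf_e = G_e.mean(axis=0) / 2.0
    exposure = _to_trait("microbe_sim", "simulated microbial taxon", "continuous", beta, se, pval, eaf_e, n, chroms, positions, ids)

    corr = np.corrcoef(G_e.T)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    r2 = np.clip(corr**2, 0.0, 1.0)
    r2 = (r2 + r2.T) / 2.0
    ld = LDMatrix(list(ids), r2)

    G_m, _, M_m, _ = phenotypes(rng_med, n)
    beta, se, pval = _linear_sumstats(G_m, M_m)
    mediator = _to_trait("metabolite_sim", "simulated blood metabolite", "continuous", beta, se, pval, G_m.mean(axis=0) / 2.0, n, chroms, positions, ids)

    G_o, _, _, Y_o = phenotypes(rng_out, n)
    if spec.outcome_type == "binary":
        beta, se, pval = _logistic_sumstats(G_o, Y_o)
        n_case = int(Y_o.sum())
        outcome = _to_trait(
            "epilepsy_sim", "simulated disease endpoint", "binary", beta, se, pval,
            G_o.mean(axis=0) / 2.0, n, chroms, positions, ids, n_case=n_case, n_control=n - n_case,
        )
    else:
        beta, se, pval = _linear_sumstats(G_o, Y_o)
        outcome = _to_trait("epilepsy_sim", "simulated disease endpoint", "continuous", beta, se, pval, G_o.mean(axis=0) / 2.0, n, chroms, positions, ids)

    total = spec.beta_direct + spec.beta1 * spec.beta2
    truth = ChainTruth(
        beta1=spec.beta1,
        beta2=spec.beta2,
        beta_direct=spec.beta_direct,
        total=total,
        proportion=(spec.beta1 * spec.beta2 / total) if total != 0 else None,
        exposure_snp_ids=[ids[j] for j in exp_idx],
        mediator_snp_ids=[ids[j] for j in med_idx],
        outcome_snp_ids=[ids[j] for j in out_idx],
        reverse_beta=spec.reverse_beta,
        mafs={ids[j]: float(mafs[j]) for j in range(m)},
    )
    return exposure, mediator, outcome, ld, truth


def simulate_paired_metabolome(spec: MetabolomeSpec) -> tuple[PairedFeatureTable, list[SeizureOutcome], dict]:
    """Simulate a paired pre/post metabolome plus seizure outcomes.

    Pre-abundances are log-normal; post = pre * exp(delta_f + noise) with
    delta_f = dz_f * feature_noise_sd for panel features.  The seizure
    control rate is a strictly monotone transform of a latent variable with
    correlation ``response_coupling`` to the top panel feature's log change,
    so the planted rank correlation is exact when coupling = +/-1.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n, F, P = spec.n_subjects, spec.n_features, spec.panel_size

    width = max(3, len(str(F)))
    feature_ids = [f"SM_{i + 1:0{width}d}" if i < P else f"MET_{i + 1:0{width}d}" for i in range(F)]
    panel_labels = {fid: ("SM" if i < P else "other") for i, fid in enumerate(feature_ids)}
    dz = np.zeros(F)
    dz[:P] = np.asarray(spec.effect_sizes_dz, dtype=float)

    base = rng.normal(0.0, 1.0, size=F)
    pre = np.exp(base[None, :] + spec.baseline_log_sd * rng.standard_normal((n, F)))
    log_change = dz[None, :] * spec.feature_noise_sd + spec.feature_noise_sd * rng.standard_normal((n, F))
    post = pre * np.exp(log_change)

    subject_ids = [f"S{i + 1}" for i in range(n)]
    table = PairedFeatureTable(subject_ids, feature_ids, pre, post, panel_labels)

    top = int(np.argmax(dz))
    d_top = log_change[:, top]
    sd = d_top.std()
    z_top = (d_top - d_top.mean()) / sd if sd > 0 else np.zeros(n)
    cpl = spec.response_coupling
    u = cpl * z_top + np.sqrt(max(1.0 - cpl**2, 0.0)) * rng.standard_normal(n)
    control = 100.0 * np.tanh(u / 2.0)  # strictly monotone in u, bounded in (-100, 100)
    pre_freq = np.exp(rng.normal(np.log(12.0), 0.4, size=n))
    post_freq = pre_freq * (1.0 - control / 100.0)
    seizures = [SeizureOutcome(subject_ids[i], float(pre_freq[i]), float(post_freq[i])) for i in range(n)]

    truth = {
        "dz_log": {feature_ids[i]: float(dz[i]) for i in range(F)},
        "panel": feature_ids[:P],
        "top_feature": feature_ids[top],
        "response_coupling": cpl,
        "feature_noise_sd": spec.feature_noise_sd,
    }
    return table, seizures, truth
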