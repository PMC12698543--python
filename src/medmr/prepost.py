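"""Paired pre/post metabolomics: t-tests, effect sizes, panel FDR, response.

The clinical arm compares fasting-serum metabolite abundances in the same
subjects before and after a dietary intervention.  Per feature it reports
the two-sided paired t-test, Cohen's dz (mean difference over SD of
differences, n-1 denominator), a seeded percentile-bootstrap 95% CI for dz
(2,000 subject resamples by default), fold change on group means,
leave-one-out (LOO) ranges of p and dz, and a BH-FDR q-value scoped to a
caller-defined feature panel.  Seizure response is summarized as the
percentage reduction in seizure frequency, and its association with feature
changes by a two-sided Spearman test whose p-value is exact (full
permutation enumeration) for n <= 7, Monte-Carlo permutation for
8 <= n <= 12 and the t approximation above that — small-cohort sizes such
as n = 9 sit where the asymptotic approximation is poor.

Model-object entry point: ``PairedPanelModel(table).fit(panel=...)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateVarianceError, DomainError, EmptyInputError
from .multiplicity import bh_fdr


@dataclass
class PairedFeatureTable:
    """Abundance matrices (subjects x features) at two time points."""

    subject_ids: list[str]
    feature_ids: list[str]
    pre: np.ndarray
    post: np.ndarray
    panel_labels: dict[str, str] | None = None

    def __post_init__(self):
        self.pre = np.asarray(self.pre, dtype=float)
        self.post = np.asarray(self.post, dtype=float)
        n, f = len(self.subject_ids), len(self.feature_ids)
        if self.pre.shape != (n, f) or self.post.shape != (n, f):
            raise ValueError("pre/post must both be (n_subjects, n_features)")
        if n < 2:
            raise ValueError("need at least 2 subjects")
        if np.isnan(self.pre).any() or np.isnan(self.post).any():
            raise ValueError("missing cells must be resolved upstream")
        if (self.pre < 0).any() or (self.post < 0).any():
            raise ValueError("abundances must be non-negative")

    def panel(self, label: str) -> list[str]:
        if not self.panel_labels:
            return []
        return [f for f in self.feature_ids if self.panel_labels.get(f) == label]

    def column(self, feature_id: str) -> tuple[np.ndarray, np.ndarray]:
        j = self.feature_ids.index(feature_id)
        return self.pre[:, j], self.post[:, j]

    @classmethod
    def from_wide_frame(cls, df: pd.DataFrame, panel_labels=None) -> "PairedFeatureTable":
        """Wide layout: index = subject, columns = '<feature>@pre'/'<feature>@post'."""
        feats = sorted({c.rsplit("@", 1)[0] for c in df.columns if c.endswith("@pre")})
        pre = df[[f + "@pre" for f in feats]].to_numpy(float)
        post = df[[f + "@post" for f in feats]].to_numpy(float)
        return cls([str(s) for s in df.index], feats, pre, post, panel_labels)

    def to_wide_frame(self) -> pd.DataFrame:
        data = {}
        for j, f in enumerate(self.feature_ids):
            data[f + "@pre"] = self.pre[:, j]
            data[f + "@post"] = self.post[:, j]
        return pd.DataFrame(data, index=self.subject_ids)


@dataclass
class BootstrapCI:
    low: float
    high: float
    n_degenerate: int = 0
    unreliable: bool = False

    def __iter__(self):
        return iter((self.low, self.high))


@dataclass
class PairedFeatureResult:
    """Pre/post statistics for one feature."""

    feature_id: str
    mean_pre: float
    mean_post: float
    t_stat: float
    pval: float
    dz: float
    qval: float | None = None
    dz_ci_low: float | None = None
    dz_ci_high: float | None = None
    fold_change: float | None = None
    log2_fc: float | None = None
    loo_p_min: float | None = None
    loo_p_max: float | None = None
    loo_dz_min: float | None = None
    loo_dz_max: float | None = None


@dataclass
class SeizureOutcome:
    """Per-subject seizure frequencies and the derived control rate."""

    subject_id: str
    pre_freq: float
    post_freq: float
    control_rate: float = field(init=False)

    def __post_init__(self):
        self.control_rate = seizure_control_rate(self.pre_freq, self.post_freq)


def paired_test(pre, post) -> tuple[float, float, float]:
    """Two-sided paired t-test and Cohen's dz on d = post - pre.

    t = mean(d) / (sd(d)/sqrt(n)) with the n-1 SD; p from t with n-1 df;
    dz = mean(d)/sd(d).  Zero-variance differences raise
    :class:`DegenerateVarianceError` carrying the mean difference.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or pre.size < 2:
        raise ValueError("pre/post must be equal-length vectors with n >= 2")
    d = post - pre
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateVarianceError(
            f"all paired differences equal (mean {d.mean()}); t undefined", mean_diff=float(d.mean())
        )
    dz = float(d.mean() / sd)
    t = dz * math.sqrt(n)
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return float(t), p, dz


def bootstrap_dz_ci(pre, post, n_boot: int = 2000, seed: int | None = None) -> BootstrapCI:
    """Percentile bootstrap 95% CI for Cohen's dz, resampling subjects.

    Degenerate replicates (zero-variance differences) are skipped and
    counted; more than 10% of them flags the interval as unreliable.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    n = pre.size
    if n < 3:
        raise ValueError("bootstrap needs n >= 3 subjects")
    # Sorting the differences makes the resample (hence the CI) invariant to
    # subject ordering without changing its distribution.
    d = np.sort(post - pre)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    samples = d[idx]
    means = samples.mean(axis=1)
    sds = samples.std(axis=1, ddof=1)
    ok = sds > 0
    n_degenerate = int(n_boot - ok.sum())
    dzs = means[ok] / sds[ok]
    if dzs.size == 0:
        # All replicates constant: the sample dz is undefined unless d itself
        # is constant, in which case the CI has zero width at infinity-free 0.
        return BootstrapCI(float(d.mean()), float(d.mean()), n_degenerate, True)
    low, high = np.percentile(dzs, [2.5, 97.5])
    return BootstrapCI(float(low), float(high), n_degenerate, n_degenerate > 0.1 * n_boot)


def fold_changes(pre, post) -> tuple[float, float]:
    """Fold change of group means, mean(post)/mean(pre), and its log2."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    mp = pre.mean()
    if mp <= 0:
        raise DomainError("mean(pre) must be > 0 for a fold change")
    fc = float(post.mean() / mp)
    return fc, float(math.log2(fc)) if fc > 0 else float("-inf")


def subject_ratio_fold_change(pre, post) -> float:
    """Mean of per-subject post/pre ratios (alternative fold-change definition)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if (pre <= 0).any():
        raise DomainError("per-subject ratios need all pre > 0")
    return float((post / pre).mean())


def loo_sensitivity(pre, post) -> dict:
    """Leave-one-out refits of the paired t-test: one refit per subject.

    Returns min/max of p and dz over non-degenerate refits plus counts.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    n = pre.size
    if n < 3:
        raise ValueError("LOO needs n >= 3 subjects")
    ps, dzs = [], []
    n_degenerate = 0
    for i in range(n):
        mask = np.arange(n) != i
        try:
            _, p, dz = paired_test(pre[mask], post[mask])
        except DegenerateVarianceError:
            n_degenerate += 1
            continue
        ps.append(p)
        dzs.append(dz)
    return {
        "loo_p_min": min(ps) if ps else None,
        "loo_p_max": max(ps) if ps else None,
        "loo_dz_min": min(dzs) if dzs else None,
        "loo_dz_max": max(dzs) if dzs else None,
        "n_refits": n,
        "n_degenerate": n_degenerate,
    }


def analyze_panel(
    table: PairedFeatureTable,
    panel: list[str] | None = None,
    n_boot: int = 2000,
    seed: int | None = None,
    followup_alpha: float = 0.05,
    transform: str = "none",
) -> list[PairedFeatureResult]:
    """Per-feature paired statistics with BH-FDR scoped to ``panel``.

    q-values are computed over the panel's p-values only; features with
    p < ``followup_alpha`` additionally get the bootstrap dz CI and the LOO
    ranges.  Bootstrap seeds are derived per feature (stable under feature
    and subject reordering).

    ``transform`` is ``none`` (statistics on abundances as given) or ``log``
    (t/p/dz/bootstrap/LOO on log abundances, the usual choice for strongly
    right-skewed intensities; requires strictly positive values).  Fold
    changes are always on the raw scale.  No transform is ever applied
    implicitly.
    """
    if transform not in ("none", "log"):
        raise ValueError("transform must be 'none' or 'log'")
    panel = list(panel) if panel is not None else list(table.feature_ids)
    if not panel:
        raise EmptyInputError("panel must contain at least one feature")
    unknown = [f for f in panel if f not in table.feature_ids]
    if unknown:
        raise KeyError(f"panel features not in table: {unknown}")

    results: list[PairedFeatureResult] = []
    for f in sorted(panel):
        raw_pre, raw_post = table.column(f)
        if transform == "log":
            if (raw_pre <= 0).any() or (raw_post <= 0).any():
                raise DomainError(f"{f}: log transform requires positive abundances")
            pre, post = np.log(raw_pre), np.log(raw_post)
        else:
            pre, post = raw_pre, raw_post
        t, p, dz = paired_test(pre, post)
        fc, lfc = fold_changes(raw_pre, raw_post)
        r = PairedFeatureResult(
            feature_id=f, mean_pre=float(raw_pre.mean()), mean_post=float(raw_post.mean()),
            t_stat=t, pval=p, dz=dz, fold_change=fc, log2_fc=lfc,
        )
        if p < followup_alpha and pre.size >= 3:
            sub_seed = None
            if seed is not None:
                # Stable per-feature stream regardless of panel composition
                # (crc32 is deterministic across processes, unlike hash()).
                import zlib

                sub_seed = np.random.SeedSequence([seed, zlib.crc32(f.encode())]).generate_state(1)[0]
            ci = bootstrap_dz_ci(pre, post, n_boot=n_boot, seed=int(sub_seed) if sub_seed is not None else None)
            r.dz_ci_low, r.dz_ci_high = ci.low, ci.high
            loo = loo_sensitivity(pre, post)
            r.loo_p_min, r.loo_p_max = loo["loo_p_min"], loo["loo_p_max"]
            r.loo_dz_min, r.loo_dz_max = loo["loo_dz_min"], loo["loo_dz_max"]
        results.append(r)

    qs = bh_fdr([r.pval for r in results])
    for r, q in zip(results, qs):
        r.qval = q
    return results


def seizure_control_rate(pre_freq: float, post_freq: float) -> float:
    """(pre - post) / pre * 100: percentage reduction in seizure frequency.

    Negative values mean worsening; 100 is complete control.
    """
    if pre_freq <= 0:
        raise DomainError(f"pre-intervention frequency must be > 0, got {pre_freq}")
    return float((pre_freq - post_freq) / pre_freq * 100.0)


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise DegenerateVarianceError("constant vector; Spearman correlation undefined")
    return float((rx @ ry) / denom)


@dataclass
class SpearmanResult:
    rho: float
    pval: float
    method: str  # exact | permutation | t_approx
    exploratory: bool = True  # never multiplicity-adjusted

    def __iter__(self):
        return iter((self.rho, self.pval))


def response_correlation(
    delta_feature,
    control_rate,
    seed: int | None = None,
    n_perm: int = 100_000,
) -> SpearmanResult:
    """Two-sided Spearman test of feature changes against seizure control.

    Exact permutation enumeration for n <= 7, seeded Monte-Carlo permutation
    (``n_perm`` draws) for 8 <= n <= 12, t approximation otherwise.  The
    p-value is deliberately unadjusted and flagged exploratory.
    """
    x = np.asarray(delta_feature, dtype=float)
    y = np.asarray(control_rate, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need equal-length vectors with n >= 4")
    n = x.size
    rho = _spearman_rho(x, y)
    eps = 1e-12
    ry = stats.rankdata(y)
    if n <= 7:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = _spearman_rho(x, ry[list(perm)])
            count += abs(r) >= abs(rho) - eps
            total += 1
        p = count / total
        method = "exact"
    elif n <= 12:
        rng = np.random.default_rng(seed)
        rx = stats.rankdata(x)
        rxc = rx - rx.mean()
        denom_x = float(rxc @ rxc)
        ryc = ry - ry.mean()
        denom = math.sqrt(denom_x * float(ryc @ ryc))
        hits = 1  # include the observed ordering
        for _ in range(n_perm):
            r = float(rxc @ ryc[rng.permutation(n)]) / denom
            hits += abs(r) >= abs(rho) - eps
        p = hits / (n_perm + 1)
        method = "permutation"
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
        method = "t_approx"
    return SpearmanResult(rho=rho, pval=min(float(p), 1.0), method=method)


class PairedPanelModel:
    """Model object over a :class:`PairedFeatureTable`.

    ``fit`` runs :func:`analyze_panel` and returns a
    :class:`PairedPanelResults` with a tidy frame and text summary.
    """

    def __init__(self, table: PairedFeatureTable):
        self.table = table

    def fit(self, panel=None, n_boot: int = 2000, seed: int | None = None, transform: str = "none") -> "PairedPanelResults":
        results = analyze_panel(self.table, panel=panel, n_boot=n_boot, seed=seed, transform=transform)
        return PairedPanelResults(self, results)


class PairedPanelResults:
    def __init__(self, model: PairedPanelModel, results: list[PairedFeatureResult]):
        self.model = model
        self.results = results

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.results]).set_index("feature_id")

    def summary(self) -> str:
        df = self.to_frame()
        lines = [f"Paired pre/post panel: {len(df)} features, n = {len(self.model.table.subject_ids)} subjects"]
        for fid, row in df.sort_values("qval").iterrows():
            lines.append(
                f"  {fid}: t = {row.t_stat:.3f}, p = {row.pval:.3g}, q = {row.qval:.3g}, "
                f"dz = {row.dz:.3f}, FC = {row.fold_change:.3f}"
            )
        return "\n".join(lines)
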