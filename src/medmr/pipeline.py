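"""End-to-end orchestration from a single flat config.

Stages: forward screen -> reverse (bidirectionality) filter -> mediator
identification (microbe -> metabolite MR) -> two-step mediation scan ->
multiplicity report.  Every stage persists a TSV, a structured log line
records each skip, and the JSON manifest carries the config hash and the
per-stage funnel counts (monotone non-increasing).  Result tables are
byte-identical across reruns with the same config and inputs; the manifest
additionally carries wall-clock timestamps and is excluded from that
guarantee.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import DomainError
from .gwas_io import TraitSummary, read_summary_stats
from .instruments import LDMatrix
from .mediation import (
    MediationResult,
    ScreenConfig,
    forward_screen,
    mediation_scan,
    reverse_filter,
)
from .mr import mr_analysis
from .multiplicity import bh_fdr, bonferroni_alpha

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat configuration for one pipeline run."""

    exposure_paths: list[str]
    mediator_paths: list[str]
    outcome_path: str
    ld_path: str
    out_dir: str = "medmr_out"
    p_max: float = 1e-5
    clump_r2: float = 0.001
    window_kb: float = 10000.0
    f_min: float = 10.0
    palindrome_eaf_limit: float = 0.42
    alpha_forward: float = 0.05
    alpha_pleiotropy: float = 0.05
    alpha_heterogeneity: float = 0.05
    alpha_reverse: float = 0.05
    alpha_mediator: float = 0.05
    alpha_fw: float = 0.05
    ci_method: str = "delta"
    n_boot: int = 10000
    seed: int = 0

    def __post_init__(self):
        for name in ("p_max", "clump_r2", "alpha_forward", "alpha_pleiotropy", "alpha_heterogeneity", "alpha_reverse", "alpha_mediator", "alpha_fw"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise DomainError(f"{name} must lie in (0, 1], got {v}")
        if self.window_kb <= 0 or self.f_min < 0:
            raise DomainError("window_kb must be > 0 and f_min >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DomainError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def screen_config(self) -> ScreenConfig:
        return ScreenConfig(
            p_max=self.p_max,
            clump_r2=self.clump_r2,
            window_kb=self.window_kb,
            f_min=self.f_min,
            palindrome_eaf_limit=self.palindrome_eaf_limit,
            alpha_forward=self.alpha_forward,
            alpha_pleiotropy=self.alpha_pleiotropy,
            alpha_heterogeneity=self.alpha_heterogeneity,
            alpha_reverse=self.alpha_reverse,
            alpha_mediator=self.alpha_mediator,
            ci_method=self.ci_method,
            n_boot=self.n_boot,
        )

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Machine-readable run record with the screening funnel."""

    config_hash: str
    version: str
    counts: dict = field(default_factory=dict)
    started_at: float = 0.0
    finished_at: float = 0.0
    failed_stage: str | None = None

    def check_funnel(self) -> bool:
        order = ["exposures_in", "with_instruments", "passed_forward", "passed_reverse"]
        vals = [self.counts.get(k) for k in order if k in self.counts]
        return all(a >= b for a, b in zip(vals, vals[1:]))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def read_ld_matrix(path) -> LDMatrix:
    """Read a square (first row/column = ids) or long (id1 id2 r2) LD file."""
    df = pd.read_csv(path, sep="\t")
    if set(df.columns[:3]) >= {"id1", "id2", "r2"} or list(df.columns[:3]) == ["id1", "id2", "r2"]:
        triples = [(r.id1, r.id2, float(r.r2)) for r in df.itertuples(index=False)]
        return LDMatrix.from_long(triples)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LDMatrix([str(c) for c in df.columns], df.to_numpy(float))


def write_ld_matrix(ld: LDMatrix, path) -> str:
    pd.DataFrame(ld.r2, index=ld.variant_ids, columns=ld.variant_ids).to_csv(path, sep="\t")
    return str(path)


def _fmt_float(x) -> str:
    return "." if x is None or (isinstance(x, float) and not np.isfinite(x)) else repr(float(x))


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) if isinstance(v, (str, int, bool)) else _fmt_float(v) for v in row) + "\n")


def run_pipeline(
    config: RunConfig,
    exposures: list[TraitSummary] | None = None,
    mediators: list[TraitSummary] | None = None,
    outcome: TraitSummary | None = None,
    ld: LDMatrix | None = None,
) -> RunManifest:
    """Execute the full analysis; in-memory traits may override file paths.

    Writes screen.tsv, reverse.tsv, mediators.tsv, mediation.tsv and
    manifest.json under ``config.out_dir`` and returns the manifest.
    """
    manifest = RunManifest(config_hash=config.content_hash(), version=__version__, started_at=time.time())
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config.screen_config()

    stage = "load_inputs"
    try:
        if exposures is None:
            exposures = [read_summary_stats(p) for p in config.exposure_paths]
        if mediators is None:
            mediators = [read_summary_stats(p) for p in config.mediator_paths]
        if outcome is None:
            outcome = read_summary_stats(config.outcome_path)
        if ld is None:
            ld = read_ld_matrix(config.ld_path)
        manifest.counts["exposures_in"] = len(exposures)
        manifest.counts["mediators_in"] = len(mediators)

        stage = "forward_screen"
        screen = forward_screen(exposures, outcome, ld, cfg)
        manifest.counts["with_instruments"] = sum(1 for s in screen if s.skip_reason is None)
        forward_ps = [s.forward.pval for s in screen if s.forward is not None]
        qvals = dict(zip([s.exposure_id for s in screen if s.forward is not None], bh_fdr(forward_ps))) if forward_ps else {}
        bonf = bonferroni_alpha(max(len(exposures), 1), config.alpha_fw)

        stage = "reverse_filter"
        screen = reverse_filter(screen, exposures, outcome, ld, cfg)
        manifest.counts["passed_forward"] = sum(1 for s in screen if s.passes_forward)
        manifest.counts["passed_reverse"] = sum(1 for s in screen if s.passes_forward and s.passes_reverse)

        rows = []
        for s in screen:
            if s.forward is None:
                rows.append([s.exposure_id, s.outcome_id, 0, None, None, None, None, None, None, False, s.skip_reason or ""])
                logger.info("pair %s -> %s: skipped (%s)", s.exposure_id, s.outcome_id, s.skip_reason)
                continue
            rows.append([
                s.exposure_id, s.outcome_id, s.forward.n_snp, s.forward.beta, s.forward.se,
                s.forward.pval, qvals.get(s.exposure_id),
                s.sensitivity.q_pval_ivw, s.sensitivity.egger_intercept_pval,
                s.passes_forward, "",
            ])
            logger.info(
                "pair %s -> %s: nsnp=%d p=%.3g passes_forward=%s",
                s.exposure_id, s.outcome_id, s.forward.n_snp, s.forward.pval, s.passes_forward,
            )
        _write_tsv(out_dir / "screen.tsv",
                   ["exposure", "outcome", "nsnp", "b", "se", "pval", "qval_bh", "q_pval", "egger_intercept_pval", "passes_forward", "skip_reason"],
                   rows)

        rows = []
        for s in screen:
            if not s.passes_forward:
                continue
            if s.reverse is None:
                rows.append([s.outcome_id, s.exposure_id, None, None, None, True, "no reverse instruments"])
            else:
                rows.append([s.outcome_id, s.exposure_id, s.reverse.beta, s.reverse.se, s.reverse.pval, s.passes_reverse, ""])
        _write_tsv(out_dir / "reverse.tsv",
                   ["exposure", "outcome", "b", "se", "pval", "passes_reverse", "note"], rows)

        stage = "mediator_identification"
        candidates = [s for s in screen if s.is_mediation_candidate]
        cand_traits = [t for t in exposures if t.trait_id in {s.exposure_id for s in candidates}]
        med_rows = []
        identified: list[TraitSummary] = []
        for med in mediators:
            hit = False
            for microbe in cand_traits:
                res = mr_analysis(microbe, med, ld, **cfg.mr_kwargs())
                if res.skipped:
                    continue
                est = res.results.primary
                med_rows.append([microbe.trait_id, med.trait_id, est.n_snp, est.beta, est.se, est.pval, est.pval < cfg.alpha_mediator])
                hit = hit or est.pval < cfg.alpha_mediator
            if hit:
                identified.append(med)
        _write_tsv(out_dir / "mediators.tsv",
                   ["microbe", "mediator", "nsnp", "b", "se", "pval", "identified"], med_rows)
        manifest.counts["mediators_identified"] = len(identified)

        stage = "mediation_scan"
        results, skips = mediation_scan(cand_traits, identified, outcome, ld, cfg, seed=config.seed)
        for sk in skips:
            logger.info("mediation %s x %s skipped: %s", sk.microbe_id, sk.mediator_id, sk.reason)
        manifest.counts["mediation_rows"] = len(results)
        manifest.counts["mediation_significant"] = sum(1 for r in results if r.significant)
        manifest.counts["bonferroni_alpha"] = bonf

        rows = [
            [
                r.microbe_id, r.mediator_id, r.outcome_id,
                r.beta1, r.se1, r.beta2, r.se2, r.beta_total, r.se_total,
                r.mediated_effect, r.mediated_ci_low, r.mediated_ci_high, r.mediated_pval,
                r.direct_effect, r.proportion, r.proportion_ci_low, r.proportion_ci_high,
                r.significant, r.n_snp1, r.n_snp2, r.n_snp_total,
            ]
            for r in results
        ]
        _write_tsv(out_dir / "mediation.tsv",
                   ["microbe", "mediator", "outcome", "b1", "se1", "b2", "se2", "b_total", "se_total",
                    "mediated_effect", "mediated_ci_low", "mediated_ci_high", "mediated_pval",
                    "direct_effect", "proportion", "proportion_ci_low", "proportion_ci_high",
                    "significant", "nsnp1", "nsnp2", "nsnp_total"],
                   rows)
    except Exception:
        manifest.failed_stage = stage
        manifest.finished_at = time.time()
        (out_dir / "manifest.json").write_text(manifest.to_json())
        logger.exception("pipeline failed at stage %s", stage)
        raise

    manifest.finished_at = time.time()
    assert manifest.check_funnel(), "screening funnel counts must be non-increasing"
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
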