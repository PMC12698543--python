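"""Instrumental-variable selection for two-sample MR.

Selection is the standard three-stage filter: genome-wide candidates at
p < ``p_max`` (default 1e-5), greedy LD clumping (r^2 < ``clump_r2`` within a
``window_kb`` physical window, default 0.001 within 10,000 kb), then a
per-SNP strength filter (F > ``f_min``, default 10).

Per-SNP strength uses the standard summary-data surrogates: with an
effect-allele frequency the variance explained is R^2 = 2 f (1-f) beta^2
under a unit-variance trait; without one it falls back to the algebraic
identity R^2 = F / (F + n - 2) with F = (beta/se)^2.  Either way
F = R^2 (n - 2) / (1 - R^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InsufficientDataError, MissingLDError
from .gwas_io import TraitSummary, VariantAssociation

logger = logging.getLogger(__name__)


@dataclass
class LDMatrix:
    """Squared-correlation matrix over a set of variants.

    ``r2`` is symmetric with unit diagonal and entries in [0, 1].  Pairs of
    variants absent from the matrix are treated as unlinked (r^2 = 0) when
    they lie on different chromosomes; within a chromosome a missing
    candidate is an error (see :func:`clump`).
    """

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise ValueError("r2 must be square over variant_ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("r2 must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-6):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 entries must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def get(self, id1: str, id2: str, default: float | None = None) -> float | None:
        i = self._index.get(id1)
        j = self._index.get(id2)
        if i is None or j is None:
            return default
        return float(self.r2[i, j])

    @classmethod
    def identity(cls, variant_ids: list[str]) -> "LDMatrix":
        return cls(list(variant_ids), np.eye(len(variant_ids)))

    @classmethod
    def from_long(cls, triples, variant_ids=None) -> "LDMatrix":
        """Build from (id1, id2, r2) triples; unlisted pairs are 0."""
        ids = list(variant_ids) if variant_ids is not None else []
        seen = set(ids)
        for a, b, _ in triples:
            for v in (a, b):
                if v not in seen:
                    seen.add(v)
                    ids.append(v)
        idx = {v: i for i, v in enumerate(ids)}
        m = np.eye(len(ids))
        for a, b, r in triples:
            m[idx[a], idx[b]] = r
            m[idx[b], idx[a]] = r
        return cls(ids, m)


@dataclass
class InstrumentSet:
    """Post-filter instruments for one exposure with strength diagnostics.

    ``snps`` is a list of (record, r2_explained, f_stat) triples; threshold
    attributes record the filter actually applied.
    """

    exposure_id: str
    snps: list[tuple[VariantAssociation, float, float]] = field(default_factory=list)
    p_max: float = 1e-5
    clump_r2: float = 0.001
    clump_window_kb: float = 10000.0
    f_min: float = 10.0

    def __len__(self) -> int:
        return len(self.snps)

    def variant_ids(self) -> list[str]:
        return [v.variant_id for v, _, _ in self.snps]

    def records(self) -> list[VariantAssociation]:
        return [v for v, _, _ in self.snps]


def variance_explained(v: VariantAssociation) -> float:
    """Per-SNP fraction of trait variance explained by the variant.

    Uses 2 f (1-f) beta^2 on a unit-variance trait when the effect-allele
    frequency is known, else the F-based identity F/(F + n - 2) with
    F = (beta/se)^2.  Clipped to [0, 1).
    """
    if v.eaf is not None:
        r2 = 2.0 * v.eaf * (1.0 - v.eaf) * v.beta**2
    else:
        if v.n < 3:
            raise InsufficientDataError(
                f"{v.variant_id}: eaf missing and n={v.n} < 3; cannot compute variance explained"
            )
        f = (v.beta / v.se) ** 2
        r2 = f / (f + v.n - 2)
    return float(min(max(r2, 0.0), 1.0 - 1e-15))


def f_statistic(v: VariantAssociation) -> float:
    """Per-SNP instrument-strength F = R^2 (n - 2) / (1 - R^2).

    With eaf missing this reduces exactly to (beta/se)^2.
    """
    if v.eaf is None:
        return float((v.beta / v.se) ** 2)
    r2 = variance_explained(v)
    return float(r2 * (v.n - 2) / (1.0 - r2))


def _sort_key(v: VariantAssociation):
    return (v.pval, v.chrom, v.pos, v.variant_id)


def clump(
    candidates: list[VariantAssociation],
    ld: LDMatrix,
    clump_r2: float = 0.001,
    window_kb: float = 10000.0,
) -> list[VariantAssociation]:
    """Greedy p-value-ordered LD clumping.

    Candidates are sorted by ascending p (ties broken by chromosome,
    position, id); the best remaining variant is kept and every other
    candidate with r^2 >= ``clump_r2`` within ``window_kb`` kilobases on the
    same chromosome is removed.  Fully deterministic.
    """
    # A candidate absent from the LD matrix is only tolerable if no other
    # candidate shares its chromosome (cross-chromosome r^2 is taken as 0).
    chrom_counts: dict[str, int] = {}
    for v in candidates:
        chrom_counts[v.chrom] = chrom_counts.get(v.chrom, 0) + 1
    for v in candidates:
        if v.variant_id not in ld and chrom_counts[v.chrom] > 1:
            raise MissingLDError(
                f"{v.variant_id} (chrom {v.chrom}) absent from LD matrix while other "
                "candidates share its chromosome"
            )

    ordered = sorted(candidates, key=_sort_key)
    kept: list[VariantAssociation] = []
    removed: set[str] = set()
    window_bp = window_kb * 1000.0
    for v in ordered:
        if v.variant_id in removed:
            continue
        kept.append(v)
        for u in ordered:
            if u.variant_id == v.variant_id or u.variant_id in removed:
                continue
            if u.chrom != v.chrom:
                continue
            if abs(u.pos - v.pos) > window_bp:
                continue
            r2 = ld.get(v.variant_id, u.variant_id, default=0.0)
            if r2 >= clump_r2:
                removed.add(u.variant_id)
    return kept


def select_instruments(
    ts: TraitSummary,
    ld: LDMatrix,
    p_max: float = 1e-5,
    clump_r2: float = 0.001,
    window_kb: float = 10000.0,
    f_min: float = 10.0,
) -> InstrumentSet:
    """p-threshold -> greedy clump -> F filter, deterministically.

    An empty result is not an error: the caller decides whether an exposure
    without instruments is skipped or fatal (a warning is logged).
    """
    candidates = [v for v in ts.records.values() if v.pval < p_max]
    # Dedup by variant_id is implicit (TraitSummary keys are unique).
    clumped = clump(candidates, ld, clump_r2=clump_r2, window_kb=window_kb)
    out = InstrumentSet(
        exposure_id=ts.trait_id,
        p_max=p_max,
        clump_r2=clump_r2,
        clump_window_kb=window_kb,
        f_min=f_min,
    )
    for v in clumped:
        r2 = variance_explained(v)
        f = f_statistic(v)
        if f > f_min:
            out.snps.append((v, r2, f))
    if not out.snps:
        logger.warning("trait %s: no instruments survive selection", ts.trait_id)
    return out
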