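"""GWAS summary-statistics data model, delimited IO and allele harmonization.

The on-disk format is a GWAS-SSF-like tab-separated table with a fixed header
(:data:`SS_COLUMNS`), ``.`` for missing values, UTF-8, no quoting.  Floats are
written with ``repr`` so a write/read round trip is bit-exact.

Harmonization orients an outcome table to the exposure's effect allele:
swapped allele labels flip the outcome beta, strand-complement labels are
matched through their complements, palindromic (A/T, C/G) variants are kept
only when both allele frequencies are informative (minor-allele frequency
below ``palindrome_eaf_limit`` on both sides, after label alignment on the
same side of 0.5); everything else is dropped with an explicit action code.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, SchemaError

logger = logging.getLogger(__name__)

#: Fixed column order of the on-disk tab-separated format.
SS_COLUMNS = [
    "variant_id",
    "chromosome",
    "base_pair_location",
    "effect_allele",
    "other_allele",
    "effect_allele_frequency",
    "beta",
    "standard_error",
    "p_value",
    "n",
    "n_case",
    "n_control",
]

MISSING = "."

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement(allele: str) -> str | None:
    try:
        return "".join(_COMPLEMENT[b] for b in allele)
    except KeyError:
        return None


@dataclass
class VariantAssociation:
    """One variant's association record within a trait's summary statistics.

    ``beta`` is the per-effect-allele estimate (log-OR scale for binary
    traits), ``se`` its standard error, ``pval`` the association p-value and
    ``eaf`` the effect-allele frequency (``None`` when unavailable).
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: int
    eaf: float | None = None
    n_case: int | None = None
    n_control: int | None = None

    def is_valid(self) -> bool:
        """Hard invariants: positive SE, p in (0, 1], eaf in (0, 1) or absent."""
        if not (self.se > 0):
            return False
        if not (0 < self.pval <= 1):
            return False
        if self.eaf is not None and not (0 < self.eaf < 1):
            return False
        if not self.effect_allele or not self.other_allele:
            return False
        return True

    def is_palindromic(self) -> bool:
        pair = {self.effect_allele, self.other_allele}
        return pair == {"A", "T"} or pair == {"C", "G"}

    def pval_consistent(self, rel_tol: float = 0.5) -> bool:
        """Check ``pval`` against the normal approximation 2*Phi(-|beta/se|).

        Loose by design (``rel_tol`` on the log scale): GWAS tables round
        p-values aggressively.  Inconsistency is a warning, never an error.
        """
        from scipy.stats import norm

        z = abs(self.beta / self.se)
        expected = 2.0 * norm.sf(z)
        if expected <= 0 or self.pval <= 0:
            return True
        return abs(math.log(max(expected, 1e-300)) - math.log(self.pval)) <= rel_tol * abs(
            math.log(max(expected, 1e-300))
        ) + 1.0


@dataclass
class TraitSummary:
    """A trait's GWAS summary statistics keyed by variant_id."""

    trait_id: str
    trait_label: str = ""
    trait_type: str = "continuous"  # or "binary"
    source: str = ""
    records: dict[str, VariantAssociation] = field(default_factory=dict)

    def __post_init__(self):
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type!r}")

    def __len__(self) -> int:
        return len(self.records)

    def add(self, rec: VariantAssociation) -> None:
        if rec.variant_id in self.records:
            raise ValueError(f"duplicate variant_id {rec.variant_id!r} in trait {self.trait_id!r}")
        self.records[rec.variant_id] = rec

    def variant_ids(self) -> list[str]:
        return list(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records.values():
            rows.append(
                {
                    "variant_id": r.variant_id,
                    "chromosome": r.chrom,
                    "base_pair_location": r.pos,
                    "effect_allele": r.effect_allele,
                    "other_allele": r.other_allele,
                    "effect_allele_frequency": r.eaf,
                    "beta": r.beta,
                    "standard_error": r.se,
                    "p_value": r.pval,
                    "n": r.n,
                    "n_case": r.n_case,
                    "n_control": r.n_control,
                }
            )
        return pd.DataFrame(rows, columns=SS_COLUMNS)


@dataclass
class HarmonizedPair:
    """Exposure/outcome estimates for one variant oriented to a common allele."""

    variant_id: str
    beta_exp: float | None
    se_exp: float | None
    beta_out: float | None
    se_out: float | None
    eaf_exp: float | None = None
    eaf_out: float | None = None
    action_taken: str = "kept"  # kept | flipped | dropped_palindromic | dropped_incompatible

    @property
    def kept(self) -> bool:
        return self.action_taken in ("kept", "flipped")


# ---------------------------------------------------------------------------
# Delimited IO


def _parse_float(tok: str) -> float | None:
    return None if tok == MISSING or tok == "" else float(tok)


def _parse_int(tok: str) -> int | None:
    return None if tok == MISSING or tok == "" else int(tok)


def _fmt(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, float):
        return repr(value)
    return str(value)


def read_summary_stats(
    path,
    schema: Mapping[str, str] | None = None,
    trait_meta: TraitSummary | None = None,
    check_pval_consistency: bool = False,
) -> TraitSummary:
    """Read a tab-separated summary-statistics table into a :class:`TraitSummary`.

    Parameters
    ----------
    path : str or Path
        File to read.
    schema : mapping, optional
        Maps canonical column names (:data:`SS_COLUMNS`) to the file's column
        names.  Unmapped canonical names are looked up under their own name.
    trait_meta : TraitSummary, optional
        Template carrying trait_id/label/type/source; records are ignored.

    Rows violating hard invariants (se <= 0, p outside (0, 1], malformed
    alleles) are dropped and counted in the log, per-record; a missing
    mandatory column raises :class:`SchemaError` naming the column.
    """
    schema = dict(schema or {})
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise EmptyInputError(f"{path}: empty summary-statistics file")
        header = header_line.rstrip("\n").split("\t")
        colidx: dict[str, int] = {}
        mandatory = ["variant_id", "effect_allele", "other_allele", "beta", "standard_error", "p_value"]
        for canon in SS_COLUMNS:
            name = schema.get(canon, canon)
            if name in header:
                colidx[canon] = header.index(name)
            elif canon in mandatory:
                raise SchemaError(f"{path}: mandatory column {name!r} (for {canon!r}) not found")

        meta = trait_meta or TraitSummary(trait_id=str(path))
        ts = TraitSummary(
            trait_id=meta.trait_id,
            trait_label=meta.trait_label,
            trait_type=meta.trait_type,
            source=meta.source,
        )

        def get(row, canon, default=MISSING):
            i = colidx.get(canon)
            return row[i] if i is not None and i < len(row) else default

        dropped = 0
        inconsistent = 0
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            row = line.split("\t")
            try:
                rec = VariantAssociation(
                    variant_id=get(row, "variant_id"),
                    chrom=str(get(row, "chromosome", MISSING)),
                    pos=_parse_int(get(row, "base_pair_location", MISSING)) or 0,
                    effect_allele=get(row, "effect_allele").upper(),
                    other_allele=get(row, "other_allele").upper(),
                    eaf=_parse_float(get(row, "effect_allele_frequency")),
                    beta=_parse_float(get(row, "beta")),
                    se=_parse_float(get(row, "standard_error")),
                    pval=_parse_float(get(row, "p_value")),
                    n=_parse_int(get(row, "n")) or 0,
                    n_case=_parse_int(get(row, "n_case")),
                    n_control=_parse_int(get(row, "n_control")),
                )
            except (ValueError, TypeError):
                dropped += 1
                continue
            if rec.beta is None or rec.se is None or rec.pval is None or not rec.is_valid():
                dropped += 1
                continue
            if check_pval_consistency and not rec.pval_consistent():
                inconsistent += 1
            if rec.variant_id in ts.records:
                dropped += 1
                continue
            ts.records[rec.variant_id] = rec

    if dropped:
        logger.warning("%s: dropped %d rows violating hard invariants", path, dropped)
    if inconsistent:
        logger.warning(
            "%s: %d rows have p-values inconsistent with beta/se under the normal approximation",
            path,
            inconsistent,
        )
    ts.n_dropped = dropped  # type: ignore[attr-defined]
    return ts


def write_summary_stats(ts: TraitSummary, path) -> str:
    """Write a :class:`TraitSummary` as a tab-separated table.

    The header is always the full fixed :data:`SS_COLUMNS`; missing values
    are written as ``.``; floats use ``repr`` so the round trip is bit-exact.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(SS_COLUMNS) + "\n")
        for rec in ts.records.values():
            fields = [
                rec.variant_id,
                rec.chrom,
                str(rec.pos),
                rec.effect_allele,
                rec.other_allele,
                _fmt(rec.eaf),
                _fmt(rec.beta),
                _fmt(rec.se),
                _fmt(rec.pval),
                str(rec.n),
                _fmt(rec.n_case),
                _fmt(rec.n_control),
            ]
            fh.write("\t".join(fields) + "\n")
    return str(path)


# ---------------------------------------------------------------------------
# Harmonization


def _harmonize_one(e: VariantAssociation, o: VariantAssociation, palindrome_eaf_limit: float) -> HarmonizedPair:
    def dropped(action: str) -> HarmonizedPair:
        return HarmonizedPair(e.variant_id, None, None, None, None, action_taken=action)

    def kept(flip: bool) -> HarmonizedPair:
        beta_out = -o.beta if flip else o.beta
        eaf_out = (1.0 - o.eaf) if (flip and o.eaf is not None) else o.eaf
        return HarmonizedPair(
            e.variant_id,
            e.beta,
            e.se,
            beta_out,
            o.se,
            eaf_exp=e.eaf,
            eaf_out=eaf_out,
            action_taken="flipped" if flip else "kept",
        )

    ea, oa = e.effect_allele, e.other_allele
    eb, ob = o.effect_allele, o.other_allele

    if e.is_palindromic():
        if {eb, ob} != {ea, oa}:
            return dropped("dropped_incompatible")
        # Label alignment first, then the frequency sanity rule.
        flip = (eb, ob) == (oa, ea)
        if e.eaf is None or o.eaf is None:
            return dropped("dropped_palindromic")
        eaf_out_aligned = 1.0 - o.eaf if flip else o.eaf
        same_side = (e.eaf - 0.5) * (eaf_out_aligned - 0.5) > 0
        maf_ok = (
            min(e.eaf, 1 - e.eaf) < palindrome_eaf_limit
            and min(eaf_out_aligned, 1 - eaf_out_aligned) < palindrome_eaf_limit
        )
        if same_side and maf_ok:
            return kept(flip)
        return dropped("dropped_palindromic")

    if (eb, ob) == (ea, oa):
        return kept(flip=False)
    if (eb, ob) == (oa, ea):
        return kept(flip=True)
    cb, cob = _complement(eb), _complement(ob)
    if cb is not None and cob is not None:
        if (cb, cob) == (ea, oa):
            return kept(flip=False)
        if (cb, cob) == (oa, ea):
            return kept(flip=True)
    return dropped("dropped_incompatible")


def harmonize(
    exposure: TraitSummary,
    outcome: TraitSummary,
    palindrome_eaf_limit: float = 0.42,
) -> list[HarmonizedPair]:
    """Orient outcome records to the exposure's effect alleles.

    Returns one :class:`HarmonizedPair` per shared variant_id, in the
    exposure's record order.  Degenerate overlaps yield an empty list.
    """
    out: list[HarmonizedPair] = []
    for vid, e in exposure.records.items():
        o = outcome.records.get(vid)
        if o is None:
            continue
        out.append(_harmonize_one(e, o, palindrome_eaf_limit))
    return out


def kept_pairs(pairs: Iterable[HarmonizedPair]) -> list[HarmonizedPair]:
    """Subset of harmonized pairs that carry estimates (kept or flipped)."""
    return [p for p in pairs if p.kept]
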