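"""Family-wise (Bonferroni) and FDR (Benjamini-Hochberg) multiplicity control.

Families are explicit: the microbiota-metabolite-epilepsy scan corrects
within three panels (871 identified metabolites, 207 shotgun-metagenomic
taxa, 196 16S core taxa), and the clinical arm applies BH-FDR within the
sphingomyelin feature panel only.  Scoping is always the caller's choice;
nothing here ever pools p-values across families implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, EmptyInputError


@dataclass
class TestFamily:
    """A named family of tests sharing one family-wise alpha."""

    __test__ = False  # not a pytest class, despite the name

    family_id: str
    pvals: list[tuple[str, float]] = field(default_factory=list)
    alpha_fw: float = 0.05

    def __post_init__(self):
        for tid, p in self.pvals:
            if not (0 < p <= 1):
                raise DomainError(f"{self.family_id}/{tid}: p={p} outside (0, 1]")

    def __len__(self) -> int:
        return len(self.pvals)

    def bonferroni_threshold(self) -> float:
        if not self.pvals:
            raise EmptyInputError(f"family {self.family_id} is empty")
        return bonferroni_alpha(len(self.pvals), self.alpha_fw)

    def qvalues(self) -> list[tuple[str, float]]:
        qs = bh_fdr([p for _, p in self.pvals])
        return [(tid, q) for (tid, _), q in zip(self.pvals, qs)]


def bonferroni_alpha(m: int, alpha_fw: float = 0.05) -> float:
    """Per-test threshold alpha_fw / m controlling the family-wise error rate."""
    if m < 1:
        raise DomainError(f"family size m must be >= 1, got {m}")
    if not (0 < alpha_fw <= 1):
        raise DomainError(f"alpha_fw must be in (0, 1], got {alpha_fw}")
    return alpha_fw / m


def bh_fdr(pvals) -> list[float]:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} m * p_(j) / j over the ascending order statistics,
    capped at 1; standard step-up with no special tie handling.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise DomainError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q.tolist()
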