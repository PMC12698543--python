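"""Shared fixtures: tiny hand-built traits and harmonized pairs."""

import numpy as np
import pytest

from medmr.gwas_io import HarmonizedPair, TraitSummary, VariantAssociation
from medmr.instruments import LDMatrix


def make_variant(
    vid="rs1",
    chrom="1",
    pos=1000,
    ea="A",
    oa="G",
    beta=0.1,
    se=0.02,
    pval=1e-8,
    n=10000,
    eaf=0.3,
    **kw,
):
    return VariantAssociation(
        variant_id=vid, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        beta=beta, se=se, pval=pval, n=n, eaf=eaf, **kw,
    )


def make_trait(records, trait_id="trait", trait_type="continuous"):
    ts = TraitSummary(trait_id=trait_id, trait_type=trait_type)
    for r in records:
        ts.add(r)
    return ts


def random_trait(rng, m=20, trait_id="trait"):
    ts = TraitSummary(trait_id=trait_id)
    for j in range(m):
        beta = rng.normal(0, 0.1)
        se = abs(rng.normal(0.02, 0.005)) + 1e-3
        ts.add(
            make_variant(
                vid=f"rs{j + 1}",
                chrom=str(rng.integers(1, 4)),
                pos=int(rng.integers(1, 10**7)),
                beta=beta,
                se=se,
                pval=float(min(1.0, max(np.exp(-abs(beta / se)), 1e-30))),
                eaf=float(rng.uniform(0.05, 0.95)),
                n=int(rng.integers(1000, 50000)),
            )
        )
    return ts


def make_pairs(bx, by, sy, sx=None):
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, float)
    return [
        HarmonizedPair(f"rs{i + 1}", float(bx[i]), float(sx[i]), float(by[i]), float(sy[i]))
        for i in range(len(bx))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def identity_ld():
    def _make(ids):
        return LDMatrix.identity(list(ids))

    return _make
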