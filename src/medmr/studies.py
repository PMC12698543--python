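"""Registry of the GWAS data sources the pipeline was designed around.

These are published cohort descriptors (taxonomic-rank composition of the
two microbiome GWAS panels, metabolite panel size, and the FinnGen R9
epilepsy endpoints with case/control splits).  They parameterize
multiplicity families and sanity checks; none of the underlying summary
statistics ship with the package.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Dutch Microbiome Project (shotgun metagenomics, 7,738 participants):
#: taxon-abundance traits retained after excluding functional pathways.
DMP_RANK_COUNTS: dict[str, int] = {
    "phylum": 5,
    "class": 10,
    "order": 13,
    "family": 26,
    "genus": 48,
    "species": 105,
}

#: MiBioGen consortium (16S rRNA, 18,340 participants): core-taxa panel
#: before prevalence/annotation filtering (no species rank in 16S data).
MIBIOGEN_CORE_RANK_COUNTS: dict[str, int] = {
    "phylum": 9,
    "class": 16,
    "order": 20,
    "family": 35,
    "genus": 131,
}

#: MiBioGen taxa retained for analysis after filtering.
MIBIOGEN_ANALYZED_TAXA = 196

#: Identified blood metabolites retained from the metabolome-wide GWAS
#: (unidentified compounds and metabolite ratios excluded).
METABOLITE_PANEL_SIZE = 871

#: Metabolome-wide GWAS cohort size.
METABOLOME_N = 8299


@dataclass(frozen=True)
class BinaryEndpoint:
    """A case/control GWAS endpoint."""

    trait_id: str
    label: str
    n: int
    n_case: int
    n_control: int

    @property
    def case_control_sum(self) -> int:
        return self.n_case + self.n_control


#: FinnGen release R9 epilepsy endpoints (ICD-10 G40).
FINNGEN_R9_ENDPOINTS: dict[str, BinaryEndpoint] = {
    "epilepsy": BinaryEndpoint("epilepsy", "Epilepsy", 299_577, 11_740, 287_837),
    "generalized_epilepsy": BinaryEndpoint(
        "generalized_epilepsy", "Generalized epilepsy", 366_832, 1_298, 365_534
    ),
    "focal_epilepsy": BinaryEndpoint("focal_epilepsy", "Focal epilepsy", 372_379, 6_842, 365_537),
}


def dmp_taxa_total() -> int:
    """Total DMP taxon-abundance traits (sum over taxonomic ranks)."""
    return sum(DMP_RANK_COUNTS.values())


def mibiogen_core_taxa_total() -> int:
    """Total MiBioGen core taxa before filtering."""
    return sum(MIBIOGEN_CORE_RANK_COUNTS.values())
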