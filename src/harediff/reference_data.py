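"""Reference data for the brown-hare lineage-differentiation analysis.

The European and Anatolian lineages of *Lepus europaeus* carry fixed mtDNA
differences, and the published comparison of their transcriptomes centres on
the genes of cellular energetics: glycolysis and the Krebs cycle (purely
nuclear) versus the OXPHOS machinery, whose five complexes mix nuclear- and
mtDNA-encoded subunits.  This module packages three small reference objects
used throughout the pipeline and its tests:

* the energy-production gene sets, split per OXPHOS complex and by genome of
  origin (mtDNA-encoded subunits use the vertebrate mitochondrial code);
* the published per-gene-set differentiating-mutation rates (mutations per
  nucleotide, total and non-synonymous) for the European-vs-Anatolian
  contrast, which serve both as worked-example inputs for fold-change
  contrasts and as default planted rates for the synthetic generator;
* the table of RNA-seq SNPs that were re-genotyped by Sanger sequencing in
  independent individuals of the two lineages.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping

import pandas as pd

#: Energy-production gene sets.  A gene may belong to more than one set
#: (SDHA is both a Krebs-cycle enzyme and a complex II subunit).
ENERGY_GENE_SETS: Mapping[str, tuple[str, ...]] = {
    "glycolysis": (
        "HK1", "GPI", "PFKL", "ALDOA", "TPI1",
        "GAPDH", "PGK1", "PGAM1", "PKM", "ENO1",
    ),
    "krebs": (
        "ACO2", "CS", "FH", "IDH2", "MDH1", "OGDH", "SDHA", "SUCLA2",
    ),
    "complex_I_nuclear": (
        "NDUFV1", "NDUFV2", "NDUFS1", "NDUFS2", "NDUFS3", "NDUFS7",
        "NDUFS8", "NDUFV3", "NDUFS4", "NDUFS5", "NDUFS6", "NDUFA1",
        "NDUFA2", "NDUFA3", "NDUFA4", "NDUFA5", "NDUFA6", "NDUFA7",
        "NDUFA8", "NDUFA9", "NDUFA11", "NDUFA12", "NDUFA13", "NDUFAB1",
        "NDUFB1", "NDUFB2", "NDUFB3", "NDUFB4", "NDUFB5", "NDUFB6",
        "NDUFB7", "NDUFB8", "NDUFB9", "NDUFB10", "NDUFB11", "NDUFC1",
        "NDUFC2",
    ),
    "complex_I_mt": ("ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6"),
    "complex_II_nuclear": ("SDHA", "SDHB", "SDHC", "SDHD"),
    "complex_III_nuclear": (
        "CYC1", "UQCRC1", "UQCRC2", "UQCRFS1", "UQCRH", "UQCRQ",
    ),
    "complex_III_mt": ("CYTB",),
    "complex_IV_nuclear": (
        "COX4I1", "COX5B", "COX6A2", "COX6B1", "COX6C", "COX7A2",
    ),
    "complex_IV_mt": ("COXI", "COXII", "COXIII"),
    "complex_V_nuclear": (
        "ATP5A1", "ATP5B", "ATP5C1", "ATP5D", "ATP5F1", "ATP5G1",
        "ATP5G2", "ATP5H", "ATP5J2", "ATP5L", "ATP5O", "ATP5S",
    ),
    "complex_V_mt": ("ATP6", "ATP8"),
}

#: The 13 mtDNA-encoded protein-coding genes (translated with the
#: vertebrate mitochondrial code; everything else is nuclear).
MITOCHONDRIAL_GENES: frozenset[str] = frozenset(
    ENERGY_GENE_SETS["complex_I_mt"]
    + ENERGY_GENE_SETS["complex_III_mt"]
    + ENERGY_GENE_SETS["complex_IV_mt"]
    + ENERGY_GENE_SETS["complex_V_mt"]
)

#: Derived union sets used for the headline contrasts.
AGGREGATE_GENE_SETS: Mapping[str, tuple[str, ...]] = {
    "oxphos_nuclear": tuple(
        g
        for name in (
            "complex_I_nuclear", "complex_II_nuclear", "complex_III_nuclear",
            "complex_IV_nuclear", "complex_V_nuclear",
        )
        for g in ENERGY_GENE_SETS[name]
    ),
    "oxphos_mt": tuple(sorted(MITOCHONDRIAL_GENES)),
}
AGGREGATE_GENE_SETS = {
    **AGGREGATE_GENE_SETS,
    "oxphos": AGGREGATE_GENE_SETS["oxphos_nuclear"]
    + AGGREGATE_GENE_SETS["oxphos_mt"],
}

#: Published differentiating-mutation rates (per nucleotide) between the
#: European and Anatolian hare lineages: {set: (total, non-synonymous)}.
PUBLISHED_RATES: Mapping[str, tuple[float, float]] = {
    "glycolysis": (0.004685, 0.000344),
    "krebs": (0.004060, 0.000451),
    "oxphos": (0.008056, 0.001258),
    "oxphos_nuclear": (0.003691, 0.001212),
    "oxphos_mt": (0.022641, 0.001409),
    "complex_I_nuclear": (0.003900, 0.001282),
    "complex_I_mt": (0.020899, 0.001583),
    "complex_II_nuclear": (0.005405, 0.000257),
    "complex_III_nuclear": (0.003373, 0.000930),
    "complex_III_mt": (0.033333, 0.001754),
    "complex_IV_nuclear": (0.005391, 0.003732),
    "complex_IV_mt": (0.016943, 0.000664),
    "complex_V_nuclear": (0.001978, 0.000923),
    "complex_V_mt": (0.040677, 0.002259),
}


def genome_of(gene_id: str) -> str:
    """Genome of origin for a reference gene id."""
    return "mitochondrial" if gene_id in MITOCHONDRIAL_GENES else "nuclear"


def gene_set_membership(
    gene_sets: Mapping[str, tuple[str, ...]] | None = None,
) -> dict[str, frozenset[str]]:
    """Invert set -> members into gene -> set labels."""
    sets = ENERGY_GENE_SETS if gene_sets is None else gene_sets
    members: dict[str, set[str]] = {}
    for name, genes in sets.items():
        for g in genes:
            members.setdefault(g, set()).add(name)
    return {g: frozenset(s) for g, s in members.items()}


def sanger_validated_sites() -> pd.DataFrame:
    """RNA-seq SNPs re-genotyped by Sanger sequencing.

    Columns: gene, position (1-based on the CDS), ref, alt (``/``-separated
    when multi-allelic), and the observed allele calls per lineage from
    RNA-seq and from Sanger re-sequencing of independent individuals.
    """
    with resources.files("harediff").joinpath(
        "data/sanger_validated_snps.tsv"
    ).open("r") as fh:
        return pd.read_csv(fh, sep="\t", dtype={"position": int})
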