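"""Codon-level effect classification of variants.

Each (site, alt allele) pair is classified as synonymous, non-synonymous,
nonsense (premature stop gained), or an indel (frameshift when the length
change is not a multiple of three, in-frame otherwise).  The translation
table follows the gene's genome of origin: nuclear genes use the standard
code, mtDNA-encoded genes the vertebrate mitochondrial code — the two
differ exactly where it matters for OXPHOS subunits (e.g. TGA is Trp, not
stop, in the mitochondrial code, and AGA/AGG are stops, not Arg).

Stop-loss substitutions (reference codon is a stop, the alternative is
not) are grouped with the non-synonymous class: they alter the protein.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

from .variant_model import (
    Allele,
    GeneRecord,
    VariantModelError,
    VariantSite,
)


class Effect(str, enum.Enum):
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    NONSENSE = "nonsense"
    INDEL_FRAMESHIFT = "indel_frameshift"
    INDEL_INFRAME = "indel_inframe"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def is_protein_changing(self) -> bool:
        return self is not Effect.SYNONYMOUS


@dataclass(frozen=True)
class CodonContext:
    """Where in the reading frame a substitution lands (1-based throughout)."""

    codon_index: int
    offset_in_codon: int
    ref_codon: str
    alt_codon: str
    table: str  # "standard" | "vertebrate_mitochondrial"


_TABLE_NAMES = {1: "standard", 2: "vertebrate_mitochondrial"}


def translate_codon(codon: str, table_id: int) -> str:
    """Single-codon translation; stops come back as ``*``."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    codon = codon.upper()
    if codon in table.stop_codons:
        return "*"
    try:
        return table.forward_table[codon]
    except KeyError:
        raise VariantModelError(f"cannot translate codon {codon!r}") from None


def _substitution_effect(ref_codon: str, alt_codon: str, table_id: int) -> Effect:
    aa_ref = translate_codon(ref_codon, table_id)
    aa_alt = translate_codon(alt_codon, table_id)
    if aa_ref == aa_alt:
        return Effect.SYNONYMOUS
    if aa_alt == "*":
        return Effect.NONSENSE
    return Effect.NONSYNONYMOUS


def classify_effect(
    gene: GeneRecord, site: VariantSite, alt: Allele
) -> Effect:
    """Effect class of one alternative allele at one site."""
    effect, _ = classify_with_context(gene, site, alt)
    return effect


def classify_with_context(
    gene: GeneRecord, site: VariantSite, alt: Allele
) -> tuple[Effect, CodonContext | None]:
    """Effect class plus the codon context (``None`` for indels)."""
    ref = site.ref
    pos = site.position
    if pos + len(ref) - 1 > gene.length:
        raise VariantModelError(
            f"{gene.gene_id}: site at {pos} (ref {ref}) beyond CDS of "
            f"{gene.length} nt"
        )
    observed = gene.cds[pos - 1 : pos - 1 + len(ref)]
    if observed != ref.value:
        raise VariantModelError(
            f"{gene.gene_id}:{pos}: reference mismatch, expected "
            f"{ref.value!r} but CDS has {observed!r}"
        )

    if len(alt) != len(ref):
        shift = abs(len(alt) - len(ref))
        return (
            Effect.INDEL_FRAMESHIFT if shift % 3 else Effect.INDEL_INFRAME,
            None,
        )

    # Same-length substitution; classify over the affected codon span.
    first_codon = (pos - 1) // 3 + 1
    last_codon = (pos + len(ref) - 2) // 3 + 1
    span_start = (first_codon - 1) * 3
    span_end = last_codon * 3
    if span_end > gene.length:
        raise VariantModelError(
            f"{gene.gene_id}:{pos}: substitution spans past the last codon"
        )
    ref_span = gene.cds[span_start:span_end]
    offset = pos - 1 - span_start
    alt_span = ref_span[:offset] + alt.value + ref_span[offset + len(alt):]

    effects = {
        _substitution_effect(
            ref_span[i : i + 3], alt_span[i : i + 3], gene.table_id
        )
        for i in range(0, len(ref_span), 3)
    }
    if Effect.NONSENSE in effects:
        effect = Effect.NONSENSE
    elif Effect.NONSYNONYMOUS in effects:
        effect = Effect.NONSYNONYMOUS
    else:
        effect = Effect.SYNONYMOUS

    context = CodonContext(
        codon_index=first_codon,
        offset_in_codon=(pos - 1) % 3 + 1,
        ref_codon=ref_span[:3],
        alt_codon=alt_span[:3],
        table=_TABLE_NAMES[gene.table_id],
    )
    return effect, context


@dataclass
class Annotation:
    site: VariantSite
    alt: Allele
    effect: Effect
    context: CodonContext | None


def annotate_all(
    sites: Sequence[VariantSite],
    genes: Mapping[str, GeneRecord],
) -> list[Annotation]:
    """One annotation row per (site, alt) pair; multi-allelic sites fan out."""
    rows: list[Annotation] = []
    for site in sites:
        gene = genes.get(site.gene_id)
        if gene is None:
            raise VariantModelError(
                f"no gene record for {site.gene_id} (site at {site.position})"
            )
        for alt in site.alts:
            effect, context = classify_with_context(gene, site, alt)
            rows.append(Annotation(site, alt, effect, context))
    return rows


def annotations_to_frame(annotations: Iterable[Annotation]) -> pd.DataFrame:
    """Flatten annotations to the TSV-ready table."""
    records = []
    for ann in annotations:
        ctx = ann.context
        records.append(
            {
                "gene_id": ann.site.gene_id,
                "position": ann.site.position,
                "ref": str(ann.site.ref),
                "alt": str(ann.alt),
                "effect": ann.effect.value,
                "codon_index": None if ctx is None else ctx.codon_index,
                "ref_codon": None if ctx is None else ctx.ref_codon,
                "alt_codon": None if ctx is None else ctx.alt_codon,
                "table": None if ctx is None else ctx.table,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "gene_id", "position", "ref", "alt", "effect",
            "codon_index", "ref_codon", "alt_codon", "table",
        ],
    )
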