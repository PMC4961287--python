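"""Per-gene-set differentiating-mutation rates and fold-change contrasts.

The statistic is deliberately simple: for a gene set, the number of
differentiating sites in member genes divided by the summed analysed CDS
length of those genes (mutations per nucleotide), computed once for all
differentiating sites and once restricted to protein-changing ones.  The
non-synonymous rate uses the same nucleotide denominator — this is not a
dN/dS-style per-site normalisation.  Nonsense substitutions count as
non-synonymous (they change the protein); indels count in the total
numerator only, by default.

A site lying in a gene that belongs to several sets contributes to every
one of those sets' rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .effect_annotation import Annotation, Effect
from .variant_model import GeneRecord

#: Effects counted in the non-synonymous numerator.
PROTEIN_CHANGING_SNV = frozenset({Effect.NONSYNONYMOUS, Effect.NONSENSE})
INDEL_EFFECTS = frozenset({Effect.INDEL_FRAMESHIFT, Effect.INDEL_INFRAME})


@dataclass
class RateRow:
    gene_set: str
    total_sites: int
    nonsyn_sites: int
    denominator_nt: int

    @property
    def defined(self) -> bool:
        return self.denominator_nt > 0

    @property
    def total_rate(self) -> float:
        return self.total_sites / self.denominator_nt if self.defined else math.nan

    @property
    def nonsyn_rate(self) -> float:
        return self.nonsyn_sites / self.denominator_nt if self.defined else math.nan


@dataclass
class RateTable:
    """Rows keyed by gene-set label; the central rate object."""

    rows: dict[str, RateRow]

    def __getitem__(self, key: str) -> RateRow:
        return self.rows[key]

    def __contains__(self, key: str) -> bool:
        return key in self.rows

    def labels(self) -> list[str]:
        return list(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_set": r.gene_set,
                    "total_sites": r.total_sites,
                    "nonsyn_sites": r.nonsyn_sites,
                    "denominator_nt": r.denominator_nt,
                    "total_rate": r.total_rate,
                    "nonsyn_rate": r.nonsyn_rate,
                }
                for r in self.rows.values()
            ]
        )

    @classmethod
    def from_rates(
        cls,
        rates: Mapping[str, tuple[float, float]],
        denominator_nt: int = 1_000_000,
    ) -> "RateTable":
        """Build a table from published (total, nonsyn) per-nt rates.

        Counts are synthesised against a nominal denominator so that
        ``rate x denominator`` reproduces the printed rates; used to feed
        published tables through the contrast machinery.
        """
        rows = {}
        for name, (total, nonsyn) in rates.items():
            rows[name] = RateRow(
                gene_set=name,
                total_sites=round(total * denominator_nt),
                nonsyn_sites=round(nonsyn * denominator_nt),
                denominator_nt=denominator_nt,
            )
        return cls(rows)


def compute_rates(
    annotations: Sequence[Annotation],
    genes: Mapping[str, GeneRecord],
    gene_sets: Mapping[str, Iterable[str]],
    include_indels_in_nonsyn: bool = False,
) -> RateTable:
    """Tabulate differentiating-site rates per gene set.

    ``annotations`` should already be restricted to differentiating sites
    (the caller chooses the stringent or the 50% path).  A multi-allelic
    site counts once in the total numerator and counts as non-synonymous if
    any of its alternative alleles is protein-changing.
    """
    nonsyn_effects = set(PROTEIN_CHANGING_SNV)
    if include_indels_in_nonsyn:
        nonsyn_effects |= INDEL_EFFECTS

    per_site: dict[tuple[str, int], bool] = {}
    for ann in annotations:
        key = ann.site.key()
        is_ns = ann.effect in nonsyn_effects
        per_site[key] = per_site.get(key, False) or is_ns

    per_gene_total: dict[str, int] = {}
    per_gene_nonsyn: dict[str, int] = {}
    for (gene_id, _), is_ns in per_site.items():
        per_gene_total[gene_id] = per_gene_total.get(gene_id, 0) + 1
        if is_ns:
            per_gene_nonsyn[gene_id] = per_gene_nonsyn.get(gene_id, 0) + 1

    rows: dict[str, RateRow] = {}
    for set_name, members in gene_sets.items():
        member_list = [g for g in members if g in genes]
        denom = sum(genes[g].length for g in member_list)
        total = sum(per_gene_total.get(g, 0) for g in member_list)
        nonsyn = sum(per_gene_nonsyn.get(g, 0) for g in member_list)
        rows[set_name] = RateRow(
            gene_set=set_name,
            total_sites=total,
            nonsyn_sites=nonsyn,
            denominator_nt=denom,
        )
    return RateTable(rows)


def fold_change(
    numerator_rate: float, denominator_rate: float, decimals: int = 1
) -> float | None:
    """Ratio of two rates, rounded half-up; ``None`` when undefined."""
    if denominator_rate is None or numerator_rate is None:
        return None
    if (
        math.isnan(denominator_rate)
        or math.isnan(numerator_rate)
        or denominator_rate <= 0
    ):
        return None
    ratio = Decimal(repr(numerator_rate)) / Decimal(repr(denominator_rate))
    quantum = Decimal(1).scaleb(-decimals)
    return float(ratio.quantize(quantum, rounding=ROUND_HALF_UP))


#: The headline contrasts: OXPHOS (nuclear and mtDNA) and each complex,
#: against the two purely nuclear pathways.
DEFAULT_CONTRASTS: tuple[tuple[str, str], ...] = tuple(
    (num, den)
    for num in (
        "oxphos", "oxphos_nuclear", "oxphos_mt",
        "complex_I_nuclear", "complex_I_mt",
        "complex_II_nuclear",
        "complex_III_nuclear", "complex_III_mt",
        "complex_IV_nuclear", "complex_IV_mt",
        "complex_V_nuclear", "complex_V_mt",
    )
    for den in ("glycolysis", "krebs")
)


def contrast_report(
    table: RateTable,
    contrasts: Sequence[tuple[str, str]] = DEFAULT_CONTRASTS,
    decimals: int = 1,
) -> pd.DataFrame:
    """Fold changes (total and non-synonymous) for each requested pair."""
    records = []
    for num, den in contrasts:
        if num not in table or den not in table:
            missing = [x for x in (num, den) if x not in table]
            raise KeyError(f"unknown rate-table row(s): {missing}")
        a, b = table[num], table[den]
        records.append(
            {
                "numerator": num,
                "denominator": den,
                "total_fold": fold_change(a.total_rate, b.total_rate, decimals),
                "nonsyn_fold": fold_change(a.nonsyn_rate, b.nonsyn_rate, decimals),
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["numerator", "denominator", "total_fold", "nonsyn_fold"]
    )
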