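"""One-to-one homolog selection over precomputed alignment hit tables.

Given tabular protein-alignment hits (query transcript against a reference
proteome), the selection keeps, per query, the hit with the highest bit
score; collapses queries sharing a best-hit subject gene down to the query
with the longest CDS (assembly fragments of one gene should map once); and
finally requires reciprocal query/subject coverage of at least 70%.  The
result is injective on subject genes.

All ties are broken deterministically — higher coverage sum, then
lexicographic id — so shuffling input rows never changes the mapping.
This module never runs an aligner; it only consumes hit tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from os import PathLike
from typing import IO, Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

HIT_COLUMNS = [
    "query_id", "subject_id", "subject_gene_id", "bit_score", "e_value",
    "query_coverage", "subject_coverage", "query_cds_length",
]


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    subject_gene_id: str
    bit_score: float
    e_value: float
    query_coverage: float
    subject_coverage: float
    query_cds_length: int

    def __post_init__(self) -> None:
        if not 0 <= self.query_coverage <= 1 or not 0 <= self.subject_coverage <= 1:
            raise ValueError(
                f"{self.query_id}->{self.subject_id}: coverages must lie in [0, 1]"
            )
        if self.bit_score < 0:
            raise ValueError("bit score must be >= 0")


def read_hits_table(source: str | PathLike | IO) -> list[HomologyHit]:
    """Read a TSV hit table with the :data:`HIT_COLUMNS` columns."""
    table = pd.read_csv(source, sep="\t")
    missing = set(HIT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    return [
        HomologyHit(
            query_id=str(r.query_id),
            subject_id=str(r.subject_id),
            subject_gene_id=str(r.subject_gene_id),
            bit_score=float(r.bit_score),
            e_value=float(r.e_value),
            query_coverage=float(r.query_coverage),
            subject_coverage=float(r.subject_coverage),
            query_cds_length=int(r.query_cds_length),
        )
        for r in table.itertuples()
    ]


def _best_hit_per_query(hits: Iterable[HomologyHit]) -> dict[str, HomologyHit]:
    def rank(h: HomologyHit) -> tuple:
        # Higher bit score wins; ties by higher coverage sum, then
        # lexicographic subject id (both levels logged when exercised).
        return (
            -h.bit_score,
            -(h.query_coverage + h.subject_coverage),
            h.subject_id,
        )

    best: dict[str, HomologyHit] = {}
    for h in sorted(hits, key=lambda h: (h.query_id,) + rank(h)):
        if h.query_id not in best:
            best[h.query_id] = h
        elif best[h.query_id].bit_score == h.bit_score:
            logger.debug(
                "bit-score tie for %s resolved toward %s",
                h.query_id, best[h.query_id].subject_id,
            )
    return best


def _dedupe_subject_genes(best: dict[str, HomologyHit]) -> dict[str, HomologyHit]:
    def rank(h: HomologyHit) -> tuple:
        # Longest CDS wins; ties by higher coverage sum, then query id.
        return (
            -h.query_cds_length,
            -(h.query_coverage + h.subject_coverage),
            h.query_id,
        )

    kept: dict[str, HomologyHit] = {}
    for h in sorted(best.values(), key=lambda h: (h.subject_gene_id,) + rank(h)):
        if h.subject_gene_id not in kept:
            kept[h.subject_gene_id] = h
    return {h.query_id: h for h in kept.values()}


def select_one_to_one(
    hits: Sequence[HomologyHit],
    min_coverage: float = 0.70,
    max_evalue: float = 1e-10,
    coverage_before_dedupe: bool = False,
) -> dict[str, str]:
    """Select a 1:1 query -> subject-gene mapping.

    Steps: e-value filter; best hit per query by bit score; longest-CDS
    de-duplication of queries sharing a subject gene; reciprocal coverage
    filter (``>= min_coverage`` on both sides).  Setting
    ``coverage_before_dedupe`` applies the coverage filter before the
    de-duplication step instead of after.
    """

    def coverage_ok(h: HomologyHit) -> bool:
        return (
            h.query_coverage >= min_coverage
            and h.subject_coverage >= min_coverage
        )

    pool = [h for h in hits if h.e_value <= max_evalue]
    if coverage_before_dedupe:
        pool = [h for h in pool if coverage_ok(h)]
    best = _best_hit_per_query(pool)
    deduped = _dedupe_subject_genes(best)
    if not coverage_before_dedupe:
        deduped = {q: h for q, h in deduped.items() if coverage_ok(h)}
    return {q: h.subject_gene_id for q, h in sorted(deduped.items())}


def write_mapping(mapping: dict[str, str], path: str | PathLike) -> None:
    pd.DataFrame(
        sorted(mapping.items()), columns=["query_id", "subject_gene_id"]
    ).to_csv(path, sep="\t", index=False)
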