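"""Core data types for pooled variant observations and their file formats.

The pipeline treats a pool of individuals sequenced as one library as a
single sample of higher ploidy: three diploid hares pooled together are
genotyped as one hexaploid (ploidy 6).  A :class:`PooledGenotype` is the
caller's multiset of allele indices for such a sample, and a
:class:`VariantSite` collects the per-pool observations (genotype, allele
read depths, call and mapping quality) at one 1-based position of a coding
sequence.

VCF conventions: ``CHROM`` is the gene/CDS id, ``POS`` the 1-based CDS
coordinate, ``GT`` carries ploidy-many slash-separated allele indices,
``AD`` per-allele read depths, ``GQ`` genotype quality, and ``MQ``/``MQ0``
the mapping-quality annotations used by the site-level pre-filter.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")

#: NCBI translation table ids per genome of origin.
TRANSLATION_TABLES = {"nuclear": 1, "mitochondrial": 2}


class VariantModelError(ValueError):
    """Malformed variant, gene or table input."""


@dataclass(frozen=True, order=True)
class Allele:
    """A nucleotide allele; length > 1 (or ref/alt length mismatch) marks an indel."""

    value: str

    def __post_init__(self) -> None:
        if not self.value:
            raise VariantModelError("allele must be non-empty")
        bad = set(self.value.upper()) - NUCLEOTIDES
        if bad:
            raise VariantModelError(
                f"allele {self.value!r} contains non-ACGT characters {sorted(bad)}"
            )
        object.__setattr__(self, "value", self.value.upper())

    def __len__(self) -> int:
        return len(self.value)

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class PooledGenotype:
    """Multiset of allele indices called for one pool (canonical sorted order)."""

    allele_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.allele_indices:
            raise VariantModelError("genotype must contain at least one allele")
        if any(i < 0 for i in self.allele_indices):
            raise VariantModelError("allele indices must be non-negative")
        object.__setattr__(
            self, "allele_indices", tuple(sorted(self.allele_indices))
        )

    @property
    def ploidy(self) -> int:
        return len(self.allele_indices)

    def allele_set(self) -> frozenset[int]:
        return frozenset(self.allele_indices)

    def count(self, index: int) -> int:
        return self.allele_indices.count(index)


@dataclass
class SiteObservation:
    """One pool's evidence at one site.

    ``total_depth`` (DP) and the sum of ``allele_depths`` (AD) are both
    recorded because caller conventions differ on whether DP includes
    uninformative reads.  Missing annotations stay ``None`` — absent is not
    zero.  ``site_quality`` is the record QUAL; ``genotype_quality`` the
    per-sample GQ, when present.
    """

    pool_id: str
    genotype: PooledGenotype | None
    allele_depths: dict[int, int] = field(default_factory=dict)
    total_depth: int | None = None
    site_quality: float | None = None
    genotype_quality: float | None = None
    mapping_quality: float | None = None
    zero_mq_reads: int | None = None

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.allele_depths.values()):
            raise VariantModelError("allele depths must be non-negative")
        if self.total_depth is not None and self.total_depth < 0:
            raise VariantModelError("total depth must be non-negative")


@dataclass
class VariantSite:
    """One polymorphic position, 1-based on the coding strand of a CDS."""

    gene_id: str
    position: int
    ref: Allele
    alts: tuple[Allele, ...]
    observations: dict[str, SiteObservation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise VariantModelError(
                f"{self.gene_id}: position must be >= 1, got {self.position}"
            )
        if not self.alts:
            raise VariantModelError(f"{self.gene_id}:{self.position}: no alt alleles")
        if self.ref in self.alts:
            raise VariantModelError(
                f"{self.gene_id}:{self.position}: ref allele repeated in alts"
            )

    @property
    def alleles(self) -> tuple[Allele, ...]:
        return (self.ref,) + self.alts

    def allele(self, index: int) -> Allele:
        try:
            return self.alleles[index]
        except IndexError:
            raise VariantModelError(
                f"{self.gene_id}:{self.position}: allele index {index} out of range"
            ) from None

    @property
    def is_indel(self) -> bool:
        return any(len(a) != len(self.ref) for a in self.alts)

    def key(self) -> tuple[str, int]:
        return (self.gene_id, self.position)


@dataclass
class GeneRecord:
    """A coding sequence with genome of origin and gene-set memberships.

    The genome flag selects the translation table (standard for nuclear,
    vertebrate mitochondrial for mtDNA-encoded genes).  A trailing
    incomplete codon is trimmed with a logged warning; an internal stop
    codon under the gene's own table is flagged, not fatal, because it can
    indicate a nuclear pseudogene copy rather than a functional gene.
    """

    gene_id: str
    cds: str
    genome: str = "nuclear"
    gene_sets: frozenset[str] = frozenset()
    trimmed_bases: int = 0
    has_internal_stop: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        if self.genome not in TRANSLATION_TABLES:
            raise VariantModelError(
                f"{self.gene_id}: unknown genome {self.genome!r}"
            )
        cds = self.cds.upper().replace("U", "T")
        overhang = len(cds) % 3
        if overhang:
            logger.warning(
                "%s: trimming %d trailing bases (incomplete codon)",
                self.gene_id, overhang,
            )
            cds = cds[: len(cds) - overhang]
            self.trimmed_bases += overhang
        self.cds = cds
        self.has_internal_stop = self._check_internal_stop()

    @property
    def table_id(self) -> int:
        return TRANSLATION_TABLES[self.genome]

    @property
    def length(self) -> int:
        return len(self.cds)

    def codon(self, codon_index: int) -> str:
        """1-based codon lookup."""
        start = (codon_index - 1) * 3
        if start < 0 or start + 3 > len(self.cds):
            raise VariantModelError(
                f"{self.gene_id}: codon {codon_index} beyond CDS of {len(self.cds)} nt"
            )
        return self.cds[start : start + 3]

    def _check_internal_stop(self) -> bool:
        if len(self.cds) < 6:
            return False
        aa = str(Seq(self.cds[:-3]).translate(table=self.table_id))
        return "*" in aa


# ---------------------------------------------------------------------------
# VCF input/output


def _maybe_open(source: str | PathLike | IO) -> IO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", newline=None)
    return open(path, "rt", newline=None)


def read_variant_sites(
    vcf_source: str | PathLike, ploidy: int = 6
) -> list[VariantSite]:
    """Read a VCF into :class:`VariantSite` records.

    Every sample genotype must carry exactly ``ploidy`` allele indices;
    a mismatch, or an allele index beyond the record's allele list, raises
    :class:`VariantModelError` naming the offending record.
    """
    sites: list[VariantSite] = []
    with pysam.VariantFile(str(vcf_source)) as vcf:
        for n, rec in enumerate(vcf, start=1):
            where = f"record {n} ({rec.chrom}:{rec.pos})"
            if rec.alts is None:
                raise VariantModelError(f"{where}: missing ALT")
            try:
                ref = Allele(rec.ref)
                alts = tuple(Allele(a) for a in rec.alts)
            except VariantModelError as exc:
                raise VariantModelError(f"{where}: {exc}") from None
            n_alleles = 1 + len(alts)
            observations: dict[str, SiteObservation] = {}
            for sample_name, sample in rec.samples.items():
                gt = sample.get("GT")
                genotype = None
                if gt is not None and not all(g is None for g in gt):
                    if len(gt) != ploidy or any(g is None for g in gt):
                        raise VariantModelError(
                            f"{where}: sample {sample_name} GT arity "
                            f"{len(gt)} != ploidy {ploidy}"
                        )
                    if any(g >= n_alleles for g in gt):
                        raise VariantModelError(
                            f"{where}: sample {sample_name} references unknown "
                            f"allele index (only {n_alleles} alleles listed)"
                        )
                    genotype = PooledGenotype(tuple(gt))
                ad = sample.get("AD")
                depths: dict[int, int] = {}
                if ad is not None:
                    for i, d in enumerate(ad):
                        if d is not None:
                            if i >= n_alleles:
                                raise VariantModelError(
                                    f"{where}: sample {sample_name} AD has more "
                                    "entries than alleles"
                                )
                            depths[i] = int(d)
                dp = sample.get("DP")
                gq = sample.get("GQ")
                mq = rec.info.get("MQ")
                mq0 = rec.info.get("MQ0")
                observations[sample_name] = SiteObservation(
                    pool_id=sample_name,
                    genotype=genotype,
                    allele_depths=depths,
                    total_depth=None if dp is None else int(dp),
                    site_quality=None if rec.qual is None else float(rec.qual),
                    genotype_quality=None if gq is None else float(gq),
                    mapping_quality=None if mq is None else float(mq),
                    zero_mq_reads=None if mq0 is None else int(mq0),
                )
            sites.append(
                VariantSite(
                    gene_id=rec.chrom,
                    position=rec.pos,
                    ref=ref,
                    alts=alts,
                    observations=observations,
                )
            )
    return sites


def write_variant_sites(
    sites: Sequence[VariantSite],
    path: str | PathLike,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write sites to a VCF; inverse of :func:`read_variant_sites`.

    Contig lengths default to the largest position seen per gene (plus the
    ref allele span), which is sufficient for round-tripping.
    """
    pool_ids: list[str] = []
    for site in sites:
        for pid in site.observations:
            if pid not in pool_ids:
                pool_ids.append(pid)
    lengths: dict[str, int] = dict(contig_lengths or {})
    for site in sites:
        need = site.position + len(site.ref)
        if lengths.get(site.gene_id, 0) < need:
            lengths[site.gene_id] = need

    header = pysam.VariantHeader()
    for gene_id in lengths:
        header.contigs.add(gene_id, length=lengths[gene_id])
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Per-allele read depth")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.info.add("MQ", 1, "Float", "RMS mapping quality")
    header.info.add("MQ0", 1, "Integer", "Reads with mapping quality zero")
    for pid in pool_ids:
        header.add_sample(pid)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site in sites:
            rec = out.new_record(
                contig=site.gene_id,
                start=site.position - 1,
                alleles=tuple(str(a) for a in site.alleles),
            )
            quals = [
                o.site_quality
                for o in site.observations.values()
                if o.site_quality is not None
            ]
            rec.qual = quals[0] if quals else None
            mqs = [
                o.mapping_quality
                for o in site.observations.values()
                if o.mapping_quality is not None
            ]
            if mqs:
                rec.info["MQ"] = float(mqs[0])
            mq0s = [
                o.zero_mq_reads
                for o in site.observations.values()
                if o.zero_mq_reads is not None
            ]
            if mq0s:
                rec.info["MQ0"] = int(max(mq0s))
            n_alleles = len(site.alleles)
            for pid in pool_ids:
                obs = site.observations.get(pid)
                fmt = rec.samples[pid]
                if obs is None:
                    continue
                if obs.genotype is not None:
                    fmt["GT"] = obs.genotype.allele_indices
                if obs.allele_depths:
                    fmt["AD"] = tuple(
                        obs.allele_depths.get(i, 0) for i in range(n_alleles)
                    )
                if obs.total_depth is not None:
                    fmt["DP"] = obs.total_depth
                if obs.genotype_quality is not None:
                    fmt["GQ"] = int(round(obs.genotype_quality))
            out.write(rec)


# ---------------------------------------------------------------------------
# Gene records


@dataclass
class GeneTableReport:
    """Reconciliation of the FASTA against the gene-set table."""

    missing_from_fasta: list[str] = field(default_factory=list)
    absent_from_table: list[str] = field(default_factory=list)
    internal_stop: list[str] = field(default_factory=list)


def read_geneset_table(source: str | PathLike | IO) -> pd.DataFrame:
    """Read the TSV of (gene_id, set_name, genome) memberships."""
    fh = _maybe_open(source)
    table = pd.read_csv(fh, sep="\t")
    required = {"gene_id", "set_name", "genome"}
    missing = required - set(table.columns)
    if missing:
        raise VariantModelError(
            f"gene-set table missing columns: {sorted(missing)}"
        )
    bad_genome = set(table["genome"]) - set(TRANSLATION_TABLES)
    if bad_genome:
        raise VariantModelError(f"unknown genome labels: {sorted(bad_genome)}")
    conflicts = (
        table.groupby("gene_id")["genome"].nunique().loc[lambda s: s > 1]
    )
    if not conflicts.empty:
        raise VariantModelError(
            f"conflicting genome labels for genes: {sorted(conflicts.index)}"
        )
    return table


def read_gene_records(
    fasta_source: str | PathLike | IO,
    geneset_table: str | PathLike | IO | pd.DataFrame,
) -> tuple[list[GeneRecord], GeneTableReport]:
    """Read CDS FASTA plus the gene-set membership table.

    Every table gene is either resolved to a record or listed in the
    report's ``missing_from_fasta`` — nothing is silently dropped.  FASTA
    sequences absent from the table become nuclear records with no set
    membership and are listed in ``absent_from_table``.
    """
    if isinstance(geneset_table, pd.DataFrame):
        table = geneset_table
    else:
        table = read_geneset_table(geneset_table)
    sets_by_gene: dict[str, set[str]] = {}
    genome_by_gene: dict[str, str] = {}
    for row in table.itertuples():
        sets_by_gene.setdefault(row.gene_id, set()).add(row.set_name)
        genome_by_gene[row.gene_id] = row.genome

    records: list[GeneRecord] = []
    report = GeneTableReport()
    seen: set[str] = set()
    fh = _maybe_open(fasta_source)
    for seq_rec in SeqIO.parse(fh, "fasta"):
        gid = seq_rec.id
        seen.add(gid)
        genome = genome_by_gene.get(gid, "nuclear")
        rec = GeneRecord(
            gene_id=gid,
            cds=str(seq_rec.seq),
            genome=genome,
            gene_sets=frozenset(sets_by_gene.get(gid, ())),
        )
        if gid not in genome_by_gene:
            report.absent_from_table.append(gid)
        if rec.has_internal_stop:
            logger.warning(
                "%s: internal stop codon under table %d (possible pseudogene)",
                gid, rec.table_id,
            )
            report.internal_stop.append(gid)
        records.append(rec)
    report.missing_from_fasta = sorted(set(genome_by_gene) - seen)
    return records, report


def write_gene_records(
    records: Iterable[GeneRecord], fasta_path: str | PathLike
) -> None:
    with open(fasta_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.cds), 60):
                fh.write(rec.cds[i : i + 60] + "\n")


def write_geneset_table(
    records: Iterable[GeneRecord], path: str | PathLike
) -> None:
    rows = [
        {"gene_id": rec.gene_id, "set_name": s, "genome": rec.genome}
        for rec in records
        for s in sorted(rec.gene_sets)
    ]
    pd.DataFrame(rows, columns=["gene_id", "set_name", "genome"]).to_csv(
        path, sep="\t", index=False
    )
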