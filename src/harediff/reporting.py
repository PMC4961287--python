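"""Pipeline orchestration: simulate/load -> nominate -> annotate -> rates.

The run report mirrors the bookkeeping a reviewer wants from a filtering
pipeline: sites in, exclusions per stage and per criterion, sites out, the
per-gene-set rate table and the requested fold-change contrasts.  Every
output embeds the package version and a hash of the fully-resolved run
configuration, and the record counts must reconcile across each stage
boundary (``sites_in - excluded == sites_out``) — no silent drops.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .effect_annotation import annotate_all, annotations_to_frame
from .geneset_rates import RateTable, compute_rates, contrast_report
from .lineage_filter import (
    FilterParams,
    NominationReport,
    apply_stringent_filters,
    flag_merged_duplicates,
    is_differentiated,
    nominate_differentiating_sites,
    passes_site_prefilter,
)
from .synthetic_data import POOL_A, POOL_B, SimConfig, SimResult, simulate
from .variant_model import GeneRecord, VariantSite, read_gene_records, read_variant_sites


def derive_aggregate_sets(
    gene_sets: Mapping[str, Sequence[str]],
) -> dict[str, tuple[str, ...]]:
    """Union OXPHOS complex sets into oxphos / oxphos_nuclear / oxphos_mt."""
    nuclear = tuple(
        g
        for name in sorted(gene_sets)
        if name.startswith("complex_") and name.endswith("_nuclear")
        for g in gene_sets[name]
    )
    mt = tuple(
        g
        for name in sorted(gene_sets)
        if name.startswith("complex_") and name.endswith("_mt")
        for g in gene_sets[name]
    )
    out: dict[str, tuple[str, ...]] = {}
    if nuclear:
        out["oxphos_nuclear"] = nuclear
    if mt:
        out["oxphos_mt"] = mt
    if nuclear or mt:
        out["oxphos"] = nuclear + mt
    return out


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run.

    Either ``sim`` is set (synthetic run) or the three input paths are.
    ``diff_criterion`` picks which differentiating-site list feeds the rate
    table: ``strict`` uses the five-criterion nomination list; ``half``
    uses the pooled-genotype 50%-differentiation criterion (with the
    quality/depth/duplicate criteria still applied, but allele privacy not
    required), matching the energy-gene analysis path.
    """

    sim: SimConfig | None = None
    vcf: str | None = None
    fasta: str | None = None
    geneset_table: str | None = None
    pool_a: str = POOL_A
    pool_b: str = POOL_B
    filter_params: FilterParams = field(default_factory=FilterParams)
    duplicate_genes: frozenset[str] = frozenset()
    auto_flag_duplicates: bool = True
    diff_criterion: str = "strict"
    contrasts: Sequence[tuple[str, str]] | None = None
    ploidy: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diff_criterion not in ("strict", "half"):
            raise ValueError("diff_criterion must be 'strict' or 'half'")
        if self.sim is None and not (self.vcf and self.fasta and self.geneset_table):
            raise ValueError(
                "provide either a simulation config or vcf+fasta+geneset_table paths"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = None if self.sim is None else self.sim.to_dict()
        d["filter_params"] = {
            **dataclasses.asdict(self.filter_params),
            "duplicate_exclusion": sorted(self.filter_params.duplicate_exclusion),
        }
        d["duplicate_genes"] = sorted(self.duplicate_genes)
        d["contrasts"] = None if self.contrasts is None else [list(c) for c in self.contrasts]
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunReport:
    config: RunConfig
    config_hash: str
    nomination: NominationReport
    n_rate_sites: int
    rate_table: RateTable
    contrasts: pd.DataFrame
    annotations: pd.DataFrame
    flagged_duplicates: frozenset[str]

    def counters(self) -> dict[str, int]:
        nom = self.nomination
        return {
            "sites_in": nom.n_input,
            "not_evaluable": nom.n_not_evaluable,
            "prefilter_fail": nom.n_prefilter_fail,
            **{f"fail_{k}": v for k, v in nom.criterion_failures.items()},
            "excluded": nom.n_excluded,
            "sites_out": nom.n_pass,
            "snvs_out": nom.n_snv,
            "indels_out": nom.n_indel,
            "genes_out": nom.n_genes,
            "rate_sites": self.n_rate_sites,
        }

    def to_text(self) -> str:
        lines = [
            f"# harediff {__version__} run report (config {self.config_hash})",
            "",
            "## Site filtering",
        ]
        for key, val in self.counters().items():
            lines.append(f"{key}\t{val}")
        if not self.nomination.reconciles():
            lines.append("WARNING: stage counts do not reconcile")
        lines += ["", "## Rates per gene set"]
        lines.append(self.rate_table.to_frame().to_string(index=False))
        lines += ["", "## Contrasts (fold changes)"]
        lines.append(self.contrasts.to_string(index=False))
        if self.flagged_duplicates:
            lines += [
                "",
                "## Duplicate-flagged genes",
                ", ".join(sorted(self.flagged_duplicates)),
            ]
        return "\n".join(lines) + "\n"

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = f"# harediff {__version__} config={self.config_hash}\n"
        paths = {
            "report": outdir / "run_report.txt",
            "rates": outdir / "rates.tsv",
            "contrasts": outdir / "contrasts.tsv",
            "annotations": outdir / "annotations.tsv",
        }
        paths["report"].write_text(self.to_text())
        for key, frame in (
            ("rates", self.rate_table.to_frame()),
            ("contrasts", self.contrasts),
            ("annotations", self.annotations),
        ):
            with open(paths[key], "w") as fh:
                fh.write(header)
                frame.to_csv(fh, sep="\t", index=False)
        return paths


def select_half_criterion_sites(
    sites: Sequence[VariantSite],
    pool_a: str,
    pool_b: str,
    params: FilterParams,
) -> list[VariantSite]:
    """Differentiating sites under the 50% pooled-genotype criterion.

    Quality, depth, off-call and duplicate criteria still apply; the
    private-allele requirement is replaced by genotype differentiation at
    ``params.diff_fraction``.
    """
    out = []
    for site in sites:
        obs_a = site.observations.get(pool_a)
        obs_b = site.observations.get(pool_b)
        if (
            obs_a is None or obs_b is None
            or obs_a.genotype is None or obs_b.genotype is None
        ):
            continue
        if not passes_site_prefilter(obs_a, obs_b, params):
            continue
        verdict = apply_stringent_filters(site, pool_a, pool_b, params)
        if not (verdict.c2_quality and verdict.c3_allele_depth
                and verdict.c4_offcall_reads and verdict.c5_not_duplicate):
            continue
        if is_differentiated(obs_a.genotype, obs_b.genotype, params.diff_fraction):
            out.append(site)
    return out


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full post-calling workflow and return the run report."""
    if config.sim is not None:
        sim: SimResult = simulate(config.sim)
        genes = sim.genes
        sites = sim.sites
        duplicate_genes = frozenset(config.duplicate_genes | sim.duplicate_genes)
    else:
        genes, _ = read_gene_records(config.fasta, config.geneset_table)
        sites = read_variant_sites(config.vcf, ploidy=config.ploidy)
        duplicate_genes = config.duplicate_genes

    genes_by_id: dict[str, GeneRecord] = {g.gene_id: g for g in genes}
    flagged = frozenset(duplicate_genes)
    if config.auto_flag_duplicates:
        flagged = frozenset(
            flag_merged_duplicates(sites, genes_by_id, user_exclusions=duplicate_genes)
        )
    params = config.filter_params.with_exclusions(flagged)

    selected, nomination = nominate_differentiating_sites(
        sites, config.pool_a, config.pool_b, params
    )
    if config.diff_criterion == "strict":
        rate_sites = [s for s, _ in selected]
    else:
        rate_sites = select_half_criterion_sites(
            sites, config.pool_a, config.pool_b, params
        )

    annotations = annotate_all(rate_sites, genes_by_id)

    gene_sets: dict[str, list[str]] = {}
    for gene in genes:
        for set_name in gene.gene_sets:
            gene_sets.setdefault(set_name, []).append(gene.gene_id)
    gene_sets = {k: sorted(v) for k, v in sorted(gene_sets.items())}
    gene_sets.update(derive_aggregate_sets(gene_sets))

    rate_table = compute_rates(annotations, genes_by_id, gene_sets)
    if config.contrasts is None:
        contrasts = [
            (num, den)
            for num in rate_table.labels()
            for den in ("glycolysis", "krebs")
            if den in rate_table and num not in ("glycolysis", "krebs")
        ]
    else:
        contrasts = list(config.contrasts)
    contrast_frame = contrast_report(rate_table, contrasts)

    return RunReport(
        config=config,
        config_hash=config.config_hash(),
        nomination=nomination,
        n_rate_sites=len(rate_sites),
        rate_table=rate_table,
        contrasts=contrast_frame,
        annotations=annotations_to_frame(annotations),
        flagged_duplicates=flagged,
    )
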