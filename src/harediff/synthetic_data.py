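"""Two-lineage synthetic datasets with known ground truth.

The generator emulates, at desk scale, the structure of a pooled
two-lineage transcriptome comparison: a reference set of coding sequences
organised into the energy-production gene sets, a pool per lineage
genotyped at elevated ploidy, and three kinds of polymorphic sites —

* *differentiating* sites planted per gene set at configurable total and
  non-synonymous per-nucleotide rates (defaults are the published rates for
  the European-vs-Anatolian hare contrast), with fixed-disjoint pooled
  genotypes (optionally a fraction planted as 50%-criterion-only patterns);
* *shared* polymorphisms present in both pools, which a correct filter must
  reject on the private-allele criterion;
* *engineered-failure* sites, each designed to fail exactly one named
  nomination criterion while passing the other four, placed in decoy genes
  outside every gene set so they cannot perturb the rate recovery.

Read depths use an overdispersed (negative-binomial) model on top of a
floor that satisfies the depth thresholds by construction, mimicking
expression-driven coverage heterogeneity.  All randomness flows from a
single seed through one named generator; the same seed and config yield
byte-identical FASTA/VCF fixtures.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .effect_annotation import Effect, translate_codon
from .reference_data import ENERGY_GENE_SETS, MITOCHONDRIAL_GENES, PUBLISHED_RATES
from .variant_model import (
    Allele,
    GeneRecord,
    PooledGenotype,
    SiteObservation,
    VariantSite,
    write_gene_records,
    write_geneset_table,
    write_variant_sites,
)

POOL_A = "european"
POOL_B = "anatolian"

_CRITERIA = ("c1", "c2", "c3", "c4", "c5")
_BASES = "ACGT"


def _default_rates() -> dict[str, tuple[float, float]]:
    return {name: PUBLISHED_RATES[name] for name in ENERGY_GENE_SETS}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Defaults plant the published per-set rates over one synthetic gene per
    reference gene-set member, with CDS lengths drawn around a typical
    transcript length, hexaploid pools, and depth/quality models that
    satisfy the default filter thresholds by construction.
    """

    gene_sets: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(ENERGY_GENE_SETS)
    )
    mitochondrial_genes: frozenset[str] = MITOCHONDRIAL_GENES
    cds_length_mean: float = 1500.0
    cds_length_sd: float = 400.0
    cds_length_min: int = 300
    ploidy: int = 6
    rates: Mapping[str, tuple[float, float]] = field(default_factory=_default_rates)
    shared_poly_rate: float = 0.002
    depth_floor: int = 30
    depth_mean_extra: float = 40.0
    depth_dispersion: float = 5.0
    pass_quality_range: tuple[float, float] = (150.0, 900.0)
    fail_quality_range: tuple[float, float] = (40.0, 99.0)
    indel_fraction: float = 0.01
    half_criterion_fraction: float = 0.0
    fail_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (total, nonsyn) in self.rates.items():
            if not 0 <= total <= 0.5 or not 0 <= nonsyn <= 0.5:
                raise ValueError(f"{name}: rates must lie in [0, 0.5]")
            if nonsyn > total:
                raise ValueError(f"{name}: nonsyn rate exceeds total rate")
        if self.cds_length_min < 60:
            raise ValueError("cds_length_min must be >= 60 nt")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        if not 0 <= self.half_criterion_fraction <= 1:
            raise ValueError("half_criterion_fraction must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gene_sets"] = {k: list(v) for k, v in self.gene_sets.items()}
        d["mitochondrial_genes"] = sorted(self.mitochondrial_genes)
        d["rates"] = {k: list(v) for k, v in self.rates.items()}
        d["pass_quality_range"] = list(self.pass_quality_range)
        d["fail_quality_range"] = list(self.fail_quality_range)
        return d


@dataclass
class SimResult:
    genes: list[GeneRecord]
    sites: list[VariantSite]
    truth: pd.DataFrame
    duplicate_genes: frozenset[str]
    config: SimConfig

    def genes_by_id(self) -> dict[str, GeneRecord]:
        return {g.gene_id: g for g in self.genes}


class SimulationError(RuntimeError):
    """Infeasible planting request (e.g. no substitution of the desired class)."""


def _random_cds(rng: np.random.Generator, length: int, table_id: int) -> str:
    """Random CDS: ATG start, no internal stop, terminal stop codon."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    sense = sorted(set(table.forward_table) - set(table.stop_codons))
    stops = sorted(table.stop_codons)
    n_codons = length // 3
    body = rng.integers(0, len(sense), size=n_codons - 2)
    codons = ["ATG"] + [sense[i] for i in body] + [stops[rng.integers(0, len(stops))]]
    return "".join(codons)


def _candidate_alts(cds: str, pos: int, table_id: int, want_nonsyn: bool) -> list[str]:
    """Alt bases at 1-based ``pos`` whose substitution has the wanted class."""
    ref = cds[pos - 1]
    codon_start = (pos - 1) // 3 * 3
    codon = cds[codon_start : codon_start + 3]
    offset = (pos - 1) % 3
    aa_ref = translate_codon(codon, table_id)
    out = []
    for b in _BASES:
        if b == ref:
            continue
        alt_codon = codon[:offset] + b + codon[offset + 1 :]
        aa_alt = translate_codon(alt_codon, table_id)
        changed = aa_alt != aa_ref
        if changed == want_nonsyn:
            out.append(b)
    return out


def _genotype_strings(a: PooledGenotype, b: PooledGenotype) -> tuple[str, str]:
    return (
        "/".join(map(str, a.allele_indices)),
        "/".join(map(str, b.allele_indices)),
    )


class _SiteFactory:
    """Builds VariantSites with the shared depth/quality model."""

    def __init__(self, config: SimConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng

    def _depth(self) -> int:
        c = self.config
        p = c.depth_dispersion / (c.depth_dispersion + c.depth_mean_extra)
        return c.depth_floor + int(self.rng.negative_binomial(c.depth_dispersion, p))

    def _quality(self, passing: bool) -> float:
        lo, hi = (
            self.config.pass_quality_range
            if passing
            else self.config.fail_quality_range
        )
        return float(int(self.rng.uniform(lo, hi)))

    def observation(
        self,
        pool_id: str,
        genotype: PooledGenotype,
        extra_depths: Mapping[int, int] | None = None,
        depth_override: Mapping[int, int] | None = None,
        quality_passing: bool = True,
    ) -> SiteObservation:
        depths: dict[int, int] = {}
        for idx in sorted(genotype.allele_set()):
            if depth_override and idx in depth_override:
                depths[idx] = depth_override[idx]
            else:
                depths[idx] = self._depth()
        if extra_depths:
            for idx, d in extra_depths.items():
                depths[idx] = depths.get(idx, 0) + d
        return SiteObservation(
            pool_id=pool_id,
            genotype=genotype,
            allele_depths=depths,
            total_depth=sum(depths.values()),
            site_quality=self._quality(True),
            genotype_quality=self._quality(quality_passing),
            mapping_quality=60.0,
            zero_mq_reads=0,
        )


def simulate(config: SimConfig | None = None) -> SimResult:
    """Generate genes, variant sites and the ground-truth ledger."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    factory = _SiteFactory(config, rng)
    ploidy = config.ploidy

    # --- genes -----------------------------------------------------------
    membership: dict[str, set[str]] = {}
    primary_set: dict[str, str] = {}
    for set_name, members in config.gene_sets.items():
        for g in members:
            membership.setdefault(g, set()).add(set_name)
            primary_set.setdefault(g, set_name)

    genes: list[GeneRecord] = []
    for gene_id in membership:
        genome = (
            "mitochondrial" if gene_id in config.mitochondrial_genes else "nuclear"
        )
        length = max(
            config.cds_length_min,
            int(rng.normal(config.cds_length_mean, config.cds_length_sd)),
        )
        length -= length % 3
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                cds=_random_cds(rng, length, 2 if genome == "mitochondrial" else 1),
                genome=genome,
                gene_sets=frozenset(membership[gene_id]),
            )
        )
    # Decoy genes host engineered-failure sites; one per criterion so each
    # engineered site fails exactly its designed criterion.
    decoys = {}
    for crit in _CRITERIA:
        length = max(config.cds_length_min, int(config.cds_length_mean))
        length -= length % 3
        decoy = GeneRecord(
            gene_id=f"DECOY_{crit.upper()}",
            cds=_random_cds(rng, length, 1),
            genome="nuclear",
            gene_sets=frozenset(),
        )
        decoys[crit] = decoy
        genes.append(decoy)

    # --- helpers ---------------------------------------------------------
    used_positions: dict[str, set[int]] = {g.gene_id: set() for g in genes}

    def eligible(gene: GeneRecord) -> range:
        return range(4, gene.length - 3 + 1)  # skip start and stop codons

    def draw_position(
        gene: GeneRecord, want_nonsyn: bool | None, max_tries: int = 200
    ) -> tuple[int, str | None]:
        pool = eligible(gene)
        for _ in range(max_tries):
            pos = int(rng.integers(pool.start, pool.stop))
            if pos in used_positions[gene.gene_id]:
                continue
            if want_nonsyn is None:
                used_positions[gene.gene_id].add(pos)
                return pos, None
            alts = _candidate_alts(gene.cds, pos, gene.table_id, want_nonsyn)
            if alts:
                used_positions[gene.gene_id].add(pos)
                return pos, alts[int(rng.integers(0, len(alts)))]
        raise SimulationError(
            f"{gene.gene_id}: no position admits a "
            f"{'non-synonymous' if want_nonsyn else 'synonymous'} substitution"
        )

    sites: list[VariantSite] = []
    truth_rows: list[dict] = []

    g_ref = PooledGenotype((0,) * ploidy)
    g_alt = PooledGenotype((1,) * ploidy)
    n_half = ploidy - ploidy // 2
    g_half = PooledGenotype((0,) * (ploidy - n_half) + (1,) * n_half)

    def emit(site: VariantSite, **truth) -> None:
        sites.append(site)
        truth_rows.append(
            {
                "gene_id": site.gene_id,
                "position": site.position,
                "ref": str(site.ref),
                "alt": ",".join(str(a) for a in site.alts),
                **truth,
            }
        )

    # --- differentiating sites ------------------------------------------
    n_planted = 0
    for gene in genes:
        if not gene.gene_sets:
            continue
        total_rate, nonsyn_rate = config.rates[primary_set[gene.gene_id]]
        if total_rate == 0:
            continue
        n_sites = int(rng.binomial(gene.length, total_rate))
        nonsyn_frac = nonsyn_rate / total_rate
        for _ in range(n_sites):
            as_indel = rng.random() < config.indel_fraction
            if as_indel:
                pos, _ = draw_position(gene, None)
                ref = Allele(gene.cds[pos - 1])
                ins_len = 3 if rng.random() < 0.5 else 1
                insert = "".join(
                    _BASES[int(i)] for i in rng.integers(0, 4, size=ins_len)
                )
                alt = Allele(ref.value + insert)
                effect = (
                    Effect.INDEL_INFRAME if ins_len % 3 == 0 else Effect.INDEL_FRAMESHIFT
                )
            else:
                want_nonsyn = bool(rng.random() < nonsyn_frac)
                pos, alt_base = draw_position(gene, want_nonsyn)
                ref = Allele(gene.cds[pos - 1])
                alt = Allele(alt_base)
                effect = Effect.NONSYNONYMOUS if want_nonsyn else Effect.SYNONYMOUS
            half = rng.random() < config.half_criterion_fraction
            gt_a, gt_b = (g_ref, g_half) if half else (g_ref, g_alt)
            site = VariantSite(
                gene_id=gene.gene_id,
                position=pos,
                ref=ref,
                alts=(alt,),
                observations={
                    POOL_A: factory.observation(POOL_A, gt_a),
                    POOL_B: factory.observation(POOL_B, gt_b),
                },
            )
            a_str, b_str = _genotype_strings(gt_a, gt_b)
            emit(
                site,
                kind="differentiating",
                effect=effect.value,
                genotype_a=a_str,
                genotype_b=b_str,
                is_differentiating=True,
                criterion_path="half" if half else "strict",
                designed_fail="",
            )
            n_planted += 1

    # --- shared polymorphisms (filter noise) ----------------------------
    g_shared_a = PooledGenotype((0,) * (ploidy - 1) + (1,))
    g_shared_b = PooledGenotype((0,) * max(ploidy - 2, 1) + (1,) * min(2, ploidy - 1))
    for gene in genes:
        if not gene.gene_sets:
            continue
        n_shared = int(rng.binomial(gene.length, config.shared_poly_rate))
        for _ in range(n_shared):
            pos, _ = draw_position(gene, None)
            ref = Allele(gene.cds[pos - 1])
            alt = Allele(_BASES[(_BASES.index(ref.value) + 1 + int(rng.integers(0, 3))) % 4])
            effect_alts = _candidate_alts(gene.cds, pos, gene.table_id, True)
            effect = (
                Effect.NONSYNONYMOUS if alt.value in effect_alts else Effect.SYNONYMOUS
            )
            site = VariantSite(
                gene_id=gene.gene_id,
                position=pos,
                ref=ref,
                alts=(alt,),
                observations={
                    POOL_A: factory.observation(POOL_A, g_shared_a),
                    POOL_B: factory.observation(POOL_B, g_shared_b),
                },
            )
            a_str, b_str = _genotype_strings(g_shared_a, g_shared_b)
            emit(
                site,
                kind="shared",
                effect=effect.value,
                genotype_a=a_str,
                genotype_b=b_str,
                is_differentiating=False,
                criterion_path="",
                designed_fail="",
            )

    # --- engineered failures --------------------------------------------
    n_fail = int(round(config.fail_fraction * n_planted))
    g_c1_a = PooledGenotype((0,) * (ploidy // 2) + (1,) * (ploidy - ploidy // 2))
    for i in range(n_fail):
        crit = _CRITERIA[i % len(_CRITERIA)]
        gene = decoys[crit]
        pos, alt_base = draw_position(gene, True)
        ref = Allele(gene.cds[pos - 1])
        alt = Allele(alt_base)
        gt_a, gt_b = g_ref, g_alt
        obs_kwargs_a: dict = {}
        obs_kwargs_b: dict = {}
        if crit == "c1":
            gt_a = g_c1_a  # shares the alt allele with the other pool
        elif crit == "c2":
            obs_kwargs_b["quality_passing"] = False
        elif crit == "c3":
            obs_kwargs_b["depth_override"] = {1: config.depth_floor - 1}
        elif crit == "c4":
            obs_kwargs_a["extra_depths"] = {1: 2}
        # c5 needs no site-level tweak: its decoy gene goes on the
        # duplicate-exclusion list.
        site = VariantSite(
            gene_id=gene.gene_id,
            position=pos,
            ref=ref,
            alts=(alt,),
            observations={
                POOL_A: factory.observation(POOL_A, gt_a, **obs_kwargs_a),
                POOL_B: factory.observation(POOL_B, gt_b, **obs_kwargs_b),
            },
        )
        a_str, b_str = _genotype_strings(gt_a, gt_b)
        emit(
            site,
            kind="engineered_fail",
            effect=Effect.NONSYNONYMOUS.value,
            genotype_a=a_str,
            genotype_b=b_str,
            is_differentiating=False,
            criterion_path="",
            designed_fail=crit,
        )

    duplicate_genes = frozenset(
        {decoys["c5"].gene_id}
        if any(r["designed_fail"] == "c5" for r in truth_rows)
        else set()
    )

    order = sorted(range(len(sites)), key=lambda i: (sites[i].gene_id, sites[i].position))
    sites = [sites[i] for i in order]
    truth = pd.DataFrame([truth_rows[i] for i in order])
    return SimResult(
        genes=genes,
        sites=sites,
        truth=truth,
        duplicate_genes=duplicate_genes,
        config=config,
    )


def planted_expectation(result: SimResult) -> pd.DataFrame:
    """Binomial expectation and variance of planted counts per gene set.

    Sites are planted per gene at the rate of the gene's primary set (its
    first listed membership), thinned into indels and non-synonymous calls,
    so for every gene set the planted totals are sums of independent
    binomials over member genes.  Returns one row per configured set with
    expected total / non-synonymous counts and their variances — the
    yardstick for parameter-recovery checks.
    """
    config = result.config
    primary: dict[str, str] = {}
    for set_name, members in config.gene_sets.items():
        for g in members:
            primary.setdefault(g, set_name)
    lengths = {g.gene_id: g.length for g in result.genes}
    rows = []
    for set_name, members in config.gene_sets.items():
        e_tot = v_tot = e_ns = v_ns = 0.0
        denom = 0
        for g in members:
            length = lengths[g]
            denom += length
            p_tot, p_ns_nominal = config.rates[primary[g]]
            p_ns = p_ns_nominal * (1 - config.indel_fraction)
            e_tot += length * p_tot
            v_tot += length * p_tot * (1 - p_tot)
            e_ns += length * p_ns
            v_ns += length * p_ns * (1 - p_ns)
        rows.append(
            {
                "gene_set": set_name,
                "denominator_nt": denom,
                "expected_total": e_tot,
                "var_total": v_tot,
                "expected_nonsyn": e_ns,
                "var_nonsyn": v_ns,
            }
        )
    return pd.DataFrame(rows).set_index("gene_set")


def write_fixtures(result: SimResult, directory: str | PathLike) -> dict[str, str]:
    """Write FASTA/VCF/TSV fixtures plus a config echo; returns checksums."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes.fasta": directory / "genes.fasta",
        "variants.vcf": directory / "variants.vcf",
        "gene_sets.tsv": directory / "gene_sets.tsv",
        "truth.tsv": directory / "truth.tsv",
        "config.json": directory / "config.json",
    }
    write_gene_records(result.genes, paths["genes.fasta"])
    write_variant_sites(
        result.sites,
        paths["variants.vcf"],
        contig_lengths={g.gene_id: g.length for g in result.genes},
    )
    write_geneset_table(result.genes, paths["gene_sets.tsv"])
    result.truth.to_csv(paths["truth.tsv"], sep="\t", index=False)
    config_doc = {
        "config": result.config.to_dict(),
        "duplicate_genes": sorted(result.duplicate_genes),
    }
    paths["config.json"].write_text(json.dumps(config_doc, indent=2) + "\n")

    manifest = {}
    for name, path in paths.items():
        manifest[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return manifest


def simulate_pooling_scenario(
    n_sites: int = 200,
    n_individuals: int = 3,
    depth_per_allele: int = 60,
    low_depth_fraction: float = 0.2,
    low_depth_value: int = 5,
    low_depth_individual: int = 0,
    other_pool_depth: int = 100,
    individual_ploidy: int = 2,
    pool_ploidy: int = 6,
    seed: int = 0,
) -> tuple[list[VariantSite], list[str], str]:
    """Scenario for the pooled-vs-individual experiment.

    Every site is a fixed difference: each individual of the first lineage
    is homozygous reference, the other lineage's pool homozygous alternate.
    A fraction of sites gives one individual a low read count, emulating
    expression dropout that pooling papers over.  Returns the sites, the
    individual sample ids and the other pool's id.
    """
    rng = np.random.default_rng(seed)
    individuals = [f"IND{i+1}" for i in range(n_individuals)]
    low = rng.random(n_sites) < low_depth_fraction
    sites = []
    for i in range(n_sites):
        ref, alt = ("A", "G") if i % 2 == 0 else ("C", "T")
        observations: dict[str, SiteObservation] = {}
        for j, ind in enumerate(individuals):
            depth = (
                low_depth_value
                if (low[i] and j == low_depth_individual)
                else depth_per_allele
            )
            observations[ind] = SiteObservation(
                pool_id=ind,
                genotype=PooledGenotype((0,) * individual_ploidy),
                allele_depths={0: depth},
                total_depth=depth,
                site_quality=500.0,
                genotype_quality=400.0,
                mapping_quality=60.0,
                zero_mq_reads=0,
            )
        observations["OTHER"] = SiteObservation(
            pool_id="OTHER",
            genotype=PooledGenotype((1,) * pool_ploidy),
            allele_depths={1: other_pool_depth},
            total_depth=other_pool_depth,
            site_quality=500.0,
            genotype_quality=400.0,
            mapping_quality=60.0,
            zero_mq_reads=0,
        )
        sites.append(
            VariantSite(
                gene_id=f"SCEN{i // 50 + 1}",
                position=(i % 50) * 7 + 3,
                ref=Allele(ref),
                alts=(Allele(alt),),
                observations=observations,
            )
        )
    return sites, individuals, "OTHER"
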