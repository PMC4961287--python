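"""Nomination of lineage-differentiating polymorphic sites.

Two notions of "differentiating" coexist and serve different analyses:

* the *stringent list*: five criteria that nominate sites whose alleles are
  completely private to one pool (c1), called with high genotype quality
  (c2), with every called allele supported by a minimum read count (c3),
  with essentially no reads supporting uncalled alleles (c4), and not lying
  in a sequence suspected to be a merged close duplicate (c5);
* the *50%-differentiation criterion* on pooled genotypes, used for the
  energy-gene rate analysis: two equal-ploidy genotypes are differentiated
  when at least half of the allele slots must change to convert one
  multiset into the other (e.g. 0/0/0/0/0/0 vs 0/0/0/1/1/1).

"Observed" alleles for criterion c1 are the alleles of the called genotype;
reads supporting alleles outside the called genotype are handled by c4.
A separate site-level pre-filter applies the mapping-quality conditions
(MQ, MQ0) and the caller's site-quality cutoff before the five criteria.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .variant_model import GeneRecord, PooledGenotype, SiteObservation, VariantSite


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for site nomination.

    Defaults follow the published analysis: caller cutoff QVALUE 30, the
    genotype-support cutoff QVALUE 100, at least 30 reads per called allele,
    at most one read for an uncalled allele, MQ >= 30 with no MQ0 reads, and
    a 50% differentiation fraction for the pooled-genotype criterion.
    """

    min_call_quality: float = 30.0
    min_genotype_quality: float = 100.0
    min_allele_reads: int = 30
    max_offcall_reads: int = 1
    min_mapping_quality: float = 30.0
    max_zero_mq: int = 0
    duplicate_exclusion: frozenset[str] = frozenset()
    diff_fraction: float = 0.5

    def __post_init__(self) -> None:
        numeric = (
            self.min_call_quality, self.min_genotype_quality,
            self.min_allele_reads, self.max_offcall_reads,
            self.min_mapping_quality, self.max_zero_mq,
        )
        if any(v < 0 for v in numeric):
            raise ValueError("filter thresholds must be >= 0")
        if not 0 < self.diff_fraction <= 1:
            raise ValueError("diff_fraction must lie in (0, 1]")

    def with_exclusions(self, genes: Iterable[str]) -> "FilterParams":
        return replace(
            self, duplicate_exclusion=self.duplicate_exclusion | frozenset(genes)
        )


@dataclass
class FilterVerdict:
    """Per-criterion outcome for one site; ``overall`` is their conjunction.

    ``evaluable`` is False when an observation for either pool is missing,
    in which case the flags are meaningless and ``reason`` explains why.
    """

    site: VariantSite
    c1_private_alleles: bool = False
    c2_quality: bool = False
    c3_allele_depth: bool = False
    c4_offcall_reads: bool = False
    c5_not_duplicate: bool = False
    prefilter: bool = True
    evaluable: bool = True
    reason: str | None = None

    @property
    def overall(self) -> bool:
        return (
            self.evaluable
            and self.prefilter
            and self.c1_private_alleles
            and self.c2_quality
            and self.c3_allele_depth
            and self.c4_offcall_reads
            and self.c5_not_duplicate
        )

    def failing_criteria(self) -> tuple[str, ...]:
        names = {
            "c1": self.c1_private_alleles,
            "c2": self.c2_quality,
            "c3": self.c3_allele_depth,
            "c4": self.c4_offcall_reads,
            "c5": self.c5_not_duplicate,
        }
        return tuple(k for k, ok in names.items() if not ok)


def genotype_distance(a: PooledGenotype, b: PooledGenotype) -> int:
    """Minimum allele-slot substitutions converting multiset ``a`` into ``b``."""
    if a.ploidy != b.ploidy:
        raise ValueError(f"unequal ploidy: {a.ploidy} vs {b.ploidy}")
    shared = Counter(a.allele_indices) & Counter(b.allele_indices)
    return a.ploidy - sum(shared.values())


def is_differentiated(
    a: PooledGenotype, b: PooledGenotype, diff_fraction: float = 0.5
) -> bool:
    """Pooled-genotype differentiation at the given slot fraction."""
    return genotype_distance(a, b) >= diff_fraction * a.ploidy


def passes_site_prefilter(
    obs_a: SiteObservation, obs_b: SiteObservation, params: FilterParams
) -> bool:
    """Site-level MQ / MQ0 / caller-quality pre-filter."""
    for obs in (obs_a, obs_b):
        if (
            obs.mapping_quality is not None
            and obs.mapping_quality < params.min_mapping_quality
        ):
            return False
        if obs.zero_mq_reads is not None and obs.zero_mq_reads > params.max_zero_mq:
            return False
        if (
            obs.site_quality is not None
            and obs.site_quality < params.min_call_quality
        ):
            return False
    return True


def _quality_for_c2(obs: SiteObservation) -> float | None:
    # Genotype-level quality preferred; the site QUAL is the fallback.
    if obs.genotype_quality is not None:
        return obs.genotype_quality
    return obs.site_quality


def apply_stringent_filters(
    site: VariantSite,
    pool_a: str,
    pool_b: str,
    params: FilterParams | None = None,
) -> FilterVerdict:
    """Evaluate the five nomination criteria for one site."""
    params = params or FilterParams()
    obs_a = site.observations.get(pool_a)
    obs_b = site.observations.get(pool_b)
    if obs_a is None or obs_b is None or obs_a.genotype is None or obs_b.genotype is None:
        missing = [
            p
            for p, o in ((pool_a, obs_a), (pool_b, obs_b))
            if o is None or o.genotype is None
        ]
        return FilterVerdict(
            site=site,
            evaluable=False,
            reason=f"missing observation or genotype for pool(s) {missing}",
        )

    set_a = obs_a.genotype.allele_set()
    set_b = obs_b.genotype.allele_set()
    c1 = set_a.isdisjoint(set_b)

    c2 = True
    for obs in (obs_a, obs_b):
        q = _quality_for_c2(obs)
        if q is None or q < params.min_genotype_quality:
            c2 = False

    c3 = all(
        obs.allele_depths.get(idx, 0) >= params.min_allele_reads
        for obs, called in ((obs_a, set_a), (obs_b, set_b))
        for idx in called
    )

    c4 = all(
        depth <= params.max_offcall_reads
        for obs, called in ((obs_a, set_a), (obs_b, set_b))
        for idx, depth in obs.allele_depths.items()
        if idx not in called
    )

    c5 = site.gene_id not in params.duplicate_exclusion

    return FilterVerdict(
        site=site,
        c1_private_alleles=c1,
        c2_quality=c2,
        c3_allele_depth=c3,
        c4_offcall_reads=c4,
        c5_not_duplicate=c5,
        prefilter=passes_site_prefilter(obs_a, obs_b, params),
    )


@dataclass
class NominationReport:
    """Stage-by-stage bookkeeping for a nomination run."""

    n_input: int = 0
    n_not_evaluable: int = 0
    n_prefilter_fail: int = 0
    criterion_failures: dict[str, int] = field(
        default_factory=lambda: {f"c{i}": 0 for i in range(1, 6)}
    )
    n_excluded: int = 0
    n_pass: int = 0
    n_snv: int = 0
    n_indel: int = 0
    n_genes: int = 0

    def reconciles(self) -> bool:
        return self.n_input - self.n_excluded == self.n_pass


def nominate_differentiating_sites(
    sites: Sequence[VariantSite],
    pool_a: str,
    pool_b: str,
    params: FilterParams | None = None,
) -> tuple[list[tuple[VariantSite, FilterVerdict]], NominationReport]:
    """Run the stringent filters over all sites.

    Returns the overall-passing (site, verdict) pairs plus a report with the
    input/excluded/passed counts and, for excluded sites, the count of each
    failing criterion (a site may increment several).
    """
    params = params or FilterParams()
    selected: list[tuple[VariantSite, FilterVerdict]] = []
    report = NominationReport(n_input=len(sites))
    for site in sites:
        verdict = apply_stringent_filters(site, pool_a, pool_b, params)
        if not verdict.evaluable:
            report.n_not_evaluable += 1
            report.n_excluded += 1
            continue
        if not verdict.prefilter:
            report.n_prefilter_fail += 1
            report.n_excluded += 1
            continue
        if verdict.overall:
            selected.append((site, verdict))
        else:
            report.n_excluded += 1
            for name in verdict.failing_criteria():
                report.criterion_failures[name] += 1
    report.n_pass = len(selected)
    report.n_indel = sum(1 for s, _ in selected if s.is_indel)
    report.n_snv = report.n_pass - report.n_indel
    report.n_genes = len({s.gene_id for s, _ in selected})
    return selected, report


def _site_depth(site: VariantSite) -> float:
    depths = []
    for obs in site.observations.values():
        if obs.total_depth is not None:
            depths.append(obs.total_depth)
        elif obs.allele_depths:
            depths.append(sum(obs.allele_depths.values()))
    return float(np.sum(depths)) if depths else float("nan")


def flag_merged_duplicates(
    sites: Sequence[VariantSite],
    genes: Mapping[str, GeneRecord] | None = None,
    depth_fold: float = 3.0,
    allele_count_limit: int = 2,
    user_exclusions: Iterable[str] = (),
) -> set[str]:
    """Heuristic for sequences that may be merged close duplicates.

    Merged paralogs inflate apparent coverage and produce spuriously
    polyallelic pooled genotypes, so a gene is flagged when its median site
    depth exceeds ``depth_fold`` times the cohort-wide median site depth, or
    when any of its sites shows more than ``allele_count_limit`` distinct
    alleles inside a single pool's genotype.  A user-supplied exclusion list
    is unioned into the result.
    """
    flagged: set[str] = set(user_exclusions)
    by_gene: dict[str, list[float]] = {}
    for site in sites:
        d = _site_depth(site)
        if not np.isnan(d):
            by_gene.setdefault(site.gene_id, []).append(d)
        for obs in site.observations.values():
            if obs.genotype is not None and len(obs.genotype.allele_set()) > allele_count_limit:
                flagged.add(site.gene_id)
    all_depths = [d for ds in by_gene.values() for d in ds]
    if all_depths:
        cohort_median = float(np.median(all_depths))
        for gene_id, ds in by_gene.items():
            if cohort_median > 0 and float(np.median(ds)) > depth_fold * cohort_median:
                flagged.add(gene_id)
    return flagged
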