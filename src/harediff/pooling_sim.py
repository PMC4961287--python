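"""Pooled-versus-individual detection experiment.

Sequencing three individuals separately and genotyping each against the
other lineage's pool is the expensive design; pooling them into one library
costs a third as much but redistributes read depth.  This module reproduces
that comparison on depth tables: a balanced, seeded downsampling of the
individuals' reads builds a synthetic pool of a target size, and both
designs are pushed through the stringent nomination filters.

The reference set for recovery is the union of sites detected by the pooled
design and by the individual design *without* the per-individual read
filter; the recovery fraction is the filtered individual-design detections
over that fixed reference, so tightening the per-individual filter can only
lower it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from .lineage_filter import FilterParams, apply_stringent_filters
from .variant_model import PooledGenotype, SiteObservation, VariantSite

DepthTable = Mapping[Hashable, int]


@dataclass(frozen=True)
class DownsampleSpec:
    """Balanced downsampling target: total reads, seed, equal-share flag."""

    target_total_reads: int
    seed: int = 0
    balance: bool = True

    def __post_init__(self) -> None:
        if self.target_total_reads < 0:
            raise ValueError("target_total_reads must be >= 0")


def downsample_balanced(
    per_sample_depths: Mapping[str, DepthTable],
    spec: DownsampleSpec,
) -> dict[Hashable, int]:
    """Draw ``target_total_reads`` reads without replacement across samples.

    Each sample's table maps an arbitrary key (site, allele, ...) to a read
    count.  Under ``balance`` every sample contributes ``target // k`` reads
    plus one extra for the first ``target % k`` samples in seeded order;
    otherwise contributions are proportional to each sample's total mass.
    Within a sample the draw is multivariate hypergeometric over its keys,
    so the output total is exactly the target.
    """
    rng = np.random.default_rng(spec.seed)
    samples = sorted(per_sample_depths)
    totals = {s: int(sum(per_sample_depths[s].values())) for s in samples}
    available = sum(totals.values())
    target = spec.target_total_reads
    if target > available:
        raise ValueError(
            f"target {target} exceeds available reads {available}"
        )

    k = len(samples)
    order = list(rng.permutation(k))
    if spec.balance:
        base, extra = divmod(target, k)
        contributions = {samples[i]: base for i in range(k)}
        for j in range(extra):
            contributions[samples[order[j]]] += 1
        # If a sample cannot cover its share, spill the shortfall onto the
        # others in seeded order.
        shortfall = 0
        for s in samples:
            if contributions[s] > totals[s]:
                shortfall += contributions[s] - totals[s]
                contributions[s] = totals[s]
        for i in order:
            if shortfall == 0:
                break
            s = samples[i]
            room = totals[s] - contributions[s]
            take = min(room, shortfall)
            contributions[s] += take
            shortfall -= take
        if shortfall:
            raise ValueError("could not distribute downsampling target")
    else:
        contributions = {
            s: int(round(target * totals[s] / available)) for s in samples
        }
        drift = target - sum(contributions.values())
        for i in order:
            if drift == 0:
                break
            s = samples[i]
            step = 1 if drift > 0 else -1
            if 0 <= contributions[s] + step <= totals[s]:
                contributions[s] += step
                drift -= step

    pooled: dict[Hashable, int] = {}
    for s in samples:
        table = per_sample_depths[s]
        keys = sorted(table, key=repr)
        counts = np.array([table[k_] for k_ in keys], dtype=np.int64)
        drawn = rng.multivariate_hypergeometric(counts, contributions[s])
        for key, n in zip(keys, drawn):
            if n:
                pooled[key] = pooled.get(key, 0) + int(n)
    return pooled


@dataclass
class PoolingReport:
    """Outcome of the pooled-vs-individual comparison."""

    n_reference: int
    n_pool_detected: int
    n_individual_detected: int
    n_both: int
    recovery_fraction: float  # nan when the reference set is empty
    disposition: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        assert self.n_both <= min(self.n_pool_detected, self.n_individual_detected)


def _individual_read_filter_ok(
    site: VariantSite, individuals: Sequence[str], min_reads: int
) -> bool:
    for ind in individuals:
        obs = site.observations.get(ind)
        if obs is None or obs.genotype is None:
            return False
        for idx in obs.genotype.allele_set():
            if obs.allele_depths.get(idx, 0) < min_reads:
                return False
    return True


def _combined_pool_observation(
    site: VariantSite,
    individuals: Sequence[str],
    pool_id: str,
    pooled_depths: Mapping[Hashable, int],
) -> SiteObservation | None:
    """Merge individual genotypes into one pooled observation.

    The pooled genotype is the concatenation of the individuals' genotypes;
    depths come from the downsampled table (keys ``(gene, pos, allele)``).
    """
    indices: list[int] = []
    quals: list[float] = []
    for ind in individuals:
        obs = site.observations.get(ind)
        if obs is None or obs.genotype is None:
            return None
        indices.extend(obs.genotype.allele_indices)
        q = obs.genotype_quality
        if q is None:
            q = obs.site_quality
        if q is not None:
            quals.append(q)
    depths = {
        idx: pooled_depths.get((site.gene_id, site.position, idx), 0)
        for idx in range(len(site.alleles))
    }
    depths = {i: d for i, d in depths.items() if d}
    template = site.observations[individuals[0]]
    return SiteObservation(
        pool_id=pool_id,
        genotype=PooledGenotype(tuple(indices)),
        allele_depths=depths,
        total_depth=sum(depths.values()),
        site_quality=template.site_quality,
        genotype_quality=min(quals) if quals else None,
        mapping_quality=template.mapping_quality,
        zero_mq_reads=template.zero_mq_reads,
    )


def compare_pooled_vs_individual(
    sites: Sequence[VariantSite],
    individuals: Sequence[str],
    other_pool: str,
    pool_spec: DownsampleSpec | None = None,
    params: FilterParams | None = None,
    per_individual_min_reads: int = 0,
    pooled_params: FilterParams | None = None,
) -> PoolingReport:
    """Compare site detection between the two designs.

    Individual design: a site is detected when the union of the individuals'
    genotypes passes the stringent filters against ``other_pool`` (allele
    depths summed across individuals) and every individual supports each of
    its own called alleles with at least ``per_individual_min_reads`` reads.

    Pooled design: the individuals' depth tables are downsampled (balanced,
    seeded) to ``pool_spec.target_total_reads`` — by default the total depth
    of ``other_pool`` — and the filters run on the synthetic pool.
    """
    params = params or FilterParams()
    pooled_params = pooled_params or params

    per_sample_depths: dict[str, dict[Hashable, int]] = {ind: {} for ind in individuals}
    other_total = 0
    for site in sites:
        for ind in individuals:
            obs = site.observations.get(ind)
            if obs is None:
                continue
            for idx, d in obs.allele_depths.items():
                per_sample_depths[ind][(site.gene_id, site.position, idx)] = d
        obs_b = site.observations.get(other_pool)
        if obs_b is not None:
            other_total += (
                obs_b.total_depth
                if obs_b.total_depth is not None
                else sum(obs_b.allele_depths.values())
            )
    if pool_spec is None:
        pool_spec = DownsampleSpec(target_total_reads=other_total)
    pooled_depths = downsample_balanced(per_sample_depths, pool_spec)

    rows = []
    pool_label = "+".join(individuals) + "_pooled"
    for site in sites:
        # Individual design, full depth, union genotype.
        merged_full: dict[Hashable, int] = {}
        for ind in individuals:
            obs = site.observations.get(ind)
            if obs is None:
                continue
            for idx, d in obs.allele_depths.items():
                key = (site.gene_id, site.position, idx)
                merged_full[key] = merged_full.get(key, 0) + d
        obs_union = _combined_pool_observation(
            site, individuals, "individuals_combined", merged_full
        )
        obs_pooled = _combined_pool_observation(
            site, individuals, pool_label, pooled_depths
        )

        def _verdict(obs: SiteObservation | None, p: FilterParams) -> bool:
            if obs is None:
                return False
            probe = VariantSite(
                gene_id=site.gene_id,
                position=site.position,
                ref=site.ref,
                alts=site.alts,
                observations={
                    obs.pool_id: obs,
                    other_pool: site.observations[other_pool],
                },
            )
            v = apply_stringent_filters(probe, obs.pool_id, other_pool, p)
            return v.overall

        if other_pool not in site.observations:
            ind_base = ind_detected = pool_detected = False
        else:
            ind_base = _verdict(obs_union, params)
            ind_detected = ind_base and _individual_read_filter_ok(
                site, individuals, per_individual_min_reads
            )
            pool_detected = _verdict(obs_pooled, pooled_params)
        rows.append(
            {
                "gene_id": site.gene_id,
                "position": site.position,
                "individual_detected": ind_detected,
                "pool_detected": pool_detected,
                "in_reference": ind_base or pool_detected,
            }
        )

    disposition = pd.DataFrame.from_records(
        rows,
        columns=[
            "gene_id", "position",
            "individual_detected", "pool_detected", "in_reference",
        ],
    )
    n_ref = int(disposition["in_reference"].sum()) if len(rows) else 0
    n_pool = int(disposition["pool_detected"].sum()) if len(rows) else 0
    n_ind = int(disposition["individual_detected"].sum()) if len(rows) else 0
    n_both = (
        int((disposition["pool_detected"] & disposition["individual_detected"]).sum())
        if len(rows)
        else 0
    )
    recovery = n_ind / n_ref if n_ref else math.nan
    return PoolingReport(
        n_reference=n_ref,
        n_pool_detected=n_pool,
        n_individual_detected=n_ind,
        n_both=n_both,
        recovery_fraction=recovery,
        disposition=disposition,
    )
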