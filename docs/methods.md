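# Methods

This note documents the models and procedures implemented in `harediff`,
the defaults they ship with, and the reasoning behind the choices that
were genuinely open.

## Pooled genotypes and the two differentiation criteria

A pool of *k* diploid individuals sequenced as one library is modelled as
a single sample of ploidy 2*k* (default 6, i.e. three individuals). A
pooled genotype is a multiset of allele indices held in canonical sorted
order, so `1/0/0/1/0/1` and `0/0/0/1/1/1` compare equal. The distance
between two equal-ploidy genotypes is the minimum number of allele slots
that must change to convert one multiset into the other, which equals
ploidy minus the multiset intersection size.

Two notions of "differentiating site" coexist because they serve
different analyses:

* **Stringent nomination** (the diagnostic-marker list) applies five
  criteria between the two pools: (c1) the called allele sets are
  disjoint; (c2) both genotype calls have quality ≥ 100 (the per-sample
  `GQ` when present, else the site `QUAL` — the genotype-level reading
  matches the intent of "genotypes supported by" a quality value);
  (c3) every called allele has ≥ 30 supporting reads in its pool;
  (c4) at most 1 read per pool supports an allele outside the called
  genotype; (c5) the gene is not suspected to be a merged duplicate.
  A site-level pre-filter (`MQ ≥ 30`, `MQ0 = 0`, caller `QUAL ≥ 30`)
  runs before the criteria and is counted separately in reports.
  "Observed alleles" in c1 means the alleles of the called genotype;
  stray reads on uncalled alleles are c4's business. c1 is implemented
  as full disjointness — the strictest reading — because the nomination
  list targets fixed differences; a shared reference allele fails it.
* **50%-differentiation** (the energy-gene rate analysis) calls two
  genotypes differentiated when the slot distance is at least half the
  ploidy: `0/0/0/0/0/0` vs `0/0/0/1/1/1` qualifies (3/6), one stray alt
  (1/6) does not. In the pipeline's `half` path this replaces c1 while
  quality/depth/duplicate criteria still apply.

Missing observations make a site "not evaluable" — it is excluded with a
reason, never silently dropped, and every report reconciles
`sites_in − excluded = sites_out`.

The merged-duplicate heuristic (c5) is necessarily a stand-in: collapsed
paralogs manifest as inflated coverage and spuriously polyallelic pooled
genotypes, so a gene is flagged when its median site depth exceeds 3× the
cohort median (`depth_fold`) or any within-pool genotype carries more
than 2 distinct alleles (`allele_count_limit`); a user exclusion list is
unioned in. Both knobs are exposed because no principled universal
threshold exists.

## Effect classification

Each (site, alt) pair is classified by translating the affected codon(s)
before and after substitution: equal amino acids → synonymous; alt is a
stop → nonsense; otherwise non-synonymous (stop-loss included — it
changes the protein). Length-changing alleles are indels, frameshift when
the net length change is not a multiple of 3. Nuclear genes use the
standard code (NCBI table 1), mtDNA-encoded genes the vertebrate
mitochondrial code (table 2); the difference is material for OXPHOS
subunits (TGA = Trp, AGA/AGG = stop in the mitochondrial code). Codon
indexing is 1-based with `offset = ((pos − 1) mod 3) + 1`. A reference
mismatch against the CDS raises an error naming gene, position and both
bases. Trailing incomplete codons on assembled transcripts are trimmed
with a warning; internal stops are flagged (possible pseudogene) but not
fatal.

## Gene-set rates and contrasts

For a gene set, `total_rate = differentiating sites in member genes /
summed analysed CDS nt` and `nonsyn_rate` uses the same nucleotide
denominator restricted to protein-changing sites. This is deliberately
*not* a dN/dS-style per-site normalisation — the statistic is mutations
per nucleotide. Nonsense counts inside the non-synonymous numerator;
indels count in the total numerator only (configurable via
`include_indels_in_nonsyn`, since the handling of the few indels in such
lists is conventionally ambiguous). A multi-allelic site counts once,
non-synonymous if any alt is protein-changing. A gene in several sets
(SDHA is both a Krebs enzyme and a complex II subunit) contributes to
each. An empty denominator yields an undefined row (NaN), not zero.

Fold changes are ratios of rates rounded half-up (decimal arithmetic, not
float banker's rounding) to 1 decimal by default, matching how such
figures are conventionally quoted. On the packaged published rate table
this yields 3.5 (nuclear OXPHOS ns vs glycolysis), 2.7 (vs Krebs), 10.8
and 8.3 (complex IV nuclear ns vs the two pathways). The quoted pair
"4.6 and 3.5" for the mtDNA ns contrast does not follow from the printed
rates by division (0.001409/0.000344 → 4.1; /0.000451 → 3.1); the
contrast report surfaces the computed ratios and takes no side.

## Pooling experiment

The pooled-vs-individual comparison operates on depth tables (site ×
allele read counts), not raw reads: the phenomenon of interest —
detection loss when one individual's coverage drops at a site, and its
rescue when reads are pooled — lives entirely at that resolution.
Balanced downsampling gives every individual `target // k` reads plus one
for the first `target mod k` in seeded order; within an individual the
draw is multivariate hypergeometric over its (site, allele) mass, so the
output total is exact and allele fractions are preserved in expectation.
If an individual cannot cover its share the shortfall spills to the
others in seeded order.

Individual-design detection requires the union of individual genotypes to
pass the stringent filters against the other pool *and* every individual
to support each of its own called alleles with ≥ `per_individual_min_reads`
reads (default 0; 10 reproduces the published extra filter). The recovery
denominator is fixed as the union of pooled detections and unfiltered
individual detections, so recovery is monotone non-increasing in the
per-individual read filter.

## Barcode distances and the clock

Uncorrected p-distance with pairwise deletion: columns where either
sequence has a gap or non-ACGT symbol are dropped per pair; a pair with
no comparable column is NaN. Group means average over all between-group
pairs, or all unordered within-group pairs (≥ 2 sequences required).
p-distance is the minimal assumption — no substitution-model correction
(K2P etc.) is offered because the downstream clock arithmetic is plainly
linear: split time (Myr) = divergence (%) / rate (% per Myr), e.g. 3.4%
Cytb divergence at 4%/Myr → 0.85 Myr.

## Homology selection

Order of operations: e-value filter (≤ 1e-10), best hit per query by bit
score, longest-CDS de-duplication among queries sharing a subject gene,
then the reciprocal ≥ 70% coverage filter. The narrative order of such
protocols is filter-last; `coverage_before_dedupe=True` selects the
alternative. Ties (equal bit scores; equal CDS lengths) resolve by higher
coverage sum, then lexicographic id, making the mapping invariant to
input row order — a property the test suite checks by shuffling.

## The synthetic generator

The generator defines the study conditions for all recovery tests. It
emulates:

* one CDS per reference gene-set member (76 genes), lengths ~
  Normal(1500, 400) nt floored at 300 and rounded down to codons —
  about 110–140 kb of coding sequence per draw; valid reading frames
  (ATG start, no internal stop under the gene's own code, terminal stop);
* differentiating sites planted per gene at the published per-set rates
  (total and non-synonymous per nucleotide), the non-synonymous status
  enforced by rejection sampling of the substituted base; 1% of planted
  sites are indels (1-nt frameshift or 3-nt in-frame insertions);
* fixed-disjoint pooled genotypes (`0×6` vs `1×6`) for planted sites by
  default, with `half_criterion_fraction` optionally planting
  `0/0/0/0/0/0` vs `0/0/0/1/1/1` patterns that only the 50% path accepts
  — this separates the two analysis paths in tests;
* shared polymorphisms (both pools carry both alleles) at 0.002/nt as
  filter noise that must fail exactly the private-allele criterion;
* engineered-failure sites (10% of the planted count, cycling c1–c5),
  each designed to fail exactly its named criterion while passing the
  other four, hosted in per-criterion decoy genes outside every gene set
  so they cannot perturb rate recovery;
* overdispersed depths: each called allele gets `30 + NegBin(mean 40,
  dispersion 5)` reads, mimicking expression-driven coverage
  heterogeneity while satisfying the depth thresholds by construction;
  genotype qualities Uniform(150, 900) for passing sites, Uniform(40, 99)
  for designed quality failures; MQ 60, MQ0 0.

It does **not** emulate: read-level errors and mapping artefacts,
assembly chimeras beyond the duplicate-flag scenario, allele-frequency
spectra within pools (planted sites are fixed differences), linkage, or
quality–depth correlation. Passing recovery tests therefore demonstrates
the correctness of the filtering/annotation/rate machinery under the
stated conditions, not robustness to upstream calling errors in real
data.

Because depth and quality floors satisfy the thresholds by construction,
recall of planted strict sites is exactly 1 with zero false positives;
the stochastic content of the recovery tests is the binomial planting
itself. Recovery is asserted within 3 binomial standard errors of the
planted expectation (conditional on each draw's gene lengths), averaged
over ten fixed seeds — roughly 1.2 Mnt of CDS per recovery run, sized to
keep the full suite under a few seconds while leaving the binomial check
statistically meaningful.

All randomness flows from a single `numpy` generator seeded from the
config; identical configs give byte-identical FASTA/VCF/TSV fixtures
(the VCF writer emits no timestamps).

## Numerical and degenerate-input choices

* Thresholds are inclusive (`≥`): depth 29 fails a 30-read criterion,
  coverage 0.70 passes a 70% cut.
* Rates with zero denominators are NaN ("undefined"), never 0; fold
  changes with non-positive denominators return `None`.
* `DP` and the `AD` sum are both recorded and neither is derived from
  the other (caller conventions differ).
* Ploidy is a parameter throughout, so diploid individuals and hexaploid
  pools share one code path; genotype comparisons require equal ploidy
  and raise otherwise.
* Multi-allelic sites stay single records (one `VariantSite`, one row
  per alt in annotation).

## Known limitations

* The merged-duplicate heuristic is a reproducible proxy; real
  paralog-collapse detection would use alignment-level evidence.
* The generator plants fixed differences only; sites segregating within
  a pool at intermediate frequency are represented only by the
  shared-polymorphism noise class.
* Absolute published counts (e.g. genome-wide site totals) are functions
  of the original sequencing data and are out of scope; the pipeline
  reproduces the *arithmetic* and the *procedure*, and its rate recovery
  is validated on synthetic ground truth.
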