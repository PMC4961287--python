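# harediff

Pooled-genotype SNP filtering and lineage-differentiation analysis for
two-lineage transcriptome data, built around the European-vs-Anatolian
comparison of the brown hare (*Lepus europaeus*).

## The problem

The brown hare carries two deeply split maternal lineages — one European,
one Anatolian — that stay geographically separated even where they meet in
a broad contact zone. One route to understanding that separation is
mitonuclear coevolution: the OXPHOS machinery is assembled from both
mtDNA- and nuclear-encoded subunits, so nuclear OXPHOS genes are expected
to accumulate protein-changing substitutions faster than purely nuclear
pathways (glycolysis, Krebs cycle) as they track the fast-evolving mtDNA.

Testing this with RNA-seq is cheap if each lineage is sequenced as a
*pool* of individuals — three diploid hares pooled into one library are
genotyped as a single hexaploid sample. That design needs dedicated
machinery, which this package provides as a tested, reusable pipeline for
the post-variant-calling stages:

* **variant model** — pooled genotypes of arbitrary ploidy (default 6),
  VCF in/out (`GT`/`AD`/`DP`/`GQ`/`MQ`/`MQ0`), CDS FASTA plus a gene-set
  membership table;
* **lineage filter** — the five stringent criteria nominating
  lineage-diagnostic sites (private alleles, genotype quality ≥ 100,
  ≥ 30 reads per called allele, ≤ 1 off-call read, no merged-duplicate
  suspicion) and the 50%-differentiation criterion on pooled genotypes
  (`0/0/0/0/0/0` vs `0/0/0/1/1/1` is differentiated);
* **effect annotation** — synonymous / non-synonymous / nonsense / indel
  per (site, alt), using the standard code for nuclear genes and the
  vertebrate mitochondrial code for mtDNA-encoded genes;
* **gene-set rates** — differentiating mutations per nucleotide, total
  and non-synonymous, per pathway and per OXPHOS complex split by genome
  of origin, with half-up-rounded fold-change contrasts;
* **pooling experiment** — balanced seeded downsampling of individual
  read masses into a synthetic pool, and the pooled-vs-individual
  detection comparison;
* **barcode distances** — uncorrected p-distances within/between groups
  of aligned COI barcodes, plus linear molecular-clock arithmetic;
* **homology filter** — 1:1 homolog selection over tabular alignment
  hits (best bit score, longest CDS per subject gene, reciprocal ≥ 70%
  coverage);
* **synthetic data** — a seeded two-lineage generator with a ground-truth
  ledger, so every stage is testable without any sequencing download.

## Worked example

Recompute the headline fold-change contrasts from the packaged published
rate table, then run the full pipeline on a synthetic dataset planted at
those same rates:

```python
from harediff import RateTable, RunConfig, SimConfig, fold_change, run_pipeline
from harediff.reference_data import PUBLISHED_RATES

table = RateTable.from_rates(PUBLISHED_RATES)
for den in ("glycolysis", "krebs"):
    print("OXPHOS-nuclear ns vs", den, "->",
          fold_change(table["oxphos_nuclear"].nonsyn_rate, table[den].nonsyn_rate))

report = run_pipeline(RunConfig(sim=SimConfig(seed=1)))
c = report.counters()
print({k: c[k] for k in ("sites_in", "excluded", "sites_out",
                         "snvs_out", "indels_out", "genes_out")})
row = report.rate_table["glycolysis"]
print(f"glycolysis: {row.total_sites} sites / {row.denominator_nt} nt -> "
      f"total {row.total_rate:.6f}, nonsyn {row.nonsyn_rate:.6f}")
```

prints

```
OXPHOS-nuclear ns vs glycolysis -> 3.5
OXPHOS-nuclear ns vs krebs -> 2.7
{'sites_in': 1283, 'excluded': 391, 'sites_out': 892, 'snvs_out': 875, 'indels_out': 17, 'genes_out': 92}
glycolysis: 79 sites / 17871 nt -> total 0.004421, nonsyn 0.000448
```

The first two lines are the published mitonuclear signal: nuclear OXPHOS
subunits accumulate protein-changing differentiating substitutions 3.5×
faster than glycolysis and 2.7× faster than the Krebs cycle, although
their *total* substitution rates are similar. The counter line is the
filter bookkeeping on the synthetic run (1283 sites in, 391 excluded by
the five criteria and the shared-polymorphism noise, 892 nominated), and
the last line shows the glycolysis row of the recomputed rate table —
close to the planted 0.004685 / 0.000344 per nucleotide, within binomial
sampling error of the 17.9 kb of glycolysis CDS in this draw.

The same workflow is available from the shell:

```bash
harediff simulate --out fixtures --seed 1
harediff run-all --vcf fixtures/variants.vcf --fasta fixtures/genes.fasta \
    --gene-table fixtures/gene_sets.tsv --out results
harediff pooling-sim --n-sites 300 --out pooling.tsv
```

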