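# ldcohorts

Detection of **linkage cohorts** — blocks of co-varying SNPs — in population
genotype matrices, by deliberately *relaxing* the standard population-genetics
filters and then looking at what they would have thrown away.

Reduced-representation SNP surveys (GBS/RADseq) are normally filtered for
Hardy–Weinberg equilibrium and linkage disequilibrium before analysing
population structure. Those filters also delete the most biologically
interesting signals a dataset can carry: sex-linked paralogue blocks (in
neo-XY systems the X/Y paralogues make the heterogametic sex constitutively
heterozygous), and genomic islands of differentiation (tightly linked loci
with elevated between-population divergence). `ldcohorts` implements the
detection workflow that keeps those loci in:

1. **Permissive QC** — drop samples with > 20 % missing calls, loci with
   > 5 % missingness or < 5 % minor allele frequency (the "5 %-only" set);
   HWE (exact test, Bonferroni-style absolute cutoff *p* < 2.5 × 10⁻⁵) and
   greedy LD pruning (*r*² > 0.5) are applied only to build the conventional
   "fully filtered" contrast set.
2. **PCA loading cohorts** — correlation-matrix PCA of dosages with
   supplementary samples projected after fitting; for each axis, the cohort of
   loci with |loading| > 0.050 (the uniform reference loading is
   1/√p ≈ 0.022 at p = 2,077, so the cutoff flags > 2× uniform weight).
3. **LD network analysis** — loci as vertices, genotypic *r*² as edges; the
   single-linkage merge forest over descending *r*² thresholds is scored per
   cluster with

   λ = *n* · ( x̄(r² within cluster) − x̄(r² cluster ↔ absorbing cluster) ),

   absent edges counting as r² = 0; clusters with λ above
   median(λ) + φ·MAD(λ) and at least *e* = 10 edges (defaults φ = 2) are
   outlier clusters.
4. **Integration** — cross-tabulation of LD clusters with loading cohorts,
   per-scaffold concentration summaries, inter-deme allele-frequency
   differentials, and **SNP-based sex imputation** from the heterozygous
   fraction over the sex-linked cohort.

A first-class synthetic-data module generates genotype matrices with the
architecture the method targets — a neo-XY paralogue block (heterogametic
samples ~99.3 % heterozygous, homogametic ~99.9 % homozygous), a
geographically differentiated island block (25 % inter-deme allele-frequency
differential), a third independent linked block, and a Balding–Nichols
two-deme neutral background — with full truth tables, so every stage is
verifiable without the original data.

## Worked example

```python
from ldcohorts import SimulationConfig, simulate, run_pipeline

gm, truth = simulate(SimulationConfig(seed=1))   # 188 samples x 2,077 SNPs
res = run_pipeline(gm)
print(res.report.to_text())
```

```
stage                 axis         input  removed  retained
sample_missingness    samples        188        0       188
locus_missingness_maf loci          2077       66      2011
hwe                   loci          2011        1      2010
ld_prune              loci          2010      338      1672
```

Note the planted sex-paralogue block *survives* the HWE stage (pooled excess
heterozygosity at 39 % males gives exact *p* ≈ 10⁻³–10⁻⁴, above the
2.5 × 10⁻⁵ cutoff) and is only removable by LD pruning — which is exactly why
the conventional pipeline never sees it.

```python
for c in res.ld_estimator.clusters_:
    print(f"LD cluster {c.label}: {c.size} loci, defining r2={c.level:.2f}, "
          f"lambda={c.lam:.1f}, edges={c.n_edges}")
print({k: len(v) for k, v in res.pc_cohorts.items()}, "| sex axis:", res.sex_axis)
```

```
LD cluster X: 87 loci, defining r2=1.00, lambda=87.0, edges=3741
LD cluster A: 37 loci, defining r2=1.00, lambda=36.6, edges=666
LD cluster B: 217 loci, defining r2=0.95, lambda=211.2, edges=23436
{'PC1': 217, 'PC2': 87, 'PC3': 37, 'PC4': 53} | sex axis: 1
```

The three LD clusters are the planted blocks; each is ≥ 97 % contained in the
matching PC loading cohort (here PC1 carries the 217-locus sex block, PC2 the
88-locus island block, PC3 the 37-locus independent block; PC4's 53 loci are
the most demically differentiated neutral tail):

```python
print(res.overlap.pct_of_cluster.round(1))
print(res.sex_calls.head(4).to_string(index=False))
```

```
         X      A      B
PC1    0.0    0.0  100.0
PC2  100.0    0.0    0.0
PC3    0.0  100.0    0.0
PC4    0.0    0.0    0.0
sample_id  het_fraction   call
 wild0000      0.000000 female
 wild0001      0.000000 female
 wild0002      0.004808 female
 wild0003      0.990654   male
```

Sex calls match simulated truth for 100 % of the 188 samples at this seed,
and the island cohort's median inter-deme differential comes out at 0.224
(generative value 0.25; the single shared haplotype makes this estimate noisy
at n = 175, s.e. ≈ 0.05).

The same chain is scriptable from a shell:

```sh
ldcohorts simulate --seed 1 --out fixture/
ldcohorts run --vcf fixture/genotypes.vcf --samples fixture/samples.tsv --out results/
```

which writes the filter report, both PCAs (scores, loadings, descending
loading-profile plots), the LD edge list and merge tree (Newick), outlier
clusters (JSON), the overlap matrix, scaffold summaries, sex calls, deme
differentials, and a checksummed run manifest. `filter`, `pca`, `ldnet` and
`integrate` run the stages standalone.

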