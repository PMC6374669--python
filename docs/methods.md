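# Methods

## The detection problem

A diploid genotype matrix (n samples × p biallelic SNPs, dosages 0/1/2 with
missing calls) is assumed to contain, besides a neutral background, one or
more *linkage cohorts*: sets of loci whose genotypes co-vary across samples
because they are carried on a shared genomic structure. The two motivating
structures are (i) X/Y paralogous SNPs in a neo-XY sex-determination system,
where reads from the diverged neo-X and neo-Y copies co-align and make
heterogametic individuals appear constitutively heterozygous, and (ii)
islands of genomic differentiation, i.e. physically clustered loci with
elevated between-population divergence. Both violate the HWE/LD assumptions
of standard SNP QC, which is why conventional filtering removes them; the
package's pipeline detects them instead, and uses the conventional fully
filtered dataset only as a contrast.

## Filtering model

Stages are sequential and literal in their inequality directions (boundary
values are retained):

| stage | rule | default |
| --- | --- | --- |
| sample QC | drop sample if missing fraction > `sample_max_missing`, assessed over loci with missingness ≤ `locus_prefilter_missing` | 0.20 / 0.20 |
| locus QC ("5 %-only") | drop locus if missingness > `locus_max_missing` **or** MAF < `min_maf` | 0.05 / 0.05 |
| HWE | drop locus if exact-test p < `hwe_bonferroni_p` (absolute printed-style threshold; `hwe_alpha / n_tests` mode available) | 2.5 × 10⁻⁵ |
| LD pruning ("FF") | greedy sweep in genome order; drop locus if r² with any retained locus > cutoff | 0.5 |

MAF and HWE use complete cases per locus; a locus with zero calls fails the
MAF filter by convention. The HWE test is the exact conditional test:
given the allele counts, all heterozygote counts of matching parity are
enumerated and the probabilities of configurations no more probable than the
observed one are summed (log-gamma arithmetic; a χ² mode exists for
large-sample work). An absolute Bonferroni-style threshold is the default
because a printed threshold is reproducible, whereas α/p changes with every
refiltering (0.05/2,077 ≈ 2.41 × 10⁻⁵, not the canonical 2.5 × 10⁻⁵).

A consequence worth stating: a sex-paralogue locus observed in a ~39 %-male
pooled sample (39 % heterozygotes, the rest homozygous-reference) has exact
HWE p ≈ 10⁻³–10⁻⁴ — excess heterozygosity, but *above* the 2.5 × 10⁻⁵
cutoff. The sex cohort therefore survives HWE filtering and is removed only
by LD pruning. The test suite pins this behaviour.

## LD and the network statistic

r² is the squared Pearson correlation of dosage vectors over pairwise
complete cases (genotypic/composite LD — phase-free, which is all that
unphased GBS genotypes support). All locus pairs are considered regardless of
scaffold: with ~1,000 short scaffolds, physical proximity is unknowable and
inter-scaffold linkage is precisely the signal of interest. Pairs are
computed with masked cross-products (a handful of p×p matrix
multiplications), and pairs below `min_r2_stored` (default 0.1) are not
materialized; in all downstream statistics absent pairs count as r² = 0.

The merge forest is built by union–find over edges in descending r²
(ties broken by locus-index pair, so the tree is invariant to edge input
order); it equals the single-linkage dendrogram of the sparse r² similarity
matrix, verified against a connected-components oracle in the tests. Each
cluster C (size n) is scored at the moment it dissolves into a larger
cluster M at level t (final roots dissolve into the disconnected remainder
at level 0):

    λ(C) = max(0, n · ( x̄({r² within C}) − x̄({r² between C and M∖C}) ))

with x̄ the **mean** by default. The median is available
(`lambda_stat="median"`) but is not the default for a structural reason: when
a tight block accretes weakly linked hangers-on (e.g. neutral loci that share
the block's deme association — admixture LD), the block's internal pairs
outnumber the added pairs, the median contrast stays saturated at the block's
internal LD, and λ then grows with cluster size alone; the per-lineage
maximum would land on straggler-inflated superclusters. The mean contrast is
diluted by exactly those weak pairs and turns over at the true block
boundary. Both modes are oracle-tested against brute-force pair enumeration.

A cluster is an **outlier cohort** when λ > median(λ) + φ·MAD(λ) over all
scored clusters (MAD unscaled, φ = 2) and it carries at least *e* = 10 edges
above its absorption level. Among nested outliers the highest-λ cluster per
lineage is reported, so reported cohorts are mutually disjoint; labels run
X, A, B, … by descending defining r². A headline size floor (default: more
than 1 % of analysed loci) separates sizable cohorts from incidental pairs.
Raising φ or *e* never increases the number of reported cohorts.

## PCA and loading cohorts

PCA is an SVD of the column-standardized dosage matrix over the *fitted*
samples only (correlation-matrix PCA by default, divisor-n eigenvalues;
covariance mode via `scale=False`). Missing dosages are mean-imputed per
locus, i.e. contribute zero after standardization — adequate at ≤ 5 %
missingness and exactly what keeps a fully missing projected sample at the
origin. Loadings are unit-norm with the largest-magnitude entry per axis
made positive. Samples flagged `supplementary` (e.g. lab-bred crosses) are
projected onto the fitted axes afterwards so they cannot influence them.

A loading cohort on axis k is {j : |v_jk| > 0.050}. The threshold is the
published operating point; against the uniform loading 1/√p it means "more
than ~2.3× uniform weight" at p ≈ 2,000. Absolute values are used because
loading sign carries no cohort meaning. Axis *identity* is never decided by
index: the sex axis is the cohort whose per-sample heterozygous fractions
split bimodally (gap ≥ 0.5) and, when any samples carry known sexes, whose
heterozygosity calls agree with them; with no sexed samples the fallback
discriminator is the scarcity of homozygous-alternate genotypes, which
distinguishes a paralogue block (alt allele rides the Y copy, so hom-alt is
essentially absent) from an equally bimodal latent-haplotype block.

## Sex imputation

For each sample, the heterozygous fraction over the sex cohort's loci
(complete cases) is thresholded at 0.5 with an optional dead zone; above →
heterogametic (male), below → homogametic (female), inside or no calls →
ambiguous. The two observed clusters sit near 0.99 and 0.001, so any mid
threshold separates them; 0.5 is the symmetric choice and the dead zone is
exposed for noisier data.

## Synthetic data: what it emulates, and what it does not

Defaults are the study conditions: 175 wild + 13 supplementary samples,
2,077 loci on ~1,000 scaffolds, 39 % males, two equal demes, blocks of
217 (sex) / 88 (island) / 37 (independent) loci, 2 % uniform missingness.
Block loci are concentrated on a few scaffolds (62/18/8) via a 1/rank-skewed
partition. The sex block writes heterozygotes into males with a 0.007
flip-to-homozygote error and homozygous-reference into females with a 0.001
flip-to-heterozygote error, reproducing the 99.3 %/99.9 % contrast. Island
and third blocks copy one latent biallelic haplotype per sample (complete
within-block LD; island alt frequency 0.50 north vs 0.25 south, third block
0.35 everywhere). The neutral background draws ancestral frequencies from
U(0.05, 0.5) and per-deme frequencies from a Balding–Nichols beta model at
F_ST = 0.02. Supplementary samples are inter-deme F1s (one allele per deme
at neutral and island loci), so they project between the parental clusters.
The seed fully determines the output, down to byte-identical VCFs.

Deliberate omissions: no recombination maps or LD decay within blocks (a
partial-decay knob would be the first extension), no genotyping-error model
beyond symmetric flips, no depth-dependent missingness, no fine-scale
geographic structure. Consequently, passing recovery tests demonstrates the
pipeline's behaviour under the assumed architecture, not its power under LD
decay or batch artifacts.

Two quantitative notes on the generator's sampling noise:

* at F_ST = 0.02 the sex block (λ ≈ 217) dominates the geographic signal
  (Σ r² ≈ 40), so the sex axis is typically PC1 in the simulation even though
  it was the second axis in the motivating beetle data — this is why axis
  identity is diagnosed, not indexed; with stronger differentiation
  (F_ST ≳ 0.3) the geographic axis comes first, which the tests exercise;
* the island differential estimate has s.e. ≈ √(2·p̄q̄/(2·88)) ≈ 0.054 at
  n = 175 because all island loci share one latent haplotype — per-locus
  averaging does not reduce the error. Its recovery band (± 0.05) therefore
  holds typically, not surely, for any given seed.

## Numerical and degenerate-input choices

* Dosages are int8 with −1 as the missing sentinel; it is never counted as
  an allele.
* Monomorphic loci: MAF 0, HWE p = 1; pairs involving a locus monomorphic
  over the pair's complete cases are skipped (no edge, NaN in the dense
  matrix); invariant loci get scale 1 and contribute nothing to PCA.
* Greedy pruning keeps the first locus in genome order (`tie="maf"` keeps
  the higher-MAF member instead); the retained set provably has no pair
  above the cutoff.
* Exact-test tie handling: configurations with probability within a 1e-12
  relative factor of the observed one are counted as ties.
* λ uses a dense r² reconstruction from the stored edge list; memory is
  O(p²) floats, fine for the ~10³–10⁴ loci this method targets.
* Newick export encodes heights as 1 − r², so branch lengths are
  non-negative as thresholds relax.
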