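# Methods

## Coordinate model

All internal coordinates are 1-based and fully closed, the convention of the
clinical cytogenetics notation the deletion intervals are given in
(`21:41,994,799-43,447,106`; `21:44,361,567-46,944,323`, hg38). BED input is
0-based half-open and converted on load; `chr21` and `21` are equated. The
four region classes (DELETION_1, DELETION_2, VICINITY, OUTSIDE) partition any
gene set for a fixed vicinity width. Vicinity is the distance to the nearest
deletion boundary, default 1,000,000 bp. Two placement modes exist:
`start_point` (default) assigns a gene by its start coordinate — the only
option when an annotation carries start positions alone, as the published
per-gene table does — and `any_overlap` counts any shared basepair. Abutting
intervals are distinct; overlapping deletion intervals are rejected at load.

## Differential expression core

A deliberately transparent two-group negative-binomial model, not a
re-implementation of a full DE framework:

- **Normalization.** Median-of-ratios size factors: factor_j = median over
  genes with positive counts in every sample of count_gj / geometric mean.
  No rescaling is applied afterwards (factors of an all-positive matrix have
  geometric mean 1). *Base mean* is the mean of normalized counts over the
  samples in the contrast.
- **Dispersion.** Per-gene method-of-moments within groups: from
  Var(K/s) ≈ q·mean(1/s) + α q², pooled across the two groups with
  degrees-of-freedom weights, clipped to [1e-8, 10] so degenerate genes keep
  finite Wald statistics. No shrinkage, no outlier refitting.
- **Wald test.** log2 fold change log2(q̂_t/q̂_r) with a half-count pseudo
  value on the normalized scale (0.5·mean(1/s)) so genes silent in one group
  stay finite; delta-method standard error
  Var(ln q̂) = Σ(1/s)/(n² q̂) + α/n per group; two-sided p from the normal
  reference; BH adjustment over all tested genes (genes with base mean 0 are
  not tested).
- **DEG rules.** UP iff 2^log2FC ≥ 1.25, DOWN iff 2^log2FC ≤ 0.75 (both
  boundaries included — the weakest published row, JAM2 at 2^-0.42 = 0.7476,
  only qualifies under the inclusive unrounded linear reading), adjusted
  p strictly < 0.05, base mean ≥ 5 (below 5 ⇒ FILTERED_LOW_EXPRESSION
  regardless of the statistics).
- Technical replicates are treated as independent columns by default,
  matching the triplicate design of the data this models; a
  `collapse_replicates` switch sums them per line instead.

**Calibration and known behaviour.** Under the model-matched null (iid NB
columns, three lines per genotype in triplicate, 2,000 genes) the raw Wald p
is approximately uniform; the empirical type-I rate at nominal 0.05 is
about 0.06 (the normal reference is mildly liberal at 9 vs 9 samples, as in
the standard NB Wald frameworks). Under realistic between-line biological
variability the per-gene test is **anticonservative** (≈0.16 at nominal 0.05
with a per-gene·line log-normal factor of SD 0.2), because replicates within
a line share that factor while the model treats them as independent. This is
a property of the design being modelled, not a defect to silently patch: all
set-level inference in this package goes through the permutation null, which
is insensitive to per-gene miscalibration. A second known behaviour is mild
fold-change compression under asymmetric dosage: with ~7% of genes shifted
1.5× in one group, median-of-ratios factors absorb a little of the shift and
the recovered trisomic median log2FC sits ≈0.04–0.08 below log2(1.5) — the
same compression any global-normalization DE tool shows.

## Mirrored-gene statistic

The trisomy lines are merged into one condition (relabelling only; column
data untouched) before the trisomy-vs-euploid contrast. For DE tables A
(monosomy) and B (trisomy) over one gene universe (a universe mismatch is an
error, never a silent inner join): shared DEGs are genes UP/DOWN in both;
mirrored genes are shared DEGs with differing directions. The headline
fraction divides |mirrored| by |DEGs in A|; the "excluding deleted" variant
removes deletion-class genes from the numerator only, matching the published
"154 of 1951" arithmetic (154/1951 = 7.89%, printed as 7.8% — the package
reports full precision).

**Permutation null.** The published analysis permuted the monosomy DE output
(n = 1,000) and re-applied the identical filtering; the precise scheme is
not stated. The scheme adopted here is the most literal reading: shuffle
table A's per-gene (log2FC, adjusted p, base mean) triples over the gene
labels of the common universe, re-apply the full DEG decision rules with the
identical thresholds, and recompute the mirrored fraction against the fixed
table B. This preserves A's marginal DEG count and direction proportions
while breaking gene-level association with B. A sign-flip alternative
(randomize only the directions of A's DEGs, keep gene assignment) is
available behind `scheme="sign_flip"`. The test is one-sided for an excess
of mirrored genes with the add-one empirical p,
(1 + #{null ≥ observed})/(n + 1) ∈ [1/(n+1), 1]; the null summary reports the
mean and the standard error (SD of null fractions / √n). The null stream
depends only on the seed and the per-gene values, not on input row order.

**Calibration conditions.** Permutation-p uniformity is checked on data
generated under the exchangeability assumptions of the shuffle null: trans
effects drawn independently per aberrant genotype with no mirrored subset,
no cis structure, and iid NB columns; the trans DEG count matches the
study-scale DEG rate (13.7% of genes), 2,000 genes, three lines per genotype
in triplicate, 1,000 permutations, 50 seeds (KS test). Two realistic
departures make the test *conservative*, never anticonservative, and are
pinned by tests: (i) cis dosage effects couple the two contrasts through
genomic position; (ii) both contrasts share the euploid control group, so
extra-NB noise in the controls correlates their false calls with the same
sign, inflating the shuffle null relative to the observed overlap. Small
published permutation p-values are therefore, if anything, understated.

## Allele-specific expression

A heterozygous site's allelic fraction is alt depth / (ref + alt depth)
(a ref-based toggle exists). Filtering follows the study rules: indels out
(an indel is any record with len(ref) ≠ len(alt)), coverage below 50
out — coverage read as summed allelic depth, boundary 50 kept. Filtering is
idempotent. Summaries count and average fractions per region class; a
heterozygous call inside a deletion (impossible under clean hemizygosity) is
reported as an anomaly, not an error. VCF I/O is minimal VCFv4.2 through
pysam: AD preferred, DP fallback (DP-only records keep their coverage for
filtering but have no meaningful fraction).

## Over-representation

For DEG set D in universe U and term T: expected overlap |D||T|/|U|, fold
enrichment k/expected (depletions < 1 are reported, matching analyses that
retain them), significance from the exact hypergeometric distribution with
the two-sided minimum-likelihood convention (identical to the two-sided
Fisher exact test), BH FDR, filter FDR ≤ 0.001 ("filtered against an
FDR > 0.001" read as discarding terms above the cutoff; the inverse reading
is implausible). Term members outside the universe are dropped and counted.
No pathway database is bundled; sets come from GMT files, so published
pathway lists are reproducible only given the same database version.

## Synthetic data generator

Emulates the study: 3 euploid control lines, 1 ring-chromosome (monosomy)
line, 2 trisomy lines, technical triplicates (all configurable). Per gene,
baseline expression is log-normal (meanlog 4.0, sdlog 1.5 — median ≈ 55
counts, right-skewed like real gene-level data); per line a log-normal
biological factor (sdlog `sigma_line` = 0.2), per replicate a smaller
technical factor (sdlog 0.05) and a uniform library-size factor in
[0.7, 1.3]; counts are NB with dispersion α = 0.05 (Poisson at α → 0).
Between-line biological variance is not quantified in the source study —
these are free parameters, stated here, not data-derived claims.

Dosage structure: deleted genes (default 30, placed uniformly inside the two
deletion intervals) at 0.5× in the monosomy condition; all chromosome-21
genes (default 7% of genes) at 1.5× in the trisomy condition. Trans effects:
`n_trans_degs` per aberrant genotype with |log2FC| ~ Uniform(0.5, 2) and
random sign; a `mirrored_fraction_true` subset is shared between genotypes
with forced opposite signs, the remainder drawn independently per genotype
(genes independently hit in both are labelled by their realized sign
pattern). Truth labels: cis_deleted, cis_trisomic, trans_mirrored,
trans_concordant, trans_mono_only, trans_tri_only, null. Heterozygous
variants draw alt depth ~ Binomial(depth, 0.5) (depth ~ Poisson(100) by
default) unless listed monoallelic; a configurable fraction are indels.
Everything is bitwise-deterministic under a fixed seed.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level effects (mapping bias, multi-mapping,
GC/length bias), transcript-level quantification uncertainty, correlated
co-expression modules (trans effects are drawn independently per gene),
batch structure, and allele-depth tables coupled to the expression matrix.

## Problem sizes and numerical choices

Simulation-based tests use 300–2,000 genes, 50 seeds for calibration and
1,000 permutations — sizes at which every statistic involved is stable while
the whole suite stays interactive. Tie-breaks and degenerate inputs:
dispersion clipped to [1e-8, 10]; genes with zero base mean are filtered,
not tested; empty DEG sets make fractions undefined (explicit error rather
than NaN); an all-DE-opposite universe is shuffle-invariant and yields
p = 1 under the one-sided ≥ convention; BH of an empty vector is empty. The
published linear fold-change columns were evidently computed from unrounded
log2 values — 9 of 46 printed entries differ by exactly 0.01 from
2^(printed log2) — so checks against them are at printed precision (±0.01).

## Limitations

Single-factor two-group contrasts only; no fold-change or dispersion
shrinkage, no outlier handling; no GO-graph propagation or annotation-bias
correction in enrichment; no phasing or mapping-bias correction in ASE; the
genome-scale published counts (1951/2049 DEGs, 486 shared, null mean 0.069,
p = 0.0011) depend on the deposited dataset (GEO GSE190053) and are out of
desk-scale reach by design.
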