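# mirror21

Dosage-mirroring expression analysis for chromosome 21.

A ring chromosome 21 with terminal 21q22.3 deletions leaves its carrier
hemizygous for the deleted genes — a genetic contrary of trisomy 21, which
carries those genes in three copies. `mirror21` implements the analysis that
compares the two states in one transcriptome experiment: neural stem cells
from a ring-chromosome-21 donor (partial monosomy, line `RD_P26`) and from
two trisomy-21 donors (`DS1`, `DS2`, merged into one condition `DSm`), each
against euploid controls. Genes that are differentially expressed in **both**
contrasts with **opposite** directions are *mirrored* — direct evidence that
the dosage of the deleted segment drives their expression genome-wide.

The package is aimed at researchers analysing copy-number dosage effects in
bulk RNA-seq count data. It provides:

- **`regions`** — 1-based closed interval model of the two deletions
  (`21:41,994,799-43,447,106` and `21:44,361,567-46,944,323`, hg38), BED
  import, and DELETION/VICINITY/OUTSIDE gene classification (1 Mb vicinity).
- **`diffexpr`** — a transparent two-group negative-binomial Wald test:
  median-of-ratios size factors, method-of-moments dispersion, BH adjustment,
  and the study's DEG rules (linear fold change ≤ 0.75 or ≥ 1.25, adjusted
  p < 0.05, base mean ≥ 5).
- **`mirror`** — trisomy-line merging, shared/mirrored DEG sets, mirrored
  fractions (with and without the deleted genes), and a permutation null:
  shuffle the monosomy table's per-gene statistics over gene labels, re-apply
  the full filter chain, recompute; empirical `p = (1 + #{null ≥ obs})/(n+1)`.
- **`ase`** — allele-specific expression filters (drop indels and sites with
  summed allelic depth < 50) and per-region allelic-fraction summaries
  (balanced biallelic sites sit near 0.5).
- **`enrichment`** — generic over-representation on GMT gene sets (fold
  enrichment, exact hypergeometric p, FDR ≤ 0.001 filter).
- **`simulate`** — a synthetic-data generator reproducing the study layout
  (3 euploid + 1 monosomy + 2 trisomy lines, technical triplicates) with NB
  counts, cis dosage effects (0.5× hemizygous, 1.5× trisomic), configurable
  trans and mirrored effects, and heterozygous-SNV allele-depth tables.
- **`mirror21` CLI** — `simulate`, `de`, `mirror`, `ase`, `enrich`, `run`.

## Model sketch

Counts for gene *g* in sample *j* are modelled as
K<sub>gj</sub> ~ NB(μ<sub>gj</sub>, α<sub>g</sub>) with
μ<sub>gj</sub> = s<sub>j</sub> q<sub>g,cond(j)</sub>, Var = μ + α μ².
The Wald statistic for a contrast is log2(q̂<sub>test</sub>/q̂<sub>ref</sub>)
over its delta-method standard error; p-values are BH-adjusted. The mirrored
fraction of a DE table pair (A = monosomy, B = trisomy) is
|{g : DE in A and B, sign<sub>A</sub> ≠ sign<sub>B</sub>}| / |DEGs in A|,
tested one-sided against the gene-label permutation null.

## Worked example

```bash
mirror21 simulate --seed 5 --outdir demo --n-variants 40
mirror21 de --counts demo/counts.tsv --samples demo/samples.tsv \
    --contrast monosomy:control --out demo/de_mono.tsv
mirror21 de --counts demo/counts.tsv --samples demo/samples.tsv \
    --contrast trisomy:control --out demo/de_tri.tsv
mirror21 mirror --de-a demo/de_mono.tsv --de-b demo/de_tri.tsv \
    --n-perm 100 --seed 2
```

prints (default generator: 2,000 genes, 30 hemizygous, 150 trans effects per
genotype of which 10% mirrored):

```
281 DEGs of 2000 genes -> demo/de_mono.tsv
309 DEGs of 2000 genes -> demo/de_tri.tsv
shared=66 mirrored=22 fraction=0.0783 p=0.495
```

281 and 309 genes pass the DEG rules in the monosomy and trisomy contrasts;
66 are shared and 22 of those flip direction, a mirrored fraction of
22/281 = 7.8%. The permutation p (100 shuffles) of 0.50 says this is not
distinguishable from chance overlap at this simulation size — with the
single monosomy line, many monosomy-contrast calls are noise-driven, which
is exactly why the statistic is judged against its permutation null rather
than the raw fraction.

The published per-gene statistics for the 23 mirrored chromosome-21 genes
ship with the package:

```python
from mirror21 import classify_degs, shared_and_mirrored
from mirror21.datasets import published_de_tables

de_mono, de_tri = published_de_tables()
result = shared_and_mirrored(classify_degs(de_mono), classify_degs(de_tri))
len(result.mirrored)   # 23
```

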