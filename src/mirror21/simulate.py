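"""Synthetic data with the statistical structure of a chr21 dosage study.

The generator emulates the study layout: three euploid control lines, one
line with a ring chromosome 21 carrying two hemizygous deletions (partial
monosomy), and two full-trisomy-21 lines, each sequenced in technical
triplicates.  Counts are negative binomial around a per-gene baseline, with

* cis dosage effects — deleted genes at ~0.5x in the monosomy line, all
  chromosome-21 genes at ~1.5x in the trisomy lines;
* trans dysregulation — configurable sets of non-chr21 genes perturbed in
  each aberrant genotype, including a "mirrored" subset forced to opposite
  directions in the two genotypes, while the remaining trans effects are
  drawn independently per genotype;
* between-line biological variability (log-normal factor per gene and line),
  a smaller technical term per replicate, and multiplicative library-size
  variation.

A companion generator produces heterozygous-SNV allele-depth records (alt
depth binomial at fraction 0.5 unless a site is listed monoallelic) for the
allele-specific-expression stage.  Everything is deterministic under a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ase import VariantRecord, write_vcf
from .diffexpr import CountMatrix
from .regions import GeneRecord, GenomicInterval, write_gene_annotation

#: the two hemizygous deletions of the studied ring chromosome 21 (hg38)
DEFAULT_DELETIONS = (
    GenomicInterval("21", 41_994_799, 43_447_106, "deletion_1"),
    GenomicInterval("21", 44_361_567, 46_944_323, "deletion_2"),
)

CHR21_LENGTH = 46_709_983  # GRCh38


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults follow the study layout.

    Fold changes are linear (0.5 = halved, 1.5 = one extra copy of two).
    ``n_trans_degs`` counts trans-perturbed genes per aberrant genotype;
    ``mirrored_fraction_true`` of them are shared between genotypes with
    opposite directions, the rest are drawn independently per genotype.
    """

    n_genes: int = 2000
    chr21_fraction: float = 0.07
    n_deleted_genes: int = 30
    deleted_gene_ids: frozenset | None = None
    n_control_lines: int = 3
    n_monosomy_lines: int = 1
    n_trisomy_lines: int = 2
    replicates_per_line: int = 3
    mean_log: float = 4.0          # log-normal baseline: mean of ln(expression)
    sd_log: float = 1.5            # log-normal baseline: sd of ln(expression)
    dispersion: float = 0.05       # NB dispersion alpha (Var = mu + alpha mu^2)
    sigma_line: float = 0.2        # between-line ln-scale SD, per gene x line
    sigma_technical: float = 0.05  # extra ln-scale SD per gene x replicate
    library_size_range: tuple[float, float] = (0.7, 1.3)
    cis_monosomy_fc: float = 0.5
    cis_trisomy_fc: float = 1.5
    n_trans_degs: int = 150
    mirrored_fraction_true: float = 0.1
    trans_log2fc_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cis_monosomy_fc <= 0 or self.cis_trisomy_fc <= 0:
            raise ValueError("fold changes must be positive")
        if not 0 <= self.mirrored_fraction_true <= 1:
            raise ValueError("mirrored_fraction_true must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        n_deleted = (
            len(self.deleted_gene_ids)
            if self.deleted_gene_ids is not None
            else self.n_deleted_genes
        )
        if self.n_genes < n_deleted:
            raise ValueError("n_genes smaller than the deleted gene set")


TRUTH_LABELS = (
    "cis_deleted",
    "cis_trisomic",
    "trans_mirrored",
    "trans_concordant",
    "trans_mono_only",
    "trans_tri_only",
    "null",
)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean mu, dispersion alpha); Poisson in the alpha -> 0 limit."""
    if alpha < 1e-12:
        return rng.poisson(mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _place_genes(
    config: SimConfig,
    rng: np.random.Generator,
    deletions: Sequence[GenomicInterval],
) -> tuple[list[GeneRecord], np.ndarray, np.ndarray]:
    """Lay out gene coordinates; deleted genes fall inside the deletions."""
    n = config.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(n)])
    n_chr21 = int(round(config.chr21_fraction * n))
    if config.deleted_gene_ids is not None:
        deleted_ids = set(config.deleted_gene_ids)
        unknown = deleted_ids - set(gene_ids)
        if unknown:
            raise ValueError(f"deleted_gene_ids not in gene universe: {sorted(unknown)}")
    else:
        deleted_ids = set(gene_ids[:config.n_deleted_genes]) if config.n_deleted_genes else set()
    n_chr21 = max(n_chr21, len(deleted_ids))

    is_chr21 = np.zeros(n, bool)
    deleted_mask = np.fromiter((g in deleted_ids for g in gene_ids), bool, n)
    is_chr21 |= deleted_mask
    extra = n_chr21 - int(deleted_mask.sum())
    candidates = np.flatnonzero(~deleted_mask)
    if extra > 0:
        is_chr21[rng.choice(candidates, size=extra, replace=False)] = True

    records: list[GeneRecord] = []
    del_cycle = 0
    for i, gid in enumerate(gene_ids):
        length = int(rng.integers(2_000, 100_000))
        if deleted_mask[i]:
            iv = deletions[del_cycle % len(deletions)] if deletions else None
            del_cycle += 1
            if iv is None:
                raise ValueError("deleted genes configured but no deletion intervals")
            start = int(rng.integers(iv.start, max(iv.start + 1, iv.end - length)))
            chrom = iv.chromosome
        elif is_chr21[i]:
            start = int(rng.integers(5_000_000, CHR21_LENGTH - length))
            chrom = "21"
        else:
            chrom = str(rng.integers(1, 21))  # autosomes 1..20
            start = int(rng.integers(1_000_000, 200_000_000))
        records.append(
            GeneRecord(
                gene_id=str(gid),
                gene_name=str(gid),
                chromosome=chrom,
                start=start,
                end=start + length,
                strand="+" if rng.random() < 0.5 else "-",
                biotype="protein_coding",
            )
        )
    return records, is_chr21, deleted_mask


def _trans_effects(
    config: SimConfig, rng: np.random.Generator, eligible: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene trans log2 fold changes for the two aberrant genotypes."""
    lfc_mono = np.zeros(n)
    lfc_tri = np.zeros(n)
    pool = np.flatnonzero(eligible)
    n_trans = min(config.n_trans_degs, len(pool))
    n_mirror = int(round(config.mirrored_fraction_true * n_trans))

    lo, hi = config.trans_log2fc_range
    mirrored_idx = rng.choice(pool, size=n_mirror, replace=False) if n_mirror else np.array([], int)
    mags = rng.uniform(lo, hi, size=(n_mirror, 2))
    signs = rng.choice([-1.0, 1.0], size=n_mirror)
    lfc_mono[mirrored_idx] = signs * mags[:, 0]
    lfc_tri[mirrored_idx] = -signs * mags[:, 1]

    remaining = np.setdiff1d(pool, mirrored_idx)
    n_indep = n_trans - n_mirror
    for target in (lfc_mono, lfc_tri):
        if n_indep and len(remaining):
            idx = rng.choice(remaining, size=min(n_indep, len(remaining)), replace=False)
            target[idx] = rng.choice([-1.0, 1.0], len(idx)) * rng.uniform(lo, hi, len(idx))
    return lfc_mono, lfc_tri, mirrored_idx


def _truth_labels(
    lfc_mono: np.ndarray,
    lfc_tri: np.ndarray,
    deleted_mask: np.ndarray,
    is_chr21: np.ndarray,
) -> np.ndarray:
    """Realized label per gene (cis beats trans; trans labelled by sign pattern)."""
    labels = np.full(len(lfc_mono), "null", dtype=object)
    in_mono = lfc_mono != 0
    in_tri = lfc_tri != 0
    labels[in_mono & ~in_tri] = "trans_mono_only"
    labels[~in_mono & in_tri] = "trans_tri_only"
    both = in_mono & in_tri
    labels[both & (np.sign(lfc_mono) == np.sign(lfc_tri))] = "trans_concordant"
    labels[both & (np.sign(lfc_mono) != np.sign(lfc_tri))] = "trans_mirrored"
    labels[is_chr21] = "cis_trisomic"
    labels[deleted_mask] = "cis_deleted"
    return labels


def simulate_experiment(
    config: SimConfig,
    deletions: Sequence[GenomicInterval] = DEFAULT_DELETIONS,
) -> tuple[CountMatrix, pd.DataFrame, list[GeneRecord]]:
    """Draw one synthetic experiment.

    Returns the count matrix (with sample sheet), a per-gene truth table
    (true linear fold changes in the monosomy and trisomy conditions and a
    realized label), and the gene annotation.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    annotation, is_chr21, deleted_mask = _place_genes(config, rng, deletions)

    baseline = rng.lognormal(config.mean_log, config.sd_log, n)

    lfc_mono, lfc_tri, _ = _trans_effects(
        config, rng, eligible=~is_chr21, n=n
    )
    fc_mono = np.exp2(lfc_mono)
    fc_tri = np.exp2(lfc_tri)
    # cis dosage overrides trans effects on chr21
    fc_mono[deleted_mask] = config.cis_monosomy_fc
    fc_mono[is_chr21 & ~deleted_mask] = 1.0
    fc_tri[is_chr21] = config.cis_trisomy_fc

    labels = _truth_labels(lfc_mono, lfc_tri, deleted_mask, is_chr21)

    lines = (
        [("CTRL%d" % (i + 1), "control") for i in range(config.n_control_lines)]
        + [("RD_P26" if config.n_monosomy_lines == 1 else f"MONO{i+1}", "monosomy")
           for i in range(config.n_monosomy_lines)]
        + [(f"DS{i+1}", "trisomy") for i in range(config.n_trisomy_lines)]
    )
    condition_fc = {"control": np.ones(n), "monosomy": fc_mono, "trisomy": fc_tri}

    columns = {}
    sheet_rows = []
    lo, hi = config.library_size_range
    for line, genotype in lines:
        line_factor = rng.lognormal(0.0, config.sigma_line, n)
        mu_line = baseline * condition_fc[genotype] * line_factor
        for rep in range(1, config.replicates_per_line + 1):
            sample_id = f"{line}_r{rep}"
            libsize = rng.uniform(lo, hi)
            tech = (
                rng.lognormal(0.0, config.sigma_technical, n)
                if config.sigma_technical > 0
                else 1.0
            )
            mu = mu_line * tech * libsize
            columns[sample_id] = _nb_draw(rng, mu, config.dispersion)
            sheet_rows.append(
                {"sample_id": sample_id, "line": line, "genotype": genotype,
                 "replicate": rep}
            )

    gene_index = pd.Index([g.gene_id for g in annotation], name="gene_id")
    counts = pd.DataFrame(columns, index=gene_index)
    samples = pd.DataFrame(sheet_rows).set_index("sample_id")
    truth = pd.DataFrame(
        {
            "label": labels,
            "fc_monosomy": fc_mono,
            "fc_trisomy": fc_tri,
            "baseline_mean": baseline,
            "chromosome": [g.chromosome for g in annotation],
        },
        index=gene_index,
    )
    return CountMatrix(counts, samples), truth, annotation


def simulate_het_variants(
    n_variants: int,
    depth_mean: float = 100.0,
    indel_fraction: float = 0.0,
    monoallelic_ids: frozenset | set | None = None,
    seed: int = 0,
    intervals: Sequence[GenomicInterval] | None = None,
) -> list[VariantRecord]:
    """Heterozygous-variant records with binomial(0.5) allele depths.

    Sites named in ``monoallelic_ids`` (ids are assigned in placement order
    as ``var00000``, ``var00001``, ...) express a single allele.  When
    ``intervals`` is given, positions are drawn uniformly inside them
    (cycled); otherwise along chromosome 21.
    """
    if n_variants < 0:
        raise ValueError("n_variants must be >= 0")
    rng = np.random.default_rng(seed)
    monoallelic_ids = monoallelic_ids or set()
    bases = np.array(list("ACGT"))
    records = []
    for i in range(n_variants):
        if intervals:
            iv = intervals[i % len(intervals)]
            chrom, pos = iv.chromosome, int(rng.integers(iv.start, iv.end + 1))
        else:
            chrom, pos = "21", int(rng.integers(5_000_000, CHR21_LENGTH))
        depth = max(1, int(rng.poisson(depth_mean)))
        var_id = f"var{i:05d}"
        is_indel = rng.random() < indel_fraction
        ref_i = int(rng.integers(4))
        ref = bases[ref_i]
        alt = bases[(ref_i + 1 + int(rng.integers(3))) % 4]
        if is_indel:
            ref = ref + "".join(rng.choice(bases, int(rng.integers(1, 4))))
        if var_id in monoallelic_ids:
            alt_depth = depth if rng.random() < 0.5 else 0
        else:
            alt_depth = int(rng.binomial(depth, 0.5))
        records.append(
            VariantRecord(
                chromosome=chrom,
                position=pos,
                ref_allele=str(ref),
                alt_allele=str(alt),
                ref_depth=depth - alt_depth,
                alt_depth=alt_depth,
                variant_id=var_id,
            )
        )
    return records


def write_experiment(
    outdir: str | Path,
    counts: CountMatrix,
    truth: pd.DataFrame,
    annotation: Sequence[GeneRecord],
    variants: Sequence[VariantRecord] | None = None,
    deletions: Sequence[GenomicInterval] = DEFAULT_DELETIONS,
) -> dict[str, Path]:
    """Write all simulator outputs as plain-text files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.tsv",
        "deletions": outdir / "deletions.bed",
    }
    counts.write(paths["counts"], paths["samples"])
    write_gene_annotation(annotation, paths["annotation"])
    truth.rename_axis("gene_id").to_csv(paths["truth"], sep="\t")
    with paths["deletions"].open("w") as bed:
        for iv in deletions:
            bed.write(f"chr{iv.chromosome}\t{iv.start - 1}\t{iv.end}\t{iv.label}\n")
    if variants is not None:
        paths["variants"] = outdir / "variants.vcf"
        write_vcf(variants, paths["variants"])
    return paths


def null_calibration_config(seed: int, n_genes: int = 2000) -> SimConfig:
    """Conditions for permutation-calibration runs.

    Calibration requires data generated under the exchangeability assumption
    of the shuffle null: trans dysregulation drawn independently per
    genotype with no mirrored subset, no cis structure (no chr21 genes, no
    deletions — cis effects couple the two contrasts through position), and
    no between-line or technical heterogeneity (both contrasts share the
    euploid control group, so shared extra-NB noise correlates their false
    calls and makes the test conservative rather than uniform).  The trans
    DEG count matches the study's genome-wide DEG rate (~13.7% of genes).
    Three lines per genotype in triplicate.
    """
    return SimConfig(
        n_genes=n_genes,
        chr21_fraction=0.0,
        n_deleted_genes=0,
        n_monosomy_lines=3,
        n_trisomy_lines=3,
        n_trans_degs=int(round(0.137 * n_genes)),
        mirrored_fraction_true=0.0,
        sigma_line=0.0,
        sigma_technical=0.0,
        seed=seed,
    )
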