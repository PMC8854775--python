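"""Negative-binomial Wald differential expression with dosage-study DEG rules.

This is a deliberately transparent two-group DE core: median-of-ratios size
factors, a per-gene negative-binomial model with a method-of-moments
dispersion estimate, a delta-method Wald test on the log2 fold change, and
Benjamini-Hochberg adjustment.  It implements the decision rules used in the
ring-chromosome-21 dosage study — a gene is differentially expressed when its
linear fold change deviates by at least 25% from the euploid reference, the
adjusted p-value is below 0.05, and the base mean (mean of normalized counts)
is at least 5 — without fold-change or dispersion shrinkage and without
outlier refitting.  Numerical equality with DESeq2 is not a goal; the
thresholds and decision rules are the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

GENOTYPES = ("control", "monosomy", "trisomy")

#: deg_status vocabulary
UP = "UP"
DOWN = "DOWN"
NOT_DE = "NOT_DE"
FILTERED_LOW_EXPRESSION = "FILTERED_LOW_EXPRESSION"

# dispersion is clipped into this range so the Wald statistic stays finite
# on degenerate genes (all-equal counts, single outliers)
DISPERSION_FLOOR = 1e-8
DISPERSION_CEILING = 10.0


class NormalizationError(ValueError):
    """No gene usable for median-of-ratios normalization."""


class DesignError(ValueError):
    """Contrast groups too small or missing."""


@dataclass
class CountMatrix:
    """Gene x sample integer counts plus the sample sheet.

    ``counts``: DataFrame indexed by gene_id, columns are sample_ids.
    ``samples``: DataFrame indexed by sample_id with columns
    ``line``, ``genotype`` (control/monosomy/trisomy) and ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("count matrix contains negative entries")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"sample sheet misses columns: {sorted(missing)}")
        bad = set(self.samples["genotype"]) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotypes in sample sheet: {sorted(bad)}")
        # align sheet to column order
        self.samples = self.samples.loc[list(self.counts.columns)]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_genotypes(self, genotypes: Sequence[str]) -> "CountMatrix":
        keep = self.samples.index[self.samples["genotype"].isin(genotypes)]
        return CountMatrix(self.counts[keep].copy(), self.samples.loc[keep].copy())

    def collapse_replicates(self) -> "CountMatrix":
        """Sum technical replicates within each line into one column."""
        lines = self.samples["line"]
        summed = self.counts.T.groupby(lines).sum().T
        sheet = (
            self.samples.groupby("line")
            .agg(genotype=("genotype", "first"))
            .assign(line=lambda d: d.index, replicate=1)
        )
        sheet.index.name = "sample_id"
        return CountMatrix(summed, sheet[["line", "genotype", "replicate"]])

    def write(self, counts_path: str | Path, samples_path: str | Path) -> None:
        self.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
        self.samples.rename_axis("sample_id").to_csv(samples_path, sep="\t")

    @classmethod
    def read(cls, counts_path: str | Path, samples_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0, dtype=str)
        return cls(counts, samples)


@dataclass(frozen=True)
class DEGThresholds:
    """The study's DEG decision rules.

    ``fc_fraction``: minimal linear fold-change deviation (0.25 means the
    linear fold change must be <= 0.75 or >= 1.25, boundary included).
    ``alpha``: adjusted-p cutoff, compared strictly.
    ``min_base_mean``: genes with base mean below this are filtered out.
    """

    fc_fraction: float = 0.25
    alpha: float = 0.05
    min_base_mean: float = 5.0

    def __post_init__(self) -> None:
        if self.fc_fraction < 0:
            raise ValueError("fc_fraction must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    For each sample, the factor is the median over reference genes (genes
    with a positive count in every sample) of the ratio count / geometric
    mean across samples.
    """
    frame = counts.counts if isinstance(counts, CountMatrix) else counts
    values = frame.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_counts = np.log(values)
    log_geomeans = log_counts.mean(axis=1)
    usable = np.isfinite(log_geomeans)
    if not usable.any():
        raise NormalizationError(
            "no gene has positive counts in every sample; "
            "cannot compute median-of-ratios size factors"
        )
    log_ratios = log_counts[usable] - log_geomeans[usable, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    if not np.all(np.isfinite(factors)) or (factors <= 0).any():
        raise NormalizationError("non-positive size factor encountered")
    return pd.Series(factors, index=frame.columns, name="size_factor")


def _mom_dispersion(
    normalized: np.ndarray, group_masks: list[np.ndarray], inv_sf: np.ndarray
) -> np.ndarray:
    """Pooled within-group method-of-moments dispersion per gene.

    For NB counts K with mean mu = s*q and dispersion alpha, the normalized
    counts y = K/s satisfy Var(y) ~= q * (1/s) + alpha * q^2, so
    alpha ~= (var(y) - q * mean(1/s)) / q^2 within a group.  Group estimates
    are pooled with df weights and clipped to keep Wald statistics finite.
    """
    n_genes = normalized.shape[0]
    num = np.zeros(n_genes)
    den = np.zeros(n_genes)
    for mask in group_masks:
        y = normalized[:, mask]
        n = mask.sum()
        if n < 2:
            continue
        q = y.mean(axis=1)
        v = y.var(axis=1, ddof=1)
        mean_inv_sf = inv_sf[mask].mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_g = (v - q * mean_inv_sf) / (q * q)
        alpha_g = np.where(q > 0, alpha_g, 0.0)
        num += (n - 1) * np.nan_to_num(alpha_g)
        den += n - 1
    alpha = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    return np.clip(alpha, DISPERSION_FLOOR, DISPERSION_CEILING)


def nb_wald(
    counts: CountMatrix,
    contrast: tuple[str, str],
    thresholds: DEGThresholds | None = None,
    collapse_replicates: bool = False,
) -> pd.DataFrame:
    """Two-group negative-binomial Wald test.

    ``contrast`` is ``(test_genotype, reference_genotype)``; the log2 fold
    change is test over reference.  Returns a DataFrame indexed by gene_id
    with columns base_mean, log2_fc, linear_fc, se, wald_p, adj_p and
    deg_status (set by :func:`classify_degs` when ``thresholds`` is given,
    else against the default thresholds).
    """
    test_geno, ref_geno = contrast
    for geno in contrast:
        if geno not in GENOTYPES:
            raise DesignError(f"unknown genotype {geno!r}")
    sub = counts.subset_genotypes([test_geno, ref_geno])
    if collapse_replicates:
        sub = sub.collapse_replicates()
    genotype = sub.samples["genotype"].to_numpy()
    test_mask = genotype == test_geno
    ref_mask = genotype == ref_geno
    if test_mask.sum() < 2 or ref_mask.sum() < 2:
        raise DesignError(
            f"need >=2 samples per group, got {test_mask.sum()} {test_geno} "
            f"vs {ref_mask.sum()} {ref_geno}"
        )

    sf = size_factors(sub).to_numpy()
    inv_sf = 1.0 / sf
    normalized = sub.counts.to_numpy(dtype=float) * inv_sf[None, :]
    base_mean = normalized.mean(axis=1)

    q_test = normalized[:, test_mask].mean(axis=1)
    q_ref = normalized[:, ref_mask].mean(axis=1)
    n_test, n_ref = int(test_mask.sum()), int(ref_mask.sum())

    alpha = _mom_dispersion(normalized, [test_mask, ref_mask], inv_sf)

    # half-count pseudo value on the normalized scale keeps logs finite for
    # genes silent in one group; negligible for well-expressed genes
    pseudo = 0.5 * inv_sf.mean()
    qt = q_test + pseudo
    qr = q_ref + pseudo
    log2_fc = np.log2(qt / qr)

    # delta method: Var(ln q_hat) = (1/q) * sum(1/s)/n^2 + alpha/n
    var_log_test = inv_sf[test_mask].sum() / (n_test**2 * qt) + alpha / n_test
    var_log_ref = inv_sf[ref_mask].sum() / (n_ref**2 * qr) + alpha / n_ref
    se = np.sqrt(var_log_test + var_log_ref) / np.log(2)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2_fc / se
    wald_p = 2.0 * stats.norm.sf(np.abs(z))

    tested = base_mean > 0
    wald_p = np.where(tested, wald_p, np.nan)
    log2_fc = np.where(tested, log2_fc, np.nan)
    adj_p = np.full_like(wald_p, np.nan)
    if tested.any():
        adj_p[tested] = bh_adjust(wald_p[tested])

    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_fc": log2_fc,
            "linear_fc": np.exp2(log2_fc),
            "se": se,
            "wald_p": wald_p,
            "adj_p": adj_p,
        },
        index=sub.counts.index.rename("gene_id"),
    )
    return classify_degs(table, thresholds or DEGThresholds())


def bh_adjust(p: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def classify_degs(
    de: pd.DataFrame, thresholds: DEGThresholds | None = None
) -> pd.DataFrame:
    """Apply the DEG decision rules; returns a copy with deg_status set.

    UP: linear fold change >= 1 + fc_fraction, adj_p < alpha, base mean kept.
    DOWN: linear fold change <= 1 - fc_fraction (boundary included), same
    significance and expression conditions.  Genes below the base-mean filter
    are FILTERED_LOW_EXPRESSION regardless of their statistics.
    """
    thresholds = thresholds or DEGThresholds()
    out = de.copy()
    linear = np.exp2(out["log2_fc"].to_numpy(dtype=float))
    adj_p = out["adj_p"].to_numpy(dtype=float)
    base_mean = out["base_mean"].to_numpy(dtype=float)

    low = base_mean < thresholds.min_base_mean
    with np.errstate(invalid="ignore"):
        significant = adj_p < thresholds.alpha
    significant &= ~np.isnan(adj_p)
    up = significant & (linear >= 1 + thresholds.fc_fraction)
    down = significant & (linear <= 1 - thresholds.fc_fraction)

    status = np.full(len(out), NOT_DE, dtype=object)
    status[up] = UP
    status[down] = DOWN
    status[low] = FILTERED_LOW_EXPRESSION
    out["deg_status"] = status
    if "linear_fc" not in out.columns:
        out["linear_fc"] = linear
    return out


def log2_to_linear(log2_fc: float, decimals: int | None = None) -> float:
    """Convert a log2 fold change to the linear scale.

    ``decimals=2`` reproduces the two-decimal linear column of the published
    per-gene table.
    """
    if not np.isfinite(log2_fc):
        raise ValueError("log2 fold change must be finite")
    value = float(2.0**log2_fc)
    return round(value, decimals) if decimals is not None else value


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.rename_axis("gene_id").to_csv(path, sep="\t")


def read_de_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
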