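"""Mirrored-gene analysis: shared DEGs with opposite dosage responses.

A deletion and a trisomy of the same chromosomal region are genetic
contraries; genes whose expression moves down under the partial monosomy and
up under trisomy (or vice versa) are "mirrored".  This module intersects two
differential-expression tables (monosomy-vs-euploid and merged-trisomy-vs-
euploid), classifies shared DEGs as mirrored or concordant, computes mirrored
fractions with and without the genes physically lost on the ring chromosome,
and attaches an empirical permutation null.

Permutation scheme: the per-gene statistics (log2 fold change, adjusted p,
base mean) of table A are shuffled over the common gene universe, the DEG
decision rules are re-applied with the identical thresholds, and the mirrored
fraction is recomputed against the fixed table B.  This preserves table A's
marginal DEG count and direction proportions while breaking any gene-level
association with table B.  A sign-flip scheme (randomise only the direction
of A's DEGs) is available as an alternative null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import DEGThresholds, DOWN, UP, classify_degs
from .regions import GeneRecord, GenomicInterval, RegionClass, classify_gene

_DE_STATUSES = (UP, DOWN)


class AlignmentError(ValueError):
    """The two DE tables do not share one gene universe."""


@dataclass
class MirrorResult:
    """Outcome of intersecting two DEG sets."""

    genes: pd.Index
    degs_a: frozenset
    degs_b: frozenset
    shared_degs: frozenset
    mirrored: frozenset
    concordant: frozenset
    deleted_genes: frozenset = frozenset()

    @property
    def fraction_all(self) -> float:
        """|mirrored| / |DEGs in contrast A|."""
        if not self.degs_a:
            raise ZeroDivisionError("contrast A has no DEGs; fraction undefined")
        return len(self.mirrored) / len(self.degs_a)

    @property
    def fraction_excluding_deleted(self) -> float:
        """Mirrored fraction after dropping genes inside the deletions.

        The denominator stays |DEGs in A|, matching the published
        "154 of 1951" arithmetic.
        """
        if not self.degs_a:
            raise ZeroDivisionError("contrast A has no DEGs; fraction undefined")
        return len(self.mirrored - self.deleted_genes) / len(self.degs_a)

    def status_table(self) -> pd.DataFrame:
        """Per-gene status: mirrored / shared_concordant / A_only / B_only / none."""
        status = []
        for g in self.genes:
            if g in self.mirrored:
                status.append("mirrored")
            elif g in self.concordant:
                status.append("shared_concordant")
            elif g in self.degs_a:
                status.append("A_only")
            elif g in self.degs_b:
                status.append("B_only")
            else:
                status.append("none")
        return pd.DataFrame({"status": status}, index=self.genes.rename("gene_id"))


@dataclass
class PermutationSummary:
    n_permutations: int
    null_fractions: np.ndarray
    observed: float
    empirical_p: float
    seed: int
    scheme: str = "shuffle_genes"

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_fractions))

    @property
    def null_std_error(self) -> float:
        return float(
            np.std(self.null_fractions, ddof=1) / np.sqrt(len(self.null_fractions))
        )

    def to_dict(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "observed_fraction": self.observed,
            "null_mean": self.null_mean,
            "null_std_error": self.null_std_error,
            "empirical_p": self.empirical_p,
            "seed": self.seed,
            "scheme": self.scheme,
        }


def merge_trisomy(counts, lines: Sequence[str], merged_line: str = "DSm"):
    """Relabel the given trisomy lines as one merged condition.

    Column data are untouched; only the ``line`` label in the sample sheet is
    rewritten so that downstream DE treats all replicates of the listed lines
    as one group.
    """
    from .diffexpr import CountMatrix

    lines = list(lines)
    if not lines:
        raise ValueError("merge_trisomy requires at least one line")
    known = set(counts.samples["line"])
    unknown = set(lines) - known
    if unknown:
        raise KeyError(f"unknown line id(s): {sorted(unknown)}")
    mask = counts.samples["line"].isin(lines)
    genos = set(counts.samples.loc[mask, "genotype"])
    if genos != {"trisomy"}:
        raise ValueError(
            f"lines {lines} must all carry genotype 'trisomy', found {sorted(genos)}"
        )
    sheet = counts.samples.copy()
    sheet.loc[mask, "line"] = merged_line
    return CountMatrix(counts.counts.copy(), sheet)


def _deg_sets(de: pd.DataFrame) -> tuple[frozenset, pd.Series]:
    status = de["deg_status"]
    degs = frozenset(de.index[status.isin(_DE_STATUSES)])
    return degs, status


def shared_and_mirrored(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    deleted_genes: Sequence[str] | None = None,
) -> MirrorResult:
    """Intersect two classified DE tables over one gene universe.

    Raises :class:`AlignmentError` when the universes differ — a silent inner
    join would invalidate the mirrored-fraction denominators.
    """
    if set(de_a.index) != set(de_b.index):
        raise AlignmentError(
            "DE tables cover different gene universes "
            f"({len(de_a)} vs {len(de_b)} genes, "
            f"{len(set(de_a.index) ^ set(de_b.index))} not shared)"
        )
    de_b = de_b.loc[de_a.index]
    degs_a, status_a = _deg_sets(de_a)
    degs_b, status_b = _deg_sets(de_b)
    shared = degs_a & degs_b
    mirrored = frozenset(g for g in shared if status_a[g] != status_b[g])
    return MirrorResult(
        genes=de_a.index,
        degs_a=degs_a,
        degs_b=degs_b,
        shared_degs=shared,
        mirrored=mirrored,
        concordant=shared - mirrored,
        deleted_genes=frozenset(deleted_genes or ()),
    )


def mirrored_fraction(
    result: MirrorResult,
    denominator: str = "all_degs_a",
    exclude_deleted: bool = False,
) -> float:
    """Mirrored fraction with a selectable denominator.

    ``all_degs_a``: all DEGs of contrast A (the published convention);
    ``shared``: only the shared DEG set.
    """
    numer = result.mirrored - result.deleted_genes if exclude_deleted else result.mirrored
    if denominator == "all_degs_a":
        denom = len(result.degs_a)
    elif denominator == "shared":
        denom = len(result.shared_degs)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ZeroDivisionError("mirrored fraction undefined: empty denominator")
    return len(numer) / denom


def deletion_gene_ids(
    annotation: Sequence[GeneRecord],
    deletions: Sequence[GenomicInterval],
    mode: str = "start_point",
) -> frozenset:
    """Gene ids classified into either deletion interval."""
    return frozenset(
        g.gene_id
        for g in annotation
        if classify_gene(g, deletions, mode=mode).in_deletion()
    )


def venn_counts(
    result: MirrorResult, annotation: Sequence[GeneRecord], deletions
) -> pd.DataFrame:
    """Shared/mirrored DEG counts stratified genome-wide / chr21 / deletions."""
    chr21 = {g.gene_id for g in annotation if g.chromosome == "21"}
    deleted = deletion_gene_ids(annotation, deletions)
    strata = {
        "genome_wide": set(result.genes),
        "chr21": chr21,
        "deletions": deleted,
    }
    rows = []
    for name, members in strata.items():
        rows.append(
            {
                "stratum": name,
                "degs_a": len(result.degs_a & members),
                "degs_b": len(result.degs_b & members),
                "shared": len(result.shared_degs & members),
                "mirrored": len(result.mirrored & members),
            }
        )
    return pd.DataFrame(rows).set_index("stratum")


_SHUFFLED_COLUMNS = ("log2_fc", "adj_p", "base_mean")


def permutation_test(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    n: int = 1000,
    seed: int = 0,
    thresholds: DEGThresholds | None = None,
    exclude_deleted: bool = False,
    deleted_genes: Sequence[str] | None = None,
    scheme: str = "shuffle_genes",
) -> PermutationSummary:
    """Permutation null for the mirrored fraction.

    Each permutation reassigns table A's per-gene (log2_fc, adj_p, base_mean)
    triples to random gene labels, re-applies the DEG decision rules with the
    identical thresholds, and recomputes the mirrored fraction against the
    fixed table B.  The one-sided empirical p is
    ``(1 + #{null >= observed}) / (n + 1)`` — never exactly zero.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if scheme not in ("shuffle_genes", "sign_flip"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    thresholds = thresholds or DEGThresholds()
    deleted = frozenset(deleted_genes or ())

    # work on a canonical (sorted) gene order so the null stream depends only
    # on the seed and the per-gene values, not on input row order
    order = de_a.index.sort_values()
    a = classify_degs(de_a.loc[order, list(_SHUFFLED_COLUMNS)].copy(), thresholds)
    b_status = de_b.loc[order, "deg_status"]

    # direction codes: +1 UP, -1 DOWN, 0 otherwise; a mirrored pair multiplies
    # to -1
    def codes(status: pd.Series) -> np.ndarray:
        return np.where(status == UP, 1, np.where(status == DOWN, -1, 0))

    b_codes = codes(b_status)
    excluded_mask = (
        np.fromiter((g in deleted for g in order), bool, len(order))
        if exclude_deleted
        else np.zeros(len(order), bool)
    )

    log2_fc = a["log2_fc"].to_numpy(float)
    adj_p = a["adj_p"].to_numpy(float)
    base_mean = a["base_mean"].to_numpy(float)
    n_degs_a = int((a["deg_status"].isin(_DE_STATUSES)).sum())
    if n_degs_a == 0:
        raise ZeroDivisionError("contrast A has no DEGs; null fraction undefined")

    # observed fraction from the identically re-classified statistics, so the
    # thresholds argument governs observed and null alike
    a_codes_obs = codes(a["deg_status"])
    observed = float(
        ((a_codes_obs * b_codes == -1) & ~excluded_mask).sum() / n_degs_a
    )

    rng = np.random.default_rng(seed)
    null_fractions = np.empty(n)
    for i in range(n):
        if scheme == "shuffle_genes":
            perm = rng.permutation(len(order))
            a_codes = _classify_codes(
                log2_fc[perm], adj_p[perm], base_mean[perm], thresholds
            )
        else:  # sign_flip: keep gene assignment, randomize DEG directions
            a_codes = _classify_codes(log2_fc, adj_p, base_mean, thresholds)
            flips = rng.integers(0, 2, len(order)) * 2 - 1
            a_codes = a_codes * flips
        mirrored_mask = (a_codes * b_codes == -1) & ~excluded_mask
        null_fractions[i] = mirrored_mask.sum() / n_degs_a

    empirical_p = (1 + int(np.sum(null_fractions >= observed))) / (n + 1)
    return PermutationSummary(
        n_permutations=n,
        null_fractions=null_fractions,
        observed=observed,
        empirical_p=empirical_p,
        seed=seed,
        scheme=scheme,
    )


def _classify_codes(
    log2_fc: np.ndarray,
    adj_p: np.ndarray,
    base_mean: np.ndarray,
    thresholds: DEGThresholds,
) -> np.ndarray:
    """Vectorised DEG direction codes under the standard decision rules."""
    linear = np.exp2(log2_fc)
    with np.errstate(invalid="ignore"):
        significant = (adj_p < thresholds.alpha) & ~np.isnan(adj_p)
    keep = base_mean >= thresholds.min_base_mean
    up = significant & keep & (linear >= 1 + thresholds.fc_fraction)
    down = significant & keep & (linear <= 1 - thresholds.fc_fraction)
    return np.where(up, 1, np.where(down, -1, 0))
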