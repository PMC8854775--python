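"""Allele-specific expression: variant filtering and allelic-fraction summary.

Heterozygous SNVs in expressed transcripts report the relative contribution
of the two homologues: a balanced site has an alternate-allele fraction near
0.5.  On a ring chromosome with hemizygous deletions, het calls are expected
only OUTSIDE the deleted intervals; a het call inside a deletion is an
anomaly worth reporting (retained heterozygosity, mosaicism or a calling
artefact), not a hard error.

Filtering follows the study rules: indels are excluded and so is any record
whose coverage (summed allelic depth) is below 50.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .regions import GenomicInterval, RegionClass, classify_position, normalize_chromosome


@dataclass(frozen=True)
class VariantRecord:
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    ref_depth: int
    alt_depth: int
    gene_id: Optional[str] = None
    variant_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError(
                f"negative allele depth at {self.chromosome}:{self.position}"
            )
        object.__setattr__(
            self, "chromosome", normalize_chromosome(self.chromosome)
        )

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)

    @property
    def total_depth(self) -> int:
        return self.ref_depth + self.alt_depth


@dataclass
class ASESummary:
    """Per-region-class allelic-fraction summary plus anomaly flags."""

    per_class: pd.DataFrame  # index RegionClass name; n, mean_fraction, sd_fraction
    n_total: int
    anomalies: list  # het calls inside a deletion

    def mean_fraction(self, region: RegionClass) -> float:
        return float(self.per_class.loc[region.name, "mean_fraction"])


def filter_variants(
    records: Sequence[VariantRecord], min_depth: int = 50
) -> list[VariantRecord]:
    """Keep biallelic SNVs with coverage (ref+alt depth) >= min_depth.

    Idempotent: filtering an already-filtered list changes nothing.
    """
    return [r for r in records if not r.is_indel and r.total_depth >= min_depth]


def allelic_fraction(record: VariantRecord, ref_based: bool = False) -> float:
    """Alternate-allele (or reference-allele) depth fraction at a site."""
    total = record.total_depth
    if total == 0:
        raise ZeroDivisionError(
            f"zero total depth at {record.chromosome}:{record.position}; "
            "allelic fraction undefined"
        )
    depth = record.ref_depth if ref_based else record.alt_depth
    return depth / total


def ase_summary(
    records: Sequence[VariantRecord],
    deletions: Sequence[GenomicInterval],
    vicinity_bp: int = 1_000_000,
    ref_based: bool = False,
) -> ASESummary:
    """Classify (already filtered) variants by region and summarise fractions.

    Het calls inside a deletion are collected as anomalies but still counted
    in their class.
    """
    rows: dict[str, list[float]] = {cls.name: [] for cls in RegionClass}
    anomalies = []
    for rec in records:
        cls = classify_position(rec.chromosome, rec.position, deletions, vicinity_bp)
        rows[cls.name].append(allelic_fraction(rec, ref_based=ref_based))
        if cls.in_deletion():
            anomalies.append(rec)
    table = pd.DataFrame(
        {
            "n": {k: len(v) for k, v in rows.items()},
            "mean_fraction": {
                k: (float(np.mean(v)) if v else float("nan")) for k, v in rows.items()
            },
            "sd_fraction": {
                k: (float(np.std(v, ddof=1)) if len(v) > 1 else float("nan"))
                for k, v in rows.items()
            },
        }
    )
    table.index.name = "region_class"
    return ASESummary(per_class=table, n_total=len(records), anomalies=anomalies)


# ---------------------------------------------------------------------------
# Minimal VCF I/O (VCFv4.2, AD preferred with DP fallback) via pysam


def read_vcf(path: str | Path, sample: str | int = 0) -> list[VariantRecord]:
    """Extract CHROM/POS/REF/ALT and per-sample AD (DP fallback) records.

    Only the first ALT allele is used.  With the DP fallback the ref/alt
    split is unknown; the record gets the full depth as ref and zero alt so
    the coverage filter still applies, and the allelic fraction is not
    meaningful for such records.
    """
    import pysam

    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if not rec.alts:
                continue
            if rec.samples:
                call = (
                    rec.samples[sample]
                    if isinstance(sample, str)
                    else rec.samples[list(rec.samples)[sample]]
                )
                ad = call.get("AD")
                if ad is not None and ad[0] is not None:
                    ref_depth, alt_depth = int(ad[0]), int(ad[1] if len(ad) > 1 else 0)
                else:
                    dp = call.get("DP")
                    if dp is None:
                        continue
                    ref_depth, alt_depth = int(dp), 0
            else:
                dp = rec.info.get("DP")
                if dp is None:
                    continue
                ref_depth, alt_depth = int(dp), 0
            records.append(
                VariantRecord(
                    chromosome=rec.chrom,
                    position=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=rec.alts[0],
                    ref_depth=ref_depth,
                    alt_depth=alt_depth,
                    variant_id=rec.id,
                )
            )
    return records


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    sample_name: str = "SAMPLE",
) -> None:
    """Write records as a minimal uncompressed VCFv4.2 with GT/AD/DP."""
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("source", "mirror21")
    for chrom in sorted({r.chromosome for r in records}, key=str):
        header.contigs.add(f"chr{chrom}", length=250_000_000)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Total depth")
    header.add_sample(sample_name)

    ordered = sorted(records, key=lambda r: (str(r.chromosome), r.position))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in ordered:
            rec = out.new_record(
                contig=f"chr{r.chromosome}",
                start=r.position - 1,
                stop=r.position - 1 + len(r.ref_allele),
                alleles=(r.ref_allele, r.alt_allele),
                id=r.variant_id,
            )
            call = rec.samples[sample_name]
            call["GT"] = (0, 1)
            call["AD"] = (r.ref_depth, r.alt_depth)
            call["DP"] = r.total_depth
            out.write(rec)


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    """TSV alternative: chromosome, position, ref, alt, ref_depth, alt_depth."""
    frame = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return [
        VariantRecord(
            chromosome=row.chromosome,
            position=int(row.position),
            ref_allele=str(row.ref),
            alt_allele=str(row.alt),
            ref_depth=int(row.ref_depth),
            alt_depth=int(row.alt_depth),
        )
        for row in frame.itertuples(index=False)
    ]
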