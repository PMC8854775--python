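"""Genomic coordinate model: deletion intervals, gene annotation, region classes.

The ring chromosome 21 studied here carries two terminal deletions on 21q22.3.
Every downstream stage (differential expression reporting, the mirrored-gene
statistic, allele-specific expression) needs to know whether a gene or variant
lies inside one of those deletions, in their 1 Mb vicinity, or elsewhere.

Coordinates are 1-based and fully closed throughout (both endpoints belong to
the interval), matching the ``21:41,994,799-43,447,106`` style used in clinical
cytogenetics.  BED input, which is 0-based half-open, is converted on load.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class RegionClass(enum.Enum):
    """Partition of the genome induced by two deletion intervals."""

    DELETION_1 = "deletion_1"
    DELETION_2 = "deletion_2"
    VICINITY = "vicinity"
    OUTSIDE = "outside"

    def in_deletion(self) -> bool:
        return self in (RegionClass.DELETION_1, RegionClass.DELETION_2)


def normalize_chromosome(name: str) -> str:
    """Equate ``chr21`` and ``21`` (case-insensitive on the prefix)."""
    name = str(name).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    return name


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, fully closed genomic interval."""

    chromosome: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"interval end {self.end} precedes start {self.start}"
            )
        object.__setattr__(
            self, "chromosome", normalize_chromosome(self.chromosome)
        )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains_point(self, chromosome: str, position: int) -> bool:
        return (
            normalize_chromosome(chromosome) == self.chromosome
            and self.start <= position <= self.end
        )

    def overlaps(self, chromosome: str, start: int, end: int) -> bool:
        """Closed-interval overlap: shares at least one basepair."""
        return (
            normalize_chromosome(chromosome) == self.chromosome
            and start <= self.end
            and end >= self.start
        )

    def distance_to_point(self, chromosome: str, position: int) -> float:
        """Basepairs from a point to the nearest interval boundary (0 if inside)."""
        if normalize_chromosome(chromosome) != self.chromosome:
            return float("inf")
        if position < self.start:
            return self.start - position
        if position > self.end:
            return position - self.end
        return 0.0

    def distance_to_interval(self, chromosome: str, start: int, end: int) -> float:
        if normalize_chromosome(chromosome) != self.chromosome:
            return float("inf")
        if end < self.start:
            return self.start - end
        if start > self.end:
            return start - self.end
        return 0.0


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene.

    ``start``/``end`` are 1-based closed genomic coordinates; ``strand`` is
    ``+``, ``-`` or ``unknown``; ``biotype`` follows Ensembl vocabulary
    (e.g. ``protein_coding``).
    """

    gene_id: str
    gene_name: str
    chromosome: str
    start: int
    end: int
    strand: str = "unknown"
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        object.__setattr__(
            self, "chromosome", normalize_chromosome(self.chromosome)
        )


class BedParseError(ValueError):
    """Raised for a malformed BED record; carries the offending line number."""


def load_deletions(path: str | Path) -> list[GenomicInterval]:
    """Read deletion intervals from a BED file.

    BED coordinates (0-based, half-open) are converted to the internal
    1-based closed convention.  Intervals are returned sorted by start;
    overlapping intervals are rejected, abutting ones are fine.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected at least 3 BED columns"
                )
            chrom = fields[0]
            try:
                bed_start, bed_end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if bed_end <= bed_start:
                raise BedParseError(
                    f"{path}:{lineno}: end must exceed start in BED"
                )
            label = fields[3] if len(fields) > 3 else f"interval_{lineno}"
            intervals.append(
                GenomicInterval(chrom, bed_start + 1, bed_end, label)
            )
    intervals.sort(key=lambda iv: (iv.chromosome, iv.start))
    for a, b in zip(intervals, intervals[1:]):
        if a.chromosome == b.chromosome and b.start <= a.end:
            raise ValueError(
                f"overlapping deletion intervals: {a.label} and {b.label}"
            )
    return intervals


_MODES = ("start_point", "any_overlap")


def classify_gene(
    gene: GeneRecord,
    deletions: Sequence[GenomicInterval],
    vicinity_bp: int = 1_000_000,
    mode: str = "start_point",
) -> RegionClass:
    """Assign a gene to DELETION_1/2, VICINITY or OUTSIDE.

    ``start_point`` mode places a gene by its start coordinate alone (the
    convention forced on analyses that only have start positions, as in the
    published per-gene table); ``any_overlap`` counts any shared basepair.
    Vicinity is measured from the nearest deletion boundary.  A gene on a
    different chromosome is OUTSIDE.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {_MODES}")
    if vicinity_bp < 0:
        raise ValueError("vicinity_bp must be >= 0")
    if len(deletions) > 2:
        raise ValueError(
            "RegionClass enumerates two deletions; got "
            f"{len(deletions)} intervals"
        )
    deletion_classes = (RegionClass.DELETION_1, RegionClass.DELETION_2)
    for cls, interval in zip(deletion_classes, deletions):
        if mode == "start_point":
            hit = interval.contains_point(gene.chromosome, gene.start)
        else:
            hit = interval.overlaps(gene.chromosome, gene.start, gene.end)
        if hit:
            return cls
    for interval in deletions:
        if mode == "start_point":
            dist = interval.distance_to_point(gene.chromosome, gene.start)
        else:
            dist = interval.distance_to_interval(
                gene.chromosome, gene.start, gene.end
            )
        if dist <= vicinity_bp:
            return RegionClass.VICINITY
    return RegionClass.OUTSIDE


def classify_position(
    chromosome: str,
    position: int,
    deletions: Sequence[GenomicInterval],
    vicinity_bp: int = 1_000_000,
) -> RegionClass:
    """Region class of a single genomic point (used for variant sites)."""
    probe = GeneRecord(
        gene_id="_point",
        gene_name="_point",
        chromosome=chromosome,
        start=position,
        end=position,
    )
    return classify_gene(probe, deletions, vicinity_bp, mode="start_point")


def count_by_region(
    genes: Iterable[GeneRecord],
    deletions: Sequence[GenomicInterval],
    vicinity_bp: int = 1_000_000,
    mode: str = "start_point",
) -> dict[RegionClass, int]:
    """Tally genes per region class; every class appears in the result."""
    counts = {cls: 0 for cls in RegionClass}
    for gene in genes:
        counts[classify_gene(gene, deletions, vicinity_bp, mode)] += 1
    return counts


# ---------------------------------------------------------------------------
# Annotation I/O

_ANNOTATION_COLUMNS = (
    "gene_id",
    "gene_name",
    "chromosome",
    "start",
    "end",
    "strand",
    "biotype",
)


def read_gene_annotation(path: str | Path) -> list[GeneRecord]:
    """Read a TSV gene annotation with the canonical seven-column header."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = set(_ANNOTATION_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"annotation {path} lacks columns: {sorted(missing)}")
    records = [
        GeneRecord(
            gene_id=row.gene_id,
            gene_name=row.gene_name,
            chromosome=row.chromosome,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            biotype=row.biotype,
        )
        for row in frame.itertuples(index=False)
    ]
    ids = [g.gene_id for g in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate gene_id entries in {path}")
    return records


def write_gene_annotation(genes: Sequence[GeneRecord], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "gene_name": g.gene_name,
                "chromosome": g.chromosome,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "biotype": g.biotype,
            }
            for g in genes
        ],
        columns=list(_ANNOTATION_COLUMNS),
    ).to_csv(path, sep="\t", index=False)


def read_gtf_genes(path: str | Path) -> list[GeneRecord]:
    """Convenience GTF reader: extract gene features into GeneRecords.

    Only ``gene`` features are used; gene_id/gene_name/gene_biotype are read
    from the attribute column.  This is a thin import helper, not a general
    GTF model.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="merge",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    records = []
    for feat in db.features_of_type("gene"):
        attrs = feat.attributes
        gene_id = attrs.get("gene_id", [feat.id])[0]
        records.append(
            GeneRecord(
                gene_id=gene_id,
                gene_name=attrs.get("gene_name", [gene_id])[0],
                chromosome=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "unknown",
                biotype=attrs.get(
                    "gene_biotype", attrs.get("gene_type", ["protein_coding"])
                )[0],
            )
        )
    return records
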