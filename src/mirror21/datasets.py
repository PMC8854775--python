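"""Bundled published reference data for the ring-chromosome-21 study.

Ships the printed per-gene results for the 23 chromosome-21 genes with
mirrored expression (downregulated in the partial-monosomy line RD_P26,
upregulated in the merged trisomy-21 condition DSm) together with the two
hemizygous deletion intervals of the ring chromosome (hg38).  The full
genome-scale expression data are deposited under GEO accession GSE190053 and
are not bundled; these desk-scale numbers suffice to replay the DEG decision
rules, the mirroring logic and the region annotation on published values.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .regions import GeneRecord, GenomicInterval

#: hemizygous deletions of the ring chromosome 21 (1-based closed, hg38)
RING21_DELETIONS = (
    GenomicInterval("21", 41_994_799, 43_447_106, "deletion_1"),
    GenomicInterval("21", 44_361_567, 46_944_323, "deletion_2"),
)


def _parse_p(value: str) -> float:
    """Printed adjusted p; ``<x`` entries are taken at their upper bound x."""
    text = str(value).strip()
    if text.startswith("<"):
        return float(text[1:])
    return float(text)


def load_chr21_mirrored_table() -> pd.DataFrame:
    """The published 23-row chr21 mirrored-gene table, indexed by gene name.

    Columns: start (hg38 bp), log2_fc / linear_fc / p_adj for the monosomy
    (RD_P26 vs euploid) and trisomy (DSm vs euploid) contrasts.  p-values
    printed as ``<0.001`` are stored as 0.001.
    """
    with resources.files("mirror21.data").joinpath(
        "chr21_mirrored_genes.tsv"
    ).open() as handle:
        frame = pd.read_csv(handle, sep="\t")
    for col in ("p_adj_monosomy", "p_adj_trisomy"):
        frame[col] = frame[col].map(_parse_p)
    return frame.set_index("gene_name")


def chr21_gene_records() -> list[GeneRecord]:
    """GeneRecords for the published table (start coordinates only).

    The table prints start positions but not gene ends; records use
    ``end = start`` and are meant for start-point region classification.
    """
    table = load_chr21_mirrored_table()
    return [
        GeneRecord(
            gene_id=name,
            gene_name=name,
            chromosome="21",
            start=int(row.start),
            end=int(row.start),
        )
        for name, row in table.iterrows()
    ]


def published_de_tables(base_mean: float = 100.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The printed statistics as a pair of DE tables (monosomy, trisomy).

    ``base_mean`` is not printed per gene; every published row survived the
    base-mean >= 5 filter, so a value above the filter is assigned.  The
    returned frames plug directly into the DEG classifier and the mirroring
    stage.
    """
    table = load_chr21_mirrored_table()
    frames = []
    for contrast in ("monosomy", "trisomy"):
        frames.append(
            pd.DataFrame(
                {
                    "base_mean": base_mean,
                    "log2_fc": table[f"log2_fc_{contrast}"].astype(float),
                    "linear_fc": np.exp2(table[f"log2_fc_{contrast}"].astype(float)),
                    "se": np.nan,
                    "wald_p": np.nan,
                    "adj_p": table[f"p_adj_{contrast}"].astype(float),
                },
                index=table.index.rename("gene_id"),
            )
        )
    return frames[0], frames[1]
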