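"""End-to-end orchestration: one reproducible run with publication-style summaries.

Stage order: region annotation -> differential expression (monosomy vs
euploid, merged trisomy vs euploid) -> mirrored-gene analysis with the
permutation null -> allele-specific expression (optional) -> gene-set
over-representation (optional).  Every output file lands in the run
directory and is listed, with a content hash, in ``manifest.json``; a rerun
with the identical config and seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import ase as ase_mod
from . import enrichment as enrich_mod
from .diffexpr import CountMatrix, DEGThresholds, nb_wald, write_de_table
from .mirror import (
    deletion_gene_ids,
    merge_trisomy,
    mirrored_fraction,
    permutation_test,
    shared_and_mirrored,
    venn_counts,
)
from .regions import RegionClass, classify_gene, load_deletions, read_gene_annotation

log = logging.getLogger("mirror21")


def format_percentage(numerator: int, denominator: int, decimals: int = 1) -> str:
    """Half-up-rounded percentage string, e.g. ``(172, 1951, 1) -> '8.8%'``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(numerator) / Decimal(denominator) * 100
    quantum = Decimal(1).scaleb(-decimals)
    return f"{pct.quantize(quantum, rounding=ROUND_HALF_UP)}%"


def format_fraction(numerator: int, denominator: int, decimals: int = 1) -> str:
    """Percentage with its ``(k of n)`` companion, e.g. ``8.8% (172 of 1951)``."""
    return (
        f"{format_percentage(numerator, denominator, decimals)} "
        f"({numerator} of {denominator})"
    )


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    counts: Path
    samples: Path
    annotation: Path
    deletions: Path
    outdir: Path
    variants: Optional[Path] = None
    gene_sets: Optional[Path] = None
    trisomy_lines: tuple[str, ...] = ("DS1", "DS2")
    thresholds: DEGThresholds = field(default_factory=DEGThresholds)
    n_permutations: int = 1000
    seed: int = 0
    vicinity_bp: int = 1_000_000
    region_mode: str = "start_point"
    min_variant_depth: int = 50
    enrichment_fdr: float = 0.001
    collapse_replicates: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thresholds = DEGThresholds(**raw.pop("thresholds", {}))
        paths = {
            k: Path(raw.pop(k))
            for k in ("counts", "samples", "annotation", "deletions", "outdir")
        }
        for opt in ("variants", "gene_sets"):
            if raw.get(opt) is not None:
                raw[opt] = Path(raw[opt])
        if "trisomy_lines" in raw:
            raw["trisomy_lines"] = tuple(raw["trisomy_lines"])
        config = cls(**paths, thresholds=thresholds, **raw)
        config.validate()
        return config

    def validate(self) -> None:
        for name in ("counts", "samples", "annotation", "deletions"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        for name in ("variants", "gene_sets"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


@dataclass
class SummaryReport:
    seed: int
    contrasts: dict
    mirror: dict
    permutation: dict
    ase: Optional[dict]
    enrichment: Optional[dict]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "contrasts": self.contrasts,
            "mirror": self.mirror,
            "permutation": self.permutation,
            "ase": self.ase,
            "enrichment": self.enrichment,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> SummaryReport:
    """Execute all stages; writes artifacts + manifest under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        # ---- regions -----------------------------------------------------
        stage = "regions"
        deletions = load_deletions(config.deletions)
        annotation = read_gene_annotation(config.annotation)
        region_class = pd.Series(
            {
                g.gene_id: classify_gene(
                    g, deletions, config.vicinity_bp, config.region_mode
                ).name
                for g in annotation
            },
            name="region_class",
        )
        chr21_ids = {g.gene_id for g in annotation if g.chromosome == "21"}
        deleted_ids = deletion_gene_ids(annotation, deletions, config.region_mode)
        log.info(
            "regions: %d genes, %d on chr21, %d in deletions",
            len(annotation), len(chr21_ids), len(deleted_ids),
        )

        # ---- differential expression ------------------------------------
        stage = "diffexpr"
        counts = CountMatrix.read(config.counts, config.samples)
        merged = merge_trisomy(counts, list(config.trisomy_lines))
        de_tables: dict[str, pd.DataFrame] = {}
        contrasts_summary: dict[str, dict] = {}
        for contrast_name in ("monosomy", "trisomy"):
            de = nb_wald(
                merged,
                (contrast_name, "control"),
                thresholds=config.thresholds,
                collapse_replicates=config.collapse_replicates,
            )
            de["region_class"] = region_class.reindex(de.index)
            path = outdir / f"de_{contrast_name}.tsv"
            write_de_table(de, path)
            written.append(path)
            de_tables[contrast_name] = de

            detected = de["deg_status"] != "FILTERED_LOW_EXPRESSION"
            is_deg = de["deg_status"].isin(["UP", "DOWN"])
            on_chr21 = de.index.isin(list(chr21_ids))
            contrasts_summary[contrast_name] = {
                "n_genes": int(len(de)),
                "n_detected": int(detected.sum()),
                "n_degs": int(is_deg.sum()),
                "percent_degs": format_fraction(
                    int(is_deg.sum()), int(detected.sum())
                ),
                "chr21_detected": int((detected & on_chr21).sum()),
                "chr21_degs": int((is_deg & on_chr21).sum()),
            }
            log.info(
                "diffexpr %s: %s DEGs", contrast_name,
                contrasts_summary[contrast_name]["percent_degs"],
            )

        # ---- mirror ------------------------------------------------------
        stage = "mirror"
        result = shared_and_mirrored(
            de_tables["monosomy"], de_tables["trisomy"], deleted_genes=deleted_ids
        )
        venn = venn_counts(result, annotation, deletions)
        venn_path = outdir / "venn_counts.tsv"
        venn.to_csv(venn_path, sep="\t")
        written.append(venn_path)
        status = result.status_table()
        status["region_class"] = region_class.reindex(status.index)
        status_path = outdir / "mirror_status.tsv"
        status.to_csv(status_path, sep="\t")
        written.append(status_path)

        perm = permutation_test(
            de_tables["monosomy"],
            de_tables["trisomy"],
            n=config.n_permutations,
            seed=config.seed,
            thresholds=config.thresholds,
            exclude_deleted=True,
            deleted_genes=deleted_ids,
        )
        perm_path = outdir / "permutation.json"
        perm_path.write_text(json.dumps(perm.to_dict(), indent=2, sort_keys=True))
        written.append(perm_path)

        have_degs = bool(result.degs_a)
        mirror_summary = {
            "n_degs_monosomy": len(result.degs_a),
            "n_degs_trisomy": len(result.degs_b),
            "n_shared": len(result.shared_degs),
            "n_mirrored": len(result.mirrored),
            "fraction_all": mirrored_fraction(result) if have_degs else None,
            "fraction_excluding_deleted": (
                mirrored_fraction(result, exclude_deleted=True) if have_degs else None
            ),
            "percent_mirrored": (
                format_fraction(len(result.mirrored), len(result.degs_a))
                if have_degs
                else None
            ),
        }
        log.info(
            "mirror: %d shared, %d mirrored, permutation p = %.4g",
            len(result.shared_degs), len(result.mirrored), perm.empirical_p,
        )

        # ---- ASE (optional) ---------------------------------------------
        stage = "ase"
        ase_summary_dict = None
        if config.variants is not None:
            records = ase_mod.read_vcf(config.variants)
            kept = ase_mod.filter_variants(records, config.min_variant_depth)
            log.info("ase: %d of %d variants pass filters", len(kept), len(records))
            summary = ase_mod.ase_summary(kept, deletions, config.vicinity_bp)
            ase_path = outdir / "ase_summary.tsv"
            summary.per_class.to_csv(ase_path, sep="\t")
            written.append(ase_path)
            ase_summary_dict = {
                "n_input": len(records),
                "n_kept": len(kept),
                "n_anomalies_in_deletions": len(summary.anomalies),
                "mean_fraction_outside": summary.mean_fraction(RegionClass.OUTSIDE),
            }

        # ---- enrichment (optional) ---------------------------------------
        stage = "enrichment"
        enrichment_dict = None
        if config.gene_sets is not None:
            collection = enrich_mod.read_gmt(config.gene_sets)
            de_a = de_tables["monosomy"]
            universe = frozenset(
                de_a.index[de_a["deg_status"] != "FILTERED_LOW_EXPRESSION"]
            )
            degs = frozenset(de_a.index[de_a["deg_status"].isin(["UP", "DOWN"])])
            table = enrich_mod.overrepresentation(
                degs, universe, collection, fdr_cutoff=config.enrichment_fdr
            )
            enrich_path = outdir / "enrichment.tsv"
            table.to_csv(enrich_path, sep="\t")
            written.append(enrich_path)
            enrichment_dict = {
                "n_terms_tested": len(collection),
                "n_terms_kept": int(len(table)),
                "fdr_cutoff": config.enrichment_fdr,
            }
            log.info(
                "enrichment: %d of %d terms pass FDR", len(table), len(collection)
            )
    except StageError:
        raise
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise StageError(f"pipeline stage '{stage}' failed: {exc}") from exc

    report = SummaryReport(
        seed=config.seed,
        contrasts=contrasts_summary,
        mirror=mirror_summary,
        permutation=perm.to_dict(),
        ase=ase_summary_dict,
        enrichment=enrichment_dict,
    )
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    written.append(report_path)

    manifest = {
        "seed": config.seed,
        "inputs": {
            name: str(getattr(config, name))
            for name in (
                "counts", "samples", "annotation", "deletions",
                "variants", "gene_sets",
            )
            if getattr(config, name) is not None
        },
        "outputs": {p.name: _sha256(p) for p in written},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return report
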