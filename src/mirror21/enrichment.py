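"""Gene-set over-representation: fold enrichment, exact p, FDR filter.

A generic stand-in for pathway-database enrichment: for each named gene set,
compare the observed overlap with a DEG list against the expectation under
random sampling from the detected-gene universe.  Fold enrichment is
observed/expected (values below 1 are depletions and are reported too);
significance is a two-sided exact hypergeometric (minimum-likelihood) p, and
terms are kept when the Benjamini-Hochberg FDR is at or below the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


@dataclass
class GeneSetCollection:
    """Named gene sets with term descriptions (GMT-style)."""

    sets: dict[str, frozenset]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {k: frozenset(v) for k, v in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def restricted_to(self, universe: frozenset) -> tuple["GeneSetCollection", int]:
        """Drop members outside the universe; returns (collection, n_dropped)."""
        dropped = 0
        restricted = {}
        for name, members in self.sets.items():
            kept = members & universe
            dropped += len(members) - len(kept)
            restricted[name] = kept
        return GeneSetCollection(restricted, dict(self.descriptions)), dropped


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (term <tab> description <tab> member...)."""
    sets, descriptions = {}, {}
    with Path(path).open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            term, desc, *members = fields
            sets[term] = frozenset(m for m in members if m)
            descriptions[term] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as out:
        for term, members in collection.sets.items():
            desc = collection.descriptions.get(term, "")
            out.write("\t".join([term, desc, *sorted(members)]) + "\n")


def hypergeometric_p(k: int, n_universe: int, n_degs: int, n_term: int) -> float:
    """Two-sided exact p for an overlap of ``k`` (minimum-likelihood method).

    Sums P(X = x) over all x whose point probability does not exceed that of
    the observed overlap, X ~ Hypergeometric(N, K, n) — the same convention
    as the two-sided Fisher exact test.
    """
    support = np.arange(
        max(0, n_degs + n_term - n_universe), min(n_degs, n_term) + 1
    )
    pmf = stats.hypergeom.pmf(support, n_universe, n_term, n_degs)
    observed = stats.hypergeom.pmf(k, n_universe, n_term, n_degs)
    # small relative tolerance guards against ties lost to rounding
    return float(min(1.0, pmf[pmf <= observed * (1 + 1e-9)].sum()))


def overrepresentation(
    degs: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
    fdr_cutoff: float = 0.001,
    apply_filter: bool = True,
) -> pd.DataFrame:
    """Over-representation of each term in the DEG list.

    Returns a table (term, n_term, k, expected, fold_enrichment, p, fdr)
    sorted by descending fold enrichment, filtered to FDR <= ``fdr_cutoff``
    unless ``apply_filter`` is False.  Set members outside the universe are
    dropped (count in the ``n_members_dropped`` attribute of the result).
    """
    degs = frozenset(degs)
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty gene universe")
    offenders = degs - universe
    if offenders:
        raise ValueError(
            f"{len(offenders)} DEG(s) outside the universe, e.g. "
            f"{sorted(offenders)[:5]}"
        )
    collection, dropped = collection.restricted_to(universe)

    n_universe, n_degs = len(universe), len(degs)
    rows = []
    for term, members in collection.sets.items():
        n_term = len(members)
        k = len(members & degs)
        expected = n_degs * n_term / n_universe
        rows.append(
            {
                "term": term,
                "description": collection.descriptions.get(term, ""),
                "n_term": n_term,
                "k": k,
                "expected": expected,
                "fold_enrichment": (k / expected) if expected > 0 else np.nan,
                "p": hypergeometric_p(k, n_universe, n_degs, n_term)
                if n_term
                else np.nan,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "term", "description", "n_term", "k", "expected",
            "fold_enrichment", "p",
        ],
    ).set_index("term")
    tested = table["p"].notna()
    table["fdr"] = np.nan
    if tested.any():
        table.loc[tested, "fdr"] = bh_adjust(table.loc[tested, "p"].to_numpy())
    if apply_filter:
        table = table[table["fdr"] <= fdr_cutoff]
    table = table.sort_values("fold_enrichment", ascending=False)
    table.attrs["n_members_dropped"] = dropped
    return table
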