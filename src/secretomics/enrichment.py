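"""Hypergeometric over-representation analysis (ORA) of gene sets.

Tests whether a hit list is enriched for members of annotated gene sets
relative to the detected-proteome universe.  For a universe of N genes of
which K belong to a set, and a hit list of n genes of which k belong to
the set, the upper-tail hypergeometric probability P(X >= k) is the ORA
p-value; BH adjustment is applied across all tested sets in a collection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .errors import ConfigurationError, ParseError
from .modstats import bh_adjust

__all__ = ["GeneSetCollection", "EnrichmentTable", "ora", "read_gmt"]


@dataclass
class GeneSetCollection:
    """Named gene sets (name -> set of gene identifiers)."""

    sets: dict[str, set[str]]
    label: str = ""
    n_dropped_empty: int = 0

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ConfigurationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EnrichmentTable:
    """ORA results, one row per tested set.

    ``table`` columns: set_name, overlap, set_size, hit_size, universe_size,
    p, p_adj, overlap_genes.  ``skipped_sets`` lists sets whose intersection
    with the universe had fewer than 2 genes.
    """

    table: pd.DataFrame
    skipped_sets: list[str] = field(default_factory=list)


def ora(
    hit_set,
    universe,
    collection: GeneSetCollection,
    min_set_size: int = 2,
) -> EnrichmentTable:
    """Upper-tail hypergeometric over-representation of each set among the hits.

    ``p = P(X >= k)`` with population ``N = |universe|``, successes
    ``K = |set ∩ universe|``, draws ``n = |hit_set|`` and observed
    ``k = |set ∩ hit_set|``.  Sets are intersected with the universe before
    testing; sets whose intersection has fewer than ``min_set_size`` genes
    are skipped and reported.  Hits must be a subset of the universe.
    """
    hits = set(hit_set)
    uni = set(universe)
    outside = sorted(hits - uni)
    if outside:
        raise ConfigurationError(f"hit genes absent from the universe: {outside[:10]}")

    n_universe, n_hits = len(uni), len(hits)
    rows = []
    skipped: list[str] = []
    for name, genes in collection.sets.items():
        in_uni = genes & uni
        if len(in_uni) < min_set_size:
            skipped.append(name)
            continue
        overlap = sorted(in_uni & hits)
        k = len(overlap)
        # P(X >= k); sf(k-1) is exact for the discrete distribution
        p = float(hypergeom.sf(k - 1, n_universe, len(in_uni), n_hits))
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": len(in_uni),
                "hit_size": n_hits,
                "universe_size": n_universe,
                "p": min(p, 1.0),
                "overlap_genes": ",".join(overlap),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["set_name", "overlap", "set_size", "hit_size",
                 "universe_size", "p", "overlap_genes"],
    )
    table["p_adj"] = bh_adjust(table["p"]) if len(table) else []
    table = table[["set_name", "overlap", "set_size", "hit_size",
                   "universe_size", "p", "p_adj", "overlap_genes"]]
    return EnrichmentTable(table, skipped)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file: name, description, then tab-separated genes.

    Duplicate genes within a set are collapsed; lines with a name and
    description but no genes define empty sets and are dropped with a
    warning count.  A line with fewer than two fields is malformed.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    n_dropped = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path.name}:{lineno}: expected name, description, genes")
            name = fields[0]
            genes = {g for g in fields[2:] if g}
            if not genes:
                n_dropped += 1
                continue
            if name in sets:
                raise ParseError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            sets[name] = genes
    if n_dropped:
        warnings.warn(f"{path.name}: dropped {n_dropped} empty gene set(s)", stacklevel=2)
    return GeneSetCollection(sets, label=path.stem, n_dropped_empty=n_dropped)
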