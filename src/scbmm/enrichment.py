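"""Hypergeometric over-representation of gene sets with BH correction.

Query gene lists (differentially expressed genes, expressed ligands or
receptors of a cell type) are tested for over-representation against a
GMT collection.  The test is the one-sided hypergeometric upper tail
(equivalently a one-sided Fisher exact test on the 2x2 table), with the
universe restricted to the measured genes and Benjamini-Hochberg
correction across the collection's terms.  Queries below a minimum size
(default 20 genes) are gated out rather than tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "EnrichmentTable",
    "read_gmt",
    "hypergeom_enrich",
    "enrich_min_genes_gate",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. GO Biological Processes) from a GMT file."""

    sets: dict[str, set[str]]
    name: str = ""

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty gene set: {term!r}")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Read a GMT file: per line, term <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (needs >= 3 fields): {line[:80]!r}")
        term = fields[0]
        if term in sets:
            raise ValueError(f"duplicate term in GMT: {term!r}")
        genes = {g for g in fields[2:] if g}
        sets[term] = genes
    return GeneSetCollection(sets, name=name or Path(path).stem)


@dataclass
class EnrichmentTable:
    table: pd.DataFrame
    meta: dict = field(default_factory=dict)
    reason: str | None = None

    COLUMNS = (
        "term", "overlap_count", "term_size", "query_size", "universe_size",
        "p_raw", "p_bh",
    )

    @classmethod
    def empty(cls, reason: str, meta: dict | None = None) -> "EnrichmentTable":
        return cls(pd.DataFrame(columns=list(cls.COLUMNS)), meta=meta or {}, reason=reason)

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def enrich_min_genes_gate(query, min_genes: int = 20) -> bool:
    """Whether a query list is large enough to be worth testing."""
    return len(set(query)) >= min_genes


def hypergeom_enrich(
    query, collection: GeneSetCollection, universe
) -> EnrichmentTable:
    """One-sided hypergeometric over-representation per term, BH across terms.

    Terms are restricted to the universe; query genes outside the
    universe are dropped with a warning.  For a term of size K in a
    universe of size M with a query of size N overlapping in k genes,
    ``p_raw = P(X >= k)`` for X ~ Hypergeom(M, K, N).
    """
    universe = set(universe)
    if len(universe) < 2:
        raise ValueError("universe must contain at least 2 genes")
    query = set(query)
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped"
        )
    query &= universe

    meta = {
        "collection": collection.name,
        "universe_size": len(universe),
        "query_size": len(query),
    }
    if not query:
        return EnrichmentTable.empty("empty_query_after_intersection", meta)

    m = len(universe)
    n_query = len(query)
    rows = []
    for term in sorted(collection.sets):
        term_genes = collection.sets[term] & universe
        k_term = len(term_genes)
        overlap = len(term_genes & query)
        # P(X >= overlap); sf(k-1) is the inclusive upper tail
        p = float(hypergeom.sf(overlap - 1, m, k_term, n_query)) if k_term else 1.0
        rows.append(
            {
                "term": term,
                "overlap_count": overlap,
                "term_size": k_term,
                "query_size": n_query,
                "universe_size": m,
                "p_raw": min(1.0, p),
            }
        )

    table = pd.DataFrame(rows, columns=[c for c in EnrichmentTable.COLUMNS if c != "p_bh"])
    if len(table):
        table["p_bh"] = multipletests(table["p_raw"].to_numpy(), method="fdr_bh")[1]
    else:
        table["p_bh"] = []
    return EnrichmentTable(table[list(EnrichmentTable.COLUMNS)], meta=meta)
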