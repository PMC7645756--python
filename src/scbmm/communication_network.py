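"""Ligand-receptor intercellular communication networks per timepoint.

A cell type "expresses" a gene at a timepoint when at least 20% of its
cells (inclusive threshold) have a nonzero raw count.  For every
ligand-receptor pair in a curated database, a directed link
sender -> receiver is formed whenever the sender expresses the ligand
and the receiver expresses the receptor; autocrine (self) links are
allowed.  Edge weights of the per-timepoint network count these links
per ordered cell-type pair, so summed edge weights equal the number of
links.  Networks across timepoints are compared by signed edge-weight
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .core_io import CountMatrix

__all__ = [
    "LRDatabase",
    "LinkTable",
    "CommNetwork",
    "expressed_genes_by_type",
    "build_links",
    "network_from_links",
    "delta_network",
    "communication_strength",
    "ligand_and_receptor_lists",
]


@dataclass
class LRDatabase:
    """Directed ligand -> receptor gene pairs (symbols)."""

    pairs: pd.DataFrame  # columns: ligand, receptor
    provenance: str = ""

    def __post_init__(self) -> None:
        required = {"ligand", "receptor"}
        if not required.issubset(self.pairs.columns):
            raise ValueError("LR table must have 'ligand' and 'receptor' columns")
        self.pairs = self.pairs[["ligand", "receptor"]].astype(str)
        if (self.pairs["ligand"].str.len() == 0).any() or (
            self.pairs["receptor"].str.len() == 0
        ).any():
            raise ValueError("empty gene symbols in LR table")
        if self.pairs.duplicated().any():
            dup = self.pairs[self.pairs.duplicated()].iloc[0]
            raise ValueError(f"duplicate LR pair: {dup['ligand']} -> {dup['receptor']}")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def ligands(self) -> set[str]:
        return set(self.pairs["ligand"])

    @property
    def receptors(self) -> set[str]:
        return set(self.pairs["receptor"])

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str | None = None) -> "LRDatabase":
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
        return cls(df, provenance=provenance or str(path))

    def to_tsv(self, path: str | Path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)

    def coverage(self, gene_universe) -> dict:
        """How much of the pair list is measurable in a gene universe."""
        universe = set(gene_universe)
        both = (
            self.pairs["ligand"].isin(universe) & self.pairs["receptor"].isin(universe)
        ).sum()
        return {
            "n_pairs": len(self.pairs),
            "n_pairs_measurable": int(both),
            "coverage": float(both / len(self.pairs)) if len(self.pairs) else 1.0,
        }


@dataclass
class LinkTable:
    """One row per directed ligand-receptor link at a timepoint."""

    links: pd.DataFrame  # ligand, receptor, sender_type, receiver_type, timepoint
    coverage: dict = field(default_factory=dict)

    COLUMNS = ("ligand", "receptor", "sender_type", "receiver_type", "timepoint")

    def __len__(self) -> int:
        return len(self.links)

    def write(self, path: str | Path) -> None:
        self.links.to_csv(path, sep="\t", index=False)


@dataclass
class CommNetwork:
    """Directed weighted cell-type graph for one timepoint."""

    timepoint: str
    nodes: list[str]
    weights: dict[tuple[str, str], int] = field(default_factory=dict)

    def weight(self, sender: str, receiver: str) -> int:
        return int(self.weights.get((sender, receiver), 0))

    def total_links(self) -> int:
        return int(sum(self.weights.values()))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(timepoint=self.timepoint)
        g.add_nodes_from(self.nodes)
        for (s, r), w in self.weights.items():
            if w:
                g.add_edge(s, r, weight=int(w))
        return g

    def to_edgelist(self) -> pd.DataFrame:
        rows = [
            {"timepoint": self.timepoint, "sender": s, "receiver": r, "weight": int(w)}
            for (s, r), w in sorted(self.weights.items())
            if w
        ]
        return pd.DataFrame(rows, columns=["timepoint", "sender", "receiver", "weight"])

    def write(self, path: str | Path) -> None:
        self.to_edgelist().to_csv(path, sep="\t", index=False)


def expressed_genes_by_type(
    cm: CountMatrix, timepoint: str, threshold: float = 0.20
) -> dict[str, set[str]]:
    """Per cell type, the genes expressed in >= ``threshold`` of its cells.

    Expression is nonzero raw count; the boundary is inclusive (exactly
    20% qualifies).  Only cell types with at least one cell at the
    timepoint appear in the result.
    """
    at_tp = (cm.cell_meta["timepoint"] == timepoint).to_numpy()
    if not at_tp.any():
        raise KeyError(f"no cells at timepoint {timepoint!r}")
    out: dict[str, set[str]] = {}
    types = [t for t in pd.unique(cm.cell_meta["cell_type"][at_tp]) if not pd.isna(t)]
    for ct in sorted(types, key=str):
        idx = np.flatnonzero(at_tp & (cm.cell_meta["cell_type"] == ct).to_numpy())
        frac = cm.counts[idx].getnnz(axis=0) / len(idx)
        out[str(ct)] = set(cm.gene_ids[frac >= threshold])
    return out


def build_links(
    expressed_map: dict[str, set[str]],
    lrdb: LRDatabase,
    timepoint: str,
    gene_universe=None,
) -> LinkTable:
    """Enumerate directed links: ligand in sender, receptor in receiver.

    Self-links (sender == receiver) are included.  Pairs whose genes are
    absent from ``gene_universe`` (when given) are silently unmatched
    but tallied in the coverage report.
    """
    if not expressed_map:
        raise ValueError("expressed_map is empty")
    types = sorted(expressed_map)
    rows = []
    for _, pair in lrdb.pairs.iterrows():
        lig, rec = pair["ligand"], pair["receptor"]
        senders = [t for t in types if lig in expressed_map[t]]
        receivers = [t for t in types if rec in expressed_map[t]]
        for s in senders:
            for r in receivers:
                rows.append(
                    {
                        "ligand": lig,
                        "receptor": rec,
                        "sender_type": s,
                        "receiver_type": r,
                        "timepoint": timepoint,
                    }
                )
    coverage = lrdb.coverage(gene_universe) if gene_universe is not None else {}
    return LinkTable(
        pd.DataFrame(rows, columns=list(LinkTable.COLUMNS)), coverage=coverage
    )


def network_from_links(links: LinkTable, nodes: list[str] | None = None) -> CommNetwork:
    """Aggregate a LinkTable into per-(sender, receiver) edge weights."""
    df = links.links
    tp = str(df["timepoint"].iloc[0]) if len(df) else ""
    if nodes is None:
        nodes = sorted(set(df["sender_type"]) | set(df["receiver_type"]))
    weights: dict[tuple[str, str], int] = {}
    if len(df):
        grouped = df.groupby(["sender_type", "receiver_type"], observed=False).size()
        weights = {(str(s), str(r)): int(w) for (s, r), w in grouped.items()}
    return CommNetwork(timepoint=tp, nodes=list(nodes), weights=weights)


def delta_network(net_t: CommNetwork, net_ref: CommNetwork) -> dict[tuple[str, str], int]:
    """Signed edge-weight differences net_t - net_ref (zero-filled union)."""
    nodes = sorted(set(net_t.nodes) | set(net_ref.nodes))
    delta = {}
    for s in nodes:
        for r in nodes:
            d = net_t.weight(s, r) - net_ref.weight(s, r)
            if d != 0:
                delta[(s, r)] = d
    return delta


def communication_strength(net: CommNetwork, cell_type: str) -> dict[str, int]:
    """Weighted out-/in-degree of a cell type (self-links count in each)."""
    if cell_type not in net.nodes:
        raise KeyError(f"unknown cell type: {cell_type}")
    out_links = sum(w for (s, _r), w in net.weights.items() if s == cell_type)
    in_links = sum(w for (_s, r), w in net.weights.items() if r == cell_type)
    return {
        "out_links": int(out_links),
        "in_links": int(in_links),
        "total": int(out_links + in_links),
    }


def ligand_and_receptor_lists(
    expressed_map: dict[str, set[str]], lrdb: LRDatabase, cell_type: str
) -> dict[str, set[str]]:
    """Expressed ligands and receptors of one cell type (feeds enrichment)."""
    if cell_type not in expressed_map:
        raise KeyError(f"cell type {cell_type!r} not in expressed_map")
    expressed = expressed_map[cell_type]
    return {
        "expressed_ligands": expressed & lrdb.ligands,
        "expressed_receptors": expressed & lrdb.receptors,
    }
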