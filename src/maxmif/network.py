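"""Weighted undirected PPI networks (HumanNet / STRING style edge lists).

Weights are standardized on load by dividing every retained raw weight by the
largest one, so W(i,j) lies in (0, 1] and at least one edge has W = 1.  The
interaction distance between two interacting genes is r_ij = 1/W(i,j) >= 1,
and r_max = 1/min(W) is the largest interaction distance in the network.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .errors import AbsentEdgeError, EmptyDataError, FormatError

#: Column-index mappings for common edge-list dialects (gene_a, gene_b, weight).
PLAIN_COLUMNS: tuple[int, int, int] = (0, 1, 2)
HUMANNET_COLUMNS: tuple[int, int, int] = (0, 1, 2)  # gene1  gene2  LLS
STRING_COLUMNS: tuple[int, int, int] = (0, 1, 2)  # protein1 protein2 combined_score


@dataclass(frozen=True)
class WeightedNetwork:
    """Undirected graph whose edges carry standardized weights in (0, 1]."""

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def r_max(self) -> float:
        """Largest interaction distance = reciprocal of the smallest weight."""
        wmin = min(w for _, _, w in self.graph.edges.data("weight"))
        return 1.0 / wmin

    def weight(self, i: str, j: str) -> float:
        if not self.graph.has_edge(i, j):
            raise AbsentEdgeError(f"({i!r}, {j!r}) is not an edge of the network")
        return float(self.graph[i][j]["weight"])

    def has_edge(self, i: str, j: str) -> bool:
        return self.graph.has_edge(i, j)

    def edges(self) -> list[tuple[str, str, float]]:
        """Deterministically ordered (u, v, weight) triples with u < v."""
        return sorted(
            (min(u, v), max(u, v), float(w)) for u, v, w in self.graph.edges.data("weight")
        )


def build_network(edges: Sequence[tuple[str, str, float]]) -> WeightedNetwork:
    """Assemble a standardized network from raw weighted edges.

    Self-loops are removed first, duplicate undirected edges collapse keeping
    the maximum raw weight, then all weights are divided by the largest
    retained raw weight.
    """
    best: dict[tuple[str, str], float] = {}
    for a, b, w in edges:
        if w <= 0:
            raise FormatError(f"nonpositive weight {w!r} on edge ({a!r}, {b!r})")
        if a == b:
            continue
        key = (a, b) if a <= b else (b, a)
        if w > best.get(key, 0.0):
            best[key] = float(w)
    if not best:
        raise EmptyDataError("no edges remain after removing self-loops")
    wmax = max(best.values())
    g = nx.Graph()
    for (a, b), w in best.items():
        g.add_edge(a, b, weight=w / wmax)
    return WeightedNetwork(g)


def load_network(
    path: str | Path, columns: tuple[int, int, int] = PLAIN_COLUMNS
) -> WeightedNetwork:
    """Read a >=3-column TSV edge list and return the standardized network.

    ``columns`` gives the (gene_a, gene_b, weight) column indices, which is all
    it takes to adapt HumanNet ('gene1 gene2 LLS') or STRING
    ('protein1 protein2 combined_score') exports.  A header line is detected by
    the weight field not parsing as a number; '#' lines are skipped.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] <= max(columns):
        raise FormatError(
            f"edge list {path} has {df.shape[1]} columns; need at least {max(columns) + 1}"
        )
    ia, ib, iw = columns
    first_w = df.iloc[0, iw]
    try:
        float(first_w)
    except (TypeError, ValueError):
        df = df.iloc[1:]  # header line
    if df.empty:
        raise EmptyDataError(f"no edges in {path}")
    try:
        weights = df.iloc[:, iw].astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric weight in {path}: {exc}") from exc
    triples = list(zip(df.iloc[:, ia], df.iloc[:, ib], weights))
    return build_network(triples)


def write_network(net: WeightedNetwork, path: str | Path) -> None:
    """Write the standardized edge list (full float precision, sorted edges)."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, w in net.edges():
            fh.write(f"{a}\t{b}\t{w!r}\n")


def interaction_distance(net: WeightedNetwork, i: str, j: str) -> float:
    """r_ij = 1/W(i,j); raises :class:`AbsentEdgeError` for non-edges."""
    return 1.0 / net.weight(i, j)


def neighbors(net: WeightedNetwork, i: str) -> set[str]:
    """Adjacency set J_i of gene ``i`` (empty for isolated or unknown genes)."""
    if i not in net.graph:
        return set()
    return set(net.graph.neighbors(i)) - {i}
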