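"""Lightweight undirected / directed graph containers.

The correlation graphs in this package are small (hundreds of nodes) and the
community-detection code needs a dense adjacency matrix with a fixed node
order, so a minimal container is used rather than a full graph library.
Node order is insertion order and every iteration method is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class Graph:
    """Undirected weighted graph without self-loops.

    Parameters
    ----------
    nodes : iterable of hashable, optional
        Initial node set; order is preserved and defines matrix row order.
    """

    def __init__(self, nodes=()):
        self._nodes: list = []
        self._index: dict = {}
        self._adj: dict = {}
        for n in nodes:
            self.add_node(n)
        self.meta: dict = {}

    # -- construction -------------------------------------------------
    def add_node(self, n) -> None:
        if n not in self._index:
            self._index[n] = len(self._nodes)
            self._nodes.append(n)
            self._adj[n] = {}

    def add_edge(self, u, v, weight: float = 1.0) -> None:
        if u == v:
            raise ValueError("self-loops are not allowed")
        self.add_node(u)
        self.add_node(v)
        self._adj[u][v] = float(weight)
        self._adj[v][u] = float(weight)

    # -- queries ------------------------------------------------------
    @property
    def nodes(self) -> list:
        return list(self._nodes)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def has_edge(self, u, v) -> bool:
        return v in self._adj.get(u, ())

    def weight(self, u, v) -> float:
        return self._adj[u][v]

    def degree(self, n) -> int:
        return len(self._adj[n])

    def neighbors(self, n) -> list:
        nbrs = self._adj[n]
        return sorted(nbrs, key=self._index.__getitem__)

    def edges(self):
        """Yield (u, v, weight) with u preceding v in node order."""
        for u in self._nodes:
            iu = self._index[u]
            for v, w in self._adj[u].items():
                if self._index[v] > iu:
                    yield u, v, w

    def adjacency_matrix(self, weighted: bool = False) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        for u, v, w in self.edges():
            val = w if weighted else 1.0
            i, j = self._index[u], self._index[v]
            a[i, j] = a[j, i] = val
        return a

    def subgraph(self, nodes) -> "Graph":
        keep = set(nodes)
        g = Graph(n for n in self._nodes if n in keep)
        for u, v, w in self.edges():
            if u in keep and v in keep:
                g.add_edge(u, v, w)
        return g

    def connected_components(self) -> list:
        """Components as lists of nodes, deterministic order."""
        seen: set = set()
        comps = []
        for start in self._nodes:
            if start in seen:
                continue
            stack, comp = [start], []
            seen.add(start)
            while stack:
                n = stack.pop()
                comp.append(n)
                for v in self.neighbors(n):
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            comps.append(sorted(comp, key=self._index.__getitem__))
        return comps

    def __contains__(self, n) -> bool:
        return n in self._index

    def __repr__(self) -> str:
        return f"Graph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass
class DirectedEdge:
    """One directed group-to-group interaction mediated by a ligand–receptor pair."""

    source: object
    target: object
    pair: str
    source_fraction: float
    target_fraction: float


@dataclass
class InteractionNetwork:
    """Directed multigraph between phenotype groups.

    Edges are justified by significant enrichment of the source group in the
    paracrine-source regime and of the target group in the paracrine-target
    regime for the mediating pair; autocrine enrichment yields self-loops.
    """

    group_sizes: dict = field(default_factory=dict)
    edges: list = field(default_factory=list)

    def add_edge(self, source, target, pair, source_fraction, target_fraction):
        self.edges.append(
            DirectedEdge(source, target, pair, float(source_fraction), float(target_fraction))
        )

    def sorted_edges(self) -> list:
        return sorted(
            self.edges, key=lambda e: (str(e.pair), str(e.source), str(e.target))
        )

    @property
    def n_edges(self) -> int:
        return len(self.edges)
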