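"""Layered (multilayer) graph container shared by all modules.

A :class:`LayeredGraph` is an undirected graph whose nodes carry a
1-based layer index (layer 1 = staff/base layer, indices increase up the
hierarchy).  Edges between nodes of equal layer are *intra-layer* edges;
edges between nodes of different layers are *inter-layer* edges.  The
container wraps a :class:`networkx.Graph` and adds the array views the
simulation engine needs (CSR adjacency, per-node layer vector).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = ["LayeredGraph", "CommunityPartition"]


@dataclass(frozen=True)
class CommunityPartition:
    """Assignment of base-layer nodes to ``c`` communities (ids ``0..c-1``)."""

    community_of: dict
    c: int

    def __post_init__(self):
        ids = set(self.community_of.values())
        if len(ids) != self.c or ids != set(range(self.c)):
            raise ValueError(
                f"partition must use exactly the community ids 0..{self.c - 1} "
                f"and every community must be non-empty"
            )

    def members(self, j: int) -> list:
        return sorted(n for n, cj in self.community_of.items() if cj == j)

    def sizes(self) -> np.ndarray:
        out = np.zeros(self.c, dtype=np.int64)
        for cj in self.community_of.values():
            out[cj] += 1
        return out


class LayeredGraph:
    """Undirected multilayer graph with integer node ids and per-node layers.

    Parameters
    ----------
    graph:
        networkx graph whose every node has an integer ``"layer"``
        attribute >= 1.  Self-loops are rejected.
    """

    def __init__(self, graph: nx.Graph):
        if any(u == v for u, v in nx.selfloop_edges(graph)):
            raise ValueError("self-loops are not allowed")
        for n, data in graph.nodes(data=True):
            lay = data.get("layer")
            if lay is None or int(lay) < 1:
                raise ValueError(f"node {n!r} lacks a valid layer index >= 1")
        self.graph = graph
        self._csr = None

    # -- basic views ---------------------------------------------------
    @property
    def node_ids(self) -> list:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def layer_of(self) -> dict:
        return {n: int(d["layer"]) for n, d in self.graph.nodes(data=True)}

    @property
    def layers(self) -> list:
        return sorted(set(self.layer_of.values()))

    def nodes_in_layer(self, layer: int) -> list:
        return sorted(n for n, l in self.layer_of.items() if l == layer)

    def layer_sizes(self) -> dict:
        sizes: dict = {}
        for l in self.layer_of.values():
            sizes[l] = sizes.get(l, 0) + 1
        return sizes

    @property
    def intra_edges(self) -> set:
        lay = self.layer_of
        return {
            frozenset((u, v)) for u, v in self.graph.edges if lay[u] == lay[v]
        }

    @property
    def inter_edges(self) -> set:
        lay = self.layer_of
        return {
            frozenset((u, v)) for u, v in self.graph.edges if lay[u] != lay[v]
        }

    # -- array views for the engine ------------------------------------
    def csr(self):
        """Return ``(indptr, indices, layer_arr, id_index)``.

        Positional CSR adjacency over nodes sorted by id; ``id_index``
        maps node id -> position.
        """
        if self._csr is None:
            ids = self.node_ids
            idx = {n: i for i, n in enumerate(ids)}
            n = len(ids)
            lay = self.layer_of
            layer_arr = np.array([lay[u] for u in ids], dtype=np.int32)
            deg = np.zeros(n, dtype=np.int64)
            for u, v in self.graph.edges:
                deg[idx[u]] += 1
                deg[idx[v]] += 1
            indptr = np.zeros(n + 1, dtype=np.int64)
            np.cumsum(deg, out=indptr[1:])
            indices = np.zeros(indptr[-1], dtype=np.int32)
            fill = indptr[:-1].copy()
            for u, v in self.graph.edges:
                iu, iv = idx[u], idx[v]
                indices[fill[iu]] = iv
                fill[iu] += 1
                indices[fill[iv]] = iu
                fill[iv] += 1
            # sort each neighbor list for reproducible speaker indexing
            for i in range(n):
                indices[indptr[i]:indptr[i + 1]].sort()
            self._csr = (indptr, indices, layer_arr, idx)
        return self._csr

    # -- dunder / comparison -------------------------------------------
    def edge_set(self) -> set:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def __eq__(self, other) -> bool:
        if not isinstance(other, LayeredGraph):
            return NotImplemented
        return (
            self.layer_of == other.layer_of
            and self.edge_set() == other.edge_set()
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"LayeredGraph(n={self.n_nodes}, "
            f"edges={self.graph.number_of_edges()}, layers={self.layers})"
        )
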