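"""Synthetic two-layer hierarchical network construction.

The staff (base) layer is a random geometric graph (RGG) on the unit
square; it is partitioned into ``c`` communities with the fluid
communities algorithm, and a management layer of exactly ``c`` nodes is
attached, one manager per community, with manager-manager wiring chosen
from {isolated, full, rgg, er, ba}.

Realized RGG mean degree falls below the nominal ``k_avg`` implied by
the radius formula ``r = sqrt(k_avg / (n * pi))`` because discs near the
unit-square boundary are clipped; the exact expectation is
``(n-1) * (pi r^2 - 8 r^3 / 3 + r^4 / 2)`` (about 6.7% low at k=20,
n=1000).  This matches the conventional generator the radius formula
assumes; no wraparound is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .layered import CommunityPartition, LayeredGraph

__all__ = [
    "SyntheticConfig",
    "make_base_rgg",
    "rgg_expected_degree",
    "partition_fluid",
    "attach_management_layer",
    "build_synthetic_hierarchy",
]

MANAGER_TOPOLOGIES = ("isolated", "full", "rgg", "er", "ba")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic hierarchy.

    ``manager_k_or_p`` is a mean degree for ``rgg``/``ba`` manager
    wiring and a connection probability for ``er``; ignored for
    ``isolated`` and ``full``.
    """

    n_staff: int = 1000
    k_avg: float = 20.0
    c_frac: float = 0.06
    manager_topology: str = "isolated"
    manager_k_or_p: float = 20.0
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.c_frac < 1:
            raise ValueError("c_frac must lie in (0, 1)")
        if self.k_avg <= 0:
            raise ValueError("k_avg must be positive")
        if round(self.c_frac * self.n_staff) < 1:
            raise ValueError("c_frac * n_staff must round to >= 1 manager")
        if self.manager_topology not in MANAGER_TOPOLOGIES:
            raise ValueError(
                f"manager_topology must be one of {MANAGER_TOPOLOGIES}"
            )

    @property
    def c(self) -> int:
        return int(round(self.c_frac * self.n_staff))


def _rgg_radius(n: int, k_avg: float) -> float:
    return math.sqrt(k_avg / (n * math.pi))


def rgg_expected_degree(n: int, k_avg: float) -> float:
    """Exact expected degree of the unit-square RGG at the nominal radius.

    Accounts for boundary clipping of the connection disc:
    ``E[deg] = (n-1) * (pi r^2 - 8 r^3/3 + r^4/2)`` for ``r <= 1``.
    """
    r = _rgg_radius(n, k_avg)
    area = math.pi * r**2 - (8.0 / 3.0) * r**3 + 0.5 * r**4
    return (n - 1) * area


def _edges_from_positions(pos: np.ndarray, radius: float) -> np.ndarray:
    """All pairs at Euclidean distance <= radius (inclusive boundary)."""
    tree = cKDTree(pos)
    return tree.query_pairs(radius, output_type="ndarray")


def make_base_rgg(n_staff: int, k_avg: float, rng_seed: int) -> LayeredGraph:
    """Random geometric graph on the unit square, all nodes in layer 1.

    Nodes ``0..n_staff-1`` are placed uniformly at random; an edge joins
    every pair at Euclidean distance <= ``r = sqrt(k_avg/(n_staff*pi))``.
    """
    if n_staff < 2:
        raise ValueError("n_staff must be >= 2")
    if k_avg <= 0:
        raise ValueError("k_avg must be positive")
    r = _rgg_radius(n_staff, k_avg)
    if r >= math.sqrt(2.0):
        raise ValueError(
            f"k_avg={k_avg} implies radius {r:.3f} >= unit-square diameter; "
            "the graph would be trivially complete"
        )
    rng = np.random.default_rng(rng_seed)
    pos = rng.random((n_staff, 2))
    g = nx.Graph()
    g.add_nodes_from(range(n_staff), layer=1)
    g.add_edges_from(map(tuple, _edges_from_positions(pos, r)))
    for i in range(n_staff):
        g.nodes[i]["pos"] = (float(pos[i, 0]), float(pos[i, 1]))
    return LayeredGraph(g)


def partition_fluid(
    graph: LayeredGraph, c: int, rng_seed: int, max_retries: int = 5
) -> CommunityPartition:
    """Partition the base layer into exactly ``c`` fluid communities.

    Requires a connected base layer.  The fluid-communities algorithm is
    retried with fresh seeds if a sweep fails to converge.
    """
    base_nodes = graph.nodes_in_layer(1)
    sub = graph.graph.subgraph(base_nodes)
    if not (1 <= c <= len(base_nodes)):
        raise ValueError("c must satisfy 1 <= c <= base-layer size")
    if not nx.is_connected(sub):
        raise ValueError("base layer must be connected for fluid communities")
    last_err: Exception | None = None
    for attempt in range(max_retries):
        try:
            comms = list(
                nx.community.asyn_fluidc(sub, c, seed=rng_seed + attempt)
            )
            community_of = {n: j for j, comm in enumerate(comms) for n in comm}
            return CommunityPartition(community_of=community_of, c=c)
        except nx.NetworkXError as err:  # pragma: no cover - rare
            last_err = err
    raise RuntimeError(
        f"fluid communities failed after {max_retries} retries"
    ) from last_err


def _manager_intra_edges(
    c: int, topology: str, k_or_p: float, rng_seed: int
) -> list:
    """Intra-layer edge list (0-based manager indices) for the topology."""
    if topology == "isolated":
        return []
    if topology == "full":
        return [(i, j) for i in range(c) for j in range(i + 1, c)]
    if topology == "er":
        p = float(k_or_p)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"er topology needs probability in [0,1], got {p}")
        g = nx.gnp_random_graph(c, p, seed=rng_seed)
        return list(g.edges)
    if topology == "ba":
        m_ba = max(1, int(round(k_or_p / 2.0)))
        if m_ba >= c:
            raise ValueError("ba attachment parameter must be < manager count")
        g = nx.barabasi_albert_graph(c, m_ba, seed=rng_seed)
        return list(g.edges)
    if topology == "rgg":
        if k_or_p <= 0:
            raise ValueError("rgg topology needs a positive mean degree")
        r = _rgg_radius(c, k_or_p)
        rng = np.random.default_rng(rng_seed)
        pos = rng.random((c, 2))
        return [tuple(e) for e in _edges_from_positions(pos, min(r, 1.5))]
    raise ValueError(f"unknown manager topology {topology!r}")


def attach_management_layer(
    base: LayeredGraph,
    partition: CommunityPartition,
    topology: str,
    manager_k_or_p: float,
    rng_seed: int,
) -> LayeredGraph:
    """Attach a layer-2 manager per community on top of the base layer.

    Manager ``j`` receives inter-layer edges to every node of community
    ``j``; manager-manager (intra-layer) edges follow ``topology``.
    Manager node ids continue after the largest base node id.
    """
    base_nodes = base.nodes_in_layer(1)
    if set(partition.community_of) != set(base_nodes):
        raise ValueError("partition must cover exactly the base layer")
    c = partition.c
    g = base.graph.copy()
    first = max(base.graph.nodes) + 1
    manager_ids = [first + j for j in range(c)]
    g.add_nodes_from(manager_ids, layer=2)
    for node, j in partition.community_of.items():
        g.add_edge(node, manager_ids[j])
    for i, j in _manager_intra_edges(c, topology, manager_k_or_p, rng_seed):
        g.add_edge(manager_ids[i], manager_ids[j])
    return LayeredGraph(g)


def build_synthetic_hierarchy(
    cfg: SyntheticConfig, max_connect_retries: int = 100
) -> tuple[LayeredGraph, CommunityPartition]:
    """RGG base + fluid partition + management layer, all from one config.

    The RGG draw is regenerated with successive seeds until connected
    (disconnection is rare at the default mean degree of 20).
    Deterministic given ``cfg.rng_seed``.
    """
    base = None
    for attempt in range(max_connect_retries):
        candidate = make_base_rgg(cfg.n_staff, cfg.k_avg, cfg.rng_seed + attempt)
        if nx.is_connected(candidate.graph):
            base = candidate
            break
    if base is None:
        raise RuntimeError(
            f"no connected RGG draw within {max_connect_retries} attempts"
        )
    partition = partition_fluid(base, cfg.c, rng_seed=cfg.rng_seed)
    graph = attach_management_layer(
        base, partition, cfg.manager_topology, cfg.manager_k_or_p, cfg.rng_seed
    )
    return graph, partition
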