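"""Seed-node selection strategies for spreading experiments.

Strategies: uniform ``random`` within a layer, top total ``degree``,
``voterank`` (iterative influential-spreader election) and ``onion``
(onion-decomposition layer, a refinement of the k-core number).
Centrality rankings are computed on the full multilayer graph and then
filtered to the requested level, so inter-layer edges contribute to a
node's influence; ``level="all"`` drops the filter.  Deterministic
strategies break ties by higher degree, then lower node id.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .layered import LayeredGraph

__all__ = ["SeedSpec", "select_seeds", "onion_layers"]

STRATEGIES = ("random", "degree", "voterank", "onion")


@dataclass(frozen=True)
class SeedSpec:
    """Strategy, target level (layer index or ``"all"``) and seed count."""

    strategy: str = "random"
    level: int | str = 1
    count: int = 1

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.level != "all" and int(self.level) < 1:
            raise ValueError('level must be a layer index >= 1 or "all"')


def onion_layers(graph: LayeredGraph | nx.Graph) -> dict:
    """Onion-decomposition index per node (iterative min-degree peeling).

    Nodes removed in the first peeling round get index 1; the index
    weakly refines the k-core number.
    """
    g = graph.graph if isinstance(graph, LayeredGraph) else graph
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    return nx.onion_layers(g)


def _eligible(graph: LayeredGraph, level) -> list:
    if level == "all":
        return graph.node_ids
    nodes = graph.nodes_in_layer(int(level))
    if not nodes:
        raise ValueError(f"no nodes on level {level}")
    return nodes


def select_seeds(
    graph: LayeredGraph,
    spec: SeedSpec,
    rng_stream: np.random.Generator | None = None,
) -> set:
    """Pick ``spec.count`` seed nodes from the eligible level.

    random: uniform without replacement (requires ``rng_stream``);
    degree: top-count by total degree; voterank: VoteRank elected order
    on the full graph filtered to the level (degree ranking fills any
    shortfall); onion: descending onion index.  All deterministic
    strategies reproduce without randomness.
    """
    eligible = _eligible(graph, spec.level)
    if spec.count > len(eligible):
        raise ValueError(
            f"count={spec.count} exceeds the {len(eligible)} eligible nodes"
        )
    if spec.count == 0:
        return set()
    g = graph.graph
    deg = dict(g.degree)

    def degree_ranked(nodes):
        return sorted(nodes, key=lambda u: (-deg[u], u))

    if spec.strategy == "random":
        if rng_stream is None:
            raise ValueError("random strategy needs an rng_stream")
        pick = rng_stream.choice(
            len(eligible), size=spec.count, replace=False
        )
        return {eligible[int(i)] for i in pick}
    if spec.strategy == "degree":
        return set(degree_ranked(eligible)[: spec.count])
    if spec.strategy == "voterank":
        elected = [u for u in nx.voterank(g) if u in set(eligible)]
        chosen = elected[: spec.count]
        if len(chosen) < spec.count:  # voterank elected too few on this level
            rest = [u for u in degree_ranked(eligible) if u not in set(chosen)]
            chosen += rest[: spec.count - len(chosen)]
        return set(chosen)
    if spec.strategy == "onion":
        onion = onion_layers(graph)
        ranked = sorted(
            eligible, key=lambda u: (-onion[u], -deg[u], u)
        )
        return set(ranked[: spec.count])
    raise AssertionError("unreachable")
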