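"""Empirical organizational networks: CSV I/O, layer statistics, fixtures.

Organizational networks arrive as two CSV files: a node list
(``node_id,level``) and an edge list (``source,target`` with an optional
``weight`` column carrying co-working hours or message counts).  The
module also generates synthetic fixtures emulating the two empirical
topologies studied here:

* *Line-Org*: formal administrative structure — base-layer department
  cliques plus a manager tree with sibling-group cliques at each
  management level and a single apex node.
* *Project*: the same nodes and manager tree, but intra-layer edges from
  a co-working model that skews degree toward the lower management
  layers (the "major hub" pattern).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .layered import LayeredGraph

__all__ = [
    "OrgNodeRecord",
    "WeightedEdgeRecord",
    "LayerStats",
    "read_org_network",
    "write_org_network",
    "read_weighted_edges",
    "threshold_weighted_edges",
    "threshold_for_target_degree",
    "layer_stats",
    "make_lineorg_fixture",
    "make_project_fixture",
]


@dataclass(frozen=True)
class OrgNodeRecord:
    node_id: int
    level: int


@dataclass(frozen=True)
class WeightedEdgeRecord:
    node_u: int
    node_v: int
    weight: float


@dataclass
class LayerStats:
    """Per-layer and total mean closeness, degree and clustering.

    ``per_layer`` maps layer index -> (closeness, degree, clustering);
    ``total`` holds the same triple over all nodes.  ``connected`` flags
    whether closeness was computed on a connected graph (otherwise the
    component-size-normalized convention applies).
    """

    per_layer: dict
    total: tuple
    connected: bool

    def to_frame(self) -> pd.DataFrame:
        rows = {
            f"Layer {l}": vals for l, vals in sorted(self.per_layer.items())
        }
        rows["Total"] = self.total
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["closeness", "degree", "clustering"]
        )


def read_org_network(node_csv, edge_csv) -> LayeredGraph:
    """Build a LayeredGraph from a node-list CSV and an edge-list CSV.

    The node list needs columns ``node_id,level`` (header required); the
    edge list ``source,target``.  Edges are undirected and deduplicated;
    any edge endpoint missing from the node list is an error.
    """
    nodes = pd.read_csv(node_csv)
    nodes.columns = [c.strip().lower() for c in nodes.columns]
    if nodes["node_id"].duplicated().any():
        dup = nodes.loc[nodes["node_id"].duplicated(), "node_id"].iloc[0]
        raise ValueError(f"duplicate node id {dup} in node list")
    g = nx.Graph()
    for rec in nodes.itertuples(index=False):
        level = int(rec.level)
        if level < 1:
            raise ValueError(f"node {rec.node_id}: level must be >= 1")
        g.add_node(int(rec.node_id), layer=level)
    edges = pd.read_csv(edge_csv)
    edges.columns = [c.strip().lower() for c in edges.columns]
    known = set(g.nodes)
    for rec in edges.itertuples(index=False):
        u, v = int(rec.source), int(rec.target)
        if u not in known or v not in known:
            missing = u if u not in known else v
            raise ValueError(f"edge references unknown node id {missing}")
        if u != v:
            g.add_edge(u, v)
    return LayeredGraph(g)


def write_org_network(graph: LayeredGraph, node_csv, edge_csv) -> None:
    """Write the node-list / edge-list CSV pair (round-trips with reader)."""
    lay = graph.layer_of
    pd.DataFrame(
        {"node_id": graph.node_ids, "level": [lay[n] for n in graph.node_ids]}
    ).to_csv(node_csv, index=False)
    rows = sorted(tuple(sorted(e)) for e in graph.edge_set())
    pd.DataFrame(rows, columns=["source", "target"]).to_csv(
        edge_csv, index=False
    )


def read_weighted_edges(edge_csv) -> list:
    """Read a weighted edge CSV (``source,target,weight``)."""
    df = pd.read_csv(edge_csv)
    df.columns = [c.strip().lower() for c in df.columns]
    out = []
    for rec in df.itertuples(index=False):
        u, v, w = int(rec.source), int(rec.target), float(rec.weight)
        if u == v:
            raise ValueError(f"self-loop on node {u} in weighted edge list")
        if w < 0:
            raise ValueError(f"negative weight on edge ({u},{v})")
        out.append(WeightedEdgeRecord(u, v, w))
    return out


def threshold_weighted_edges(records, threshold: float) -> set:
    """Keep edges whose weight is *strictly* greater than ``threshold``.

    This is the co-working rule used to define the Project graph (e.g.
    "more than 370 hours").
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return {
        frozenset((r.node_u, r.node_v))
        for r in records
        if r.weight > threshold
    }


def threshold_for_target_degree(
    records, n_nodes: int, target_k: float
) -> float:
    """Pick the weight threshold whose surviving edges best match a mean degree.

    Scans the sorted unique weights and returns the threshold for which
    the surviving edge count is closest to ``target_k * n_nodes / 2``.
    """
    target_edges = target_k * n_nodes / 2.0
    weights = np.array(sorted({r.weight for r in records}))
    counts = np.array(
        [sum(1 for r in records if r.weight > w) for w in weights]
    )
    best = int(np.argmin(np.abs(counts - target_edges)))
    return float(weights[best])


def layer_stats(graph: LayeredGraph) -> LayerStats:
    """Mean closeness centrality, degree and local clustering by layer.

    Closeness is computed on the whole multilayer graph (the hierarchy's
    apex keeps it connected in the intended use); per-layer means
    average the per-node values within each layer.  On disconnected
    graphs the component-size-normalized closeness convention is used
    and the result is flagged via ``connected=False``.
    """
    g = graph.graph
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    closeness = nx.closeness_centrality(g)  # wf_improved: component-normalized
    clustering = nx.clustering(g)
    degree = dict(g.degree)
    lay = graph.layer_of

    def _means(nodes):
        return (
            float(np.mean([closeness[n] for n in nodes])),
            float(np.mean([degree[n] for n in nodes])),
            float(np.mean([clustering[n] for n in nodes])),
        )

    per_layer = {
        l: _means(graph.nodes_in_layer(l)) for l in graph.layers
    }
    return LayerStats(
        per_layer=per_layer,
        total=_means(graph.node_ids),
        connected=nx.is_connected(g),
    )


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def _manager_tree_levels(dept_count: int, depth: int) -> list:
    """Sizes of management levels 2..depth over ``dept_count`` departments.

    Each level groups the previous one by a branching factor chosen so
    that the hierarchy reaches a single apex at level ``depth``.
    """
    if depth < 2:
        raise ValueError("depth must be >= 2")
    sizes = [dept_count]  # level 2 has one manager per department
    n_levels_above = depth - 2  # levels 3..depth
    cur = dept_count
    if n_levels_above > 0:
        b = max(2, int(np.ceil(cur ** (1.0 / n_levels_above))))
        for _ in range(n_levels_above - 1):
            cur = max(1, int(np.ceil(cur / b)))
            sizes.append(cur)
        sizes.append(1)  # apex
    elif dept_count > 1:
        raise ValueError(
            "depth=2 requires a single department (no apex otherwise)"
        )
    return sizes


def _build_manager_tree(dept_sizes, level_sizes, sibling_cliques: bool):
    """Shared skeleton for both fixtures.

    ``level_sizes`` lists the management-level sizes for levels
    2..depth; level 2 must equal ``len(dept_sizes)`` and the top level
    must be 1 (the apex).  Returns ``(graph, dept_members, level_nodes)``
    with base nodes (no intra-layer edges yet), manager nodes, the
    inter-layer tree edges, and — if ``sibling_cliques`` — clique edges
    among managers sharing a parent.
    """
    dept_count = len(dept_sizes)
    if level_sizes[0] != dept_count:
        raise ValueError("level-2 size must equal the department count")
    if level_sizes[-1] != 1:
        raise ValueError("top level must hold a single apex node")
    if any(a < b for a, b in zip(level_sizes, level_sizes[1:])):
        raise ValueError("management levels must shrink going up")
    g = nx.Graph()
    next_id = 0
    dept_members = []
    for size in dept_sizes:
        members = list(range(next_id, next_id + size))
        g.add_nodes_from(members, layer=1)
        dept_members.append(members)
        next_id += size

    level_nodes = {1: [n for m in dept_members for n in m]}
    for li, size in enumerate(level_sizes, start=2):
        nodes = list(range(next_id, next_id + size))
        g.add_nodes_from(nodes, layer=li)
        level_nodes[li] = nodes
        next_id += size
        if li == 2:
            for mgr, members in zip(nodes, dept_members, strict=True):
                for n in members:
                    g.add_edge(mgr, n)
        else:
            # split previous level's managers into `size` contiguous groups
            prev = level_nodes[li - 1]
            groups = [list(arr) for arr in np.array_split(prev, size)]
            for mgr, members in zip(nodes, groups, strict=True):
                for n in members:
                    g.add_edge(mgr, n)
                if sibling_cliques:
                    for i, u in enumerate(members):
                        for v in members[i + 1:]:
                            g.add_edge(u, v)
    return g, dept_members, level_nodes


def make_lineorg_fixture(
    dept_count: int,
    dept_size_mean: float,
    depth: int,
    rng_seed: int,
) -> LayeredGraph:
    """Synthetic administrative hierarchy in the Line-Org style.

    Base layer: ``dept_count`` disjoint department cliques with sizes
    drawn around ``dept_size_mean`` (>= 2).  Each department's manager
    connects down to all members and up to its group manager; managers
    sharing a parent form sibling cliques; a single apex sits at layer
    ``depth``.
    """
    rng = np.random.default_rng(rng_seed)
    sizes = np.maximum(
        2, rng.poisson(max(dept_size_mean - 2.0, 0.0), size=dept_count) + 2
    )
    g, dept_members, level_nodes = _build_manager_tree(
        sizes.tolist(),
        _manager_tree_levels(dept_count, depth),
        sibling_cliques=True,
    )
    # department cliques
    for members in dept_members:
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                g.add_edge(u, v)
    # level-2 sibling cliques: managers grouped under a common level-3 parent
    if depth >= 3:
        for parent in level_nodes[3]:
            sibs = [
                n for n in g.neighbors(parent) if g.nodes[n]["layer"] == 2
            ]
            for i, u in enumerate(sibs):
                for v in sibs[i + 1:]:
                    g.add_edge(u, v)
    return LayeredGraph(g)


def make_project_fixture(
    layer_sizes,
    hub_skew: float,
    k_avg: float,
    rng_seed: int,
) -> LayeredGraph:
    """Synthetic co-working network in the Project style.

    Keeps the Line-Org manager *tree* for inter-layer edges but draws
    intra-layer edges from layer-wise Erdos-Renyi models whose target
    mean degree grows as ``hub_skew**(min(layer,3)-1)``, concentrating
    degree in the lower management layers.  The base scale is set so the
    whole-graph mean degree (tree edges included) is approximately
    ``k_avg``.
    """
    layer_sizes = list(layer_sizes)
    depth = len(layer_sizes)
    if depth < 2:
        raise ValueError("need at least two layers")
    if layer_sizes[-1] != 1:
        raise ValueError("top layer must have exactly one (apex) node")
    if hub_skew <= 0:
        raise ValueError("hub_skew must be positive")
    dept_count = layer_sizes[1]
    # distribute staff across departments as evenly as possible
    staff = layer_sizes[0]
    base, extra = divmod(staff, dept_count)
    dept_sizes = [base + (1 if i < extra else 0) for i in range(dept_count)]
    if min(dept_sizes) < 1:
        raise ValueError("more departments than staff")
    g, _, level_nodes = _build_manager_tree(
        dept_sizes, layer_sizes[1:], sibling_cliques=False
    )
    n_total = g.number_of_nodes()
    tree_degree = 2.0 * g.number_of_edges() / n_total
    k_intra = k_avg - tree_degree
    if k_intra <= 0:
        raise ValueError(f"k_avg={k_avg} below the tree's own mean degree")
    rel = {
        li: hub_skew ** (min(li, 3) - 1) for li in range(1, depth + 1)
    }
    weight_mass = sum(len(level_nodes[li]) * rel[li] for li in level_nodes)
    scale = k_intra * n_total / weight_mass
    rng = np.random.default_rng(rng_seed)
    for li, nodes in level_nodes.items():
        n_l = len(nodes)
        if n_l < 2:
            continue
        k_l = min(scale * rel[li], n_l - 1.0)
        p = k_l / (n_l - 1)
        sub = nx.gnp_random_graph(
            n_l, p, seed=int(rng.integers(2**31 - 1))
        )
        relabel = dict(enumerate(nodes))
        g.add_edges_from(
            (relabel[u], relabel[v]) for u, v in sub.edges
        )
    return LayeredGraph(g)
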