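"""Weighted entity graph, modularity, and hierarchical Leiden communities.

Entities are nodes; merged relations are undirected weighted edges
(parallel relations between the same pair collapse into one edge with
summed weight).  Partition quality is Newman-Girvan modularity

    Q = (1/2m) * sum_ij [ A_ij - k_i k_j / 2m ] * delta(c_i, c_j)

with k_i the weighted degree and m half the total of the adjacency matrix.
Q = 0 for the all-in-one partition; negative Q means worse than the
degree-preserving random expectation.

Community detection uses the Leiden algorithm (via ``leidenalg``), chosen
for its guarantee that every community is internally connected.  A
hierarchy is built by iterated coarsening: communities become nodes of an
aggregate graph (inter-community weights summed, intra-community weight as
a self-loop) which is re-clustered, until a single community remains, the
partition stops coarsening, or ``max_levels`` is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import networkx as nx

from agrigraph.errors import DataError
from agrigraph.extraction import EntityRecord, RelationRecord

__all__ = [
    "CommunityHierarchy",
    "Partition",
    "build_graph",
    "detect_hierarchy",
    "modularity",
]


def build_graph(
    entities: list[EntityRecord], relations: list[RelationRecord]
) -> nx.Graph:
    """Build the undirected weighted entity graph.

    Node ids are the (normalized) entity names; edge attribute ``weight``
    sums parallel relation weights and ``relation_types`` records the
    collapsed relation labels.  Isolated entities stay as degree-0 nodes.
    """
    g = nx.Graph()
    names = {e.name for e in entities}
    for e in entities:
        g.add_node(e.name, entity_type=e.entity_type)
    for r in relations:
        if r.head not in names or r.tail not in names:
            raise DataError(f"relation endpoint not among entities: {r.head}|{r.tail}")
        if g.has_edge(r.head, r.tail):
            g[r.head][r.tail]["weight"] += r.weight
            g[r.head][r.tail]["relation_types"].append(r.relation_type)
        else:
            g.add_edge(r.head, r.tail, weight=r.weight, relation_types=[r.relation_type])
    return g


def modularity(g: nx.Graph, partition: dict[str, int | str]) -> float:
    """Weighted modularity Q of *partition* on *g*.

    Computed per community as ``(w_in - (k_c)^2 / 2m) / 2m`` aggregates,
    algebraically equal to the pairwise double sum.  Degree-0 nodes
    contribute nothing.  An empty edge set leaves Q undefined.
    """
    missing = set(g.nodes) - set(partition)
    if missing:
        raise DataError(f"partition missing nodes: {sorted(missing)[:3]}")
    two_m = 2.0 * g.size(weight="weight")
    if two_m == 0:
        raise DataError("modularity undefined on a graph with no edge weight")
    degree = dict(g.degree(weight="weight"))
    comm_k: dict[object, float] = {}
    comm_in: dict[object, float] = {}
    for node, c in partition.items():
        comm_k[c] = comm_k.get(c, 0.0) + degree.get(node, 0.0)
    for u, v, w in g.edges(data="weight", default=1.0):
        if partition[u] == partition[v]:
            # each undirected edge appears twice in the double sum
            comm_in[partition[u]] = comm_in.get(partition[u], 0.0) + 2.0 * w
    return sum(
        (comm_in.get(c, 0.0) - comm_k[c] ** 2 / two_m) / two_m for c in comm_k
    )


@dataclass(frozen=True)
class Partition:
    """One hierarchy level: community id -> frozen member set."""

    level: int
    communities: dict[str, frozenset[str]]

    def community_of(self) -> dict[str, str]:
        return {n: cid for cid, members in self.communities.items() for n in members}


@dataclass
class CommunityHierarchy:
    """Nested partitions from leaves (level 0) upward.

    ``parent_of`` maps a community id at level l to its enclosing community
    at level l+1; top-level communities have no entry.
    """

    levels: list[Partition]
    parent_of: dict[str, str] = field(default_factory=dict)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def children_of(self, community_id: str) -> list[str]:
        return sorted(c for c, p in self.parent_of.items() if p == community_id)

    def modularities(self, g: nx.Graph) -> list[float]:
        return [modularity(g, p.community_of()) for p in self.levels]


def _to_igraph(g: nx.Graph) -> tuple[ig.Graph, list[str]]:
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges]
    weights = [float(g[u][v].get("weight", 1.0)) for u, v in g.edges]
    ig_g = ig.Graph(n=len(nodes), edges=edges)
    ig_g.es["weight"] = weights
    return ig_g, nodes


def _community_ids(level: int, groups: list[list[str]]) -> dict[str, frozenset[str]]:
    # stable ids: communities ordered by their smallest member
    ordered = sorted(groups, key=lambda members: min(members))
    return {f"c{level}_{i}": frozenset(members) for i, members in enumerate(ordered)}


def detect_hierarchy(
    g: nx.Graph,
    seed: int = 0,
    resolution: float = 1.0,
    max_levels: int = 2,
) -> CommunityHierarchy:
    """Hierarchical Leiden partition of *g*.

    Level 0 is a Leiden partition at the given resolution and seed (every
    leaf community internally connected, modularity at least that of the
    singleton partition).  Higher levels re-cluster the aggregate graph
    until one community remains, coarsening stalls, or ``max_levels``
    levels exist.  A single-node graph yields one trivial community.
    """
    if g.number_of_nodes() == 0:
        raise DataError("cannot partition an empty graph")
    ig_g, nodes = _to_igraph(g)
    part = leidenalg.find_partition(
        ig_g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if ig_g.ecount() else None,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    groups = [[nodes[i] for i in members] for members in part]
    levels = [Partition(0, _community_ids(0, groups))]
    parent_of: dict[str, str] = {}

    while len(levels) < max_levels and len(levels[-1].communities) > 1:
        prev = levels[-1]
        cids = sorted(prev.communities)
        agg = nx.Graph()
        agg.add_nodes_from(cids)
        node_comm = prev.community_of()
        for u, v, w in g.edges(data="weight", default=1.0):
            cu, cv = node_comm[u], node_comm[v]
            if agg.has_edge(cu, cv):
                agg[cu][cv]["weight"] += w
            else:
                agg.add_edge(cu, cv, weight=w)  # cu == cv -> self-loop (intra weight)
        ig_agg, agg_nodes = _to_igraph(agg)
        agg_part = leidenalg.find_partition(
            ig_agg,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight" if ig_agg.ecount() else None,
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=-1,
        )
        agg_groups = [[agg_nodes[i] for i in members] for members in agg_part]
        if len(agg_groups) >= len(prev.communities):
            break  # coarsening stalled
        level = len(levels)
        merged: list[list[str]] = [
            sorted(set().union(*(prev.communities[c] for c in group)))
            for group in agg_groups
        ]
        new_comms = _community_ids(level, merged)
        levels.append(Partition(level, new_comms))
        for pid, members in new_comms.items():
            for cid in cids:
                if prev.communities[cid] <= members:
                    parent_of[cid] = pid
    return CommunityHierarchy(levels=levels, parent_of=parent_of)


def singleton_modularity(g: nx.Graph) -> float:
    return modularity(g, {n: n for n in g.nodes})


def leaf_connected(g: nx.Graph, hierarchy: CommunityHierarchy) -> bool:
    """True iff every leaf community induces a connected subgraph
    (singletons count as connected) — the Leiden guarantee."""
    for members in hierarchy.levels[0].communities.values():
        sub = g.subgraph(members)
        if sub.number_of_nodes() > 1 and not nx.is_connected(sub):
            return False
    return True
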