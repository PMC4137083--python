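"""Interaction Strength and the community-wise network.

Communities interact when their member genes do.  The Interaction Strength
(IS) between two disjoint communities is the observed number of inter-
community edges divided by the count expected if edges were placed
uniformly at the gene-wise network's global density rho = 2E / (N(N-1)):

    IS(i, j) = observed_ij / (n_i * n_j * rho)

IS = 0 exactly when no inter-edge exists; an edge joins two communities in
the community-wise network iff IS > 0.  Super-communities are found by
re-running MCODE on the unweighted topology of that network restricted to
communities of at least ``min_size`` genes — IS magnitudes rank edges for
reporting but do not influence the clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .config import MCODEParams
from .errors import DataError
from .mcode import Community, detect_communities

__all__ = [
    "interaction_strength",
    "CommunityGraph",
    "build_community_graph",
    "SuperCommunity",
    "detect_supercommunities",
]


def _inter_edges(graph: nx.Graph, a: frozenset, b: frozenset) -> int:
    small, other = (a, b) if len(a) <= len(b) else (b, a)
    return sum(1 for u in small for v in graph.neighbors(u) if v in other)


def interaction_strength(graph: nx.Graph, comm_i, comm_j) -> float:
    """IS between two disjoint gene sets on the gene-wise network *graph*."""
    a, b = frozenset(comm_i), frozenset(comm_j)
    if not a or not b:
        raise DataError("communities must be non-empty")
    if a & b:
        raise DataError(f"communities overlap on {sorted(a & b)[:3]}")
    rho = nx.density(graph)
    if rho == 0.0:
        return 0.0
    obs = _inter_edges(graph, a, b)
    return obs / (len(a) * len(b) * rho)


@dataclass
class CommunityGraph:
    """Community-wise network: nodes are community ids, edges carry IS."""

    graph: nx.Graph           # node attrs: size, eligible; edge attrs: inter_edges, IS
    global_density: float
    min_size: int

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (min(i, j), max(i, j), d["inter_edges"], d["IS"])
            for i, j, d in self.graph.edges(data=True)
        ]
        rows.sort()
        return pd.DataFrame(rows, columns=["comm_i", "comm_j", "inter_edges", "IS"])


def build_community_graph(
    graph: nx.Graph,
    communities: list[Community],
    min_size: int = 5,
) -> CommunityGraph:
    """Build the community-wise network over disjoint communities.

    All communities become nodes (for reporting); only those with at least
    ``min_size`` genes are marked eligible for super-community detection.
    An edge (i, j) exists iff at least one gene-wise edge crosses the pair,
    and carries the raw inter-edge count and the IS.
    """
    seen: set = set()
    for c in communities:
        if c.members & seen:
            raise DataError(f"community {c.id} overlaps a previous community")
        seen |= c.members
    rho = nx.density(graph)
    cg = nx.Graph()
    for c in communities:
        cg.add_node(c.id, size=len(c.members), eligible=len(c.members) >= min_size)
    for idx, ci in enumerate(communities):
        for cj in communities[idx + 1:]:
            obs = _inter_edges(graph, ci.members, cj.members)
            if obs > 0:
                is_ = obs / (len(ci.members) * len(cj.members) * rho) if rho else 0.0
                cg.add_edge(ci.id, cj.id, inter_edges=obs, IS=is_)
    return CommunityGraph(graph=cg, global_density=rho, min_size=min_size)


@dataclass(frozen=True)
class SuperCommunity:
    """A densely interconnected group of communities."""

    id: int
    members: frozenset          # community ids
    total_genes: int


def detect_supercommunities(
    cg: CommunityGraph,
    params: MCODEParams = MCODEParams(),
) -> list[SuperCommunity]:
    """MCODE on the eligible-community topology of the community graph."""
    eligible = [n for n, d in cg.graph.nodes(data=True) if d.get("eligible", True)]
    sub = cg.graph.subgraph(eligible)
    found = detect_communities(sub, params)
    out = []
    for sc in found:
        total = sum(cg.graph.nodes[c]["size"] for c in sc.members)
        out.append(SuperCommunity(id=sc.id, members=sc.members, total_genes=total))
    return out


def edge_conservation(graph: nx.Graph, communities: list[Community]) -> dict:
    """Audit: intra + inter + unassigned-touching edge counts sum to E."""
    comm_of: dict = {}
    for c in communities:
        for g in c.members:
            comm_of[g] = c.id
    intra = inter = loose = 0
    for u, v in graph.edges():
        cu, cv = comm_of.get(u), comm_of.get(v)
        if cu is None or cv is None:
            loose += 1
        elif cu == cv:
            intra += 1
        else:
            inter += 1
    return {
        "intra": intra,
        "inter": inter,
        "unassigned": loose,
        "total": graph.number_of_edges(),
    }
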