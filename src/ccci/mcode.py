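"""Molecular Complex Detection (MCODE) from scratch.

Three stages, following the classic seeded-growth design:

1. *Vertex weighting* — each vertex gets ``k * density`` of the highest
   k-core of its closed neighbourhood (the "core-clustering coefficient"
   scaled by the core level).  Vertices below the degree cutoff weigh 0.
2. *Complex prediction* — seeds are visited in decreasing weight; from each
   unassigned seed a breadth-first expansion adds unassigned neighbours
   whose weight is at least ``seed_weight * (1 - node_score_cutoff)``.
3. *Post-processing* — complexes without a 2-core are discarded, degree-1
   members are iteratively shaved off (haircut), optional fluff re-adds
   dense boundary vertices, and complexes are scored ``density * size``.

Topology only: edge weights are carried as metadata but never influence the
clustering.  All ties (seed order, neighbour order, final ranking) break
lexicographically on vertex id so results are independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .config import MCODEParams

__all__ = ["MCODEParams", "Community", "vertex_weight", "compute_weights",
           "predict_complexes", "postprocess", "detect_communities"]


@dataclass(frozen=True)
class Community:
    """A detected complex: disjoint member set with a density*size score."""

    id: int
    members: frozenset
    complex_score: float
    seed: object


def _strip_loops(graph: nx.Graph, params: MCODEParams) -> nx.Graph:
    if not params.include_loops and any(True for _ in nx.selfloop_edges(graph)):
        graph = graph.copy()
        graph.remove_edges_from(nx.selfloop_edges(graph))
    return graph


def _highest_kcore(sub: nx.Graph) -> tuple[int, nx.Graph]:
    """Highest k-core of *sub*: the largest k with a non-empty k-core."""
    if sub.number_of_edges() == 0:
        return 0, sub.subgraph([])
    core_num = nx.core_number(sub)
    k_max = max(core_num.values())
    core_nodes = [v for v, k in core_num.items() if k >= k_max]
    return k_max, sub.subgraph(core_nodes)


def vertex_weight(graph: nx.Graph, v, params: MCODEParams = MCODEParams()) -> float:
    """Core-weighted local density of *v*'s closed neighbourhood.

    Returns ``k * density(highest k-core of G[N[v]])``; 0 when ``deg(v)``
    is below ``params.degree_cutoff``.
    """
    graph = _strip_loops(graph, params)
    if graph.degree(v) < params.degree_cutoff:
        return 0.0
    closed = [v, *graph.neighbors(v)]
    k_max, core = _highest_kcore(graph.subgraph(closed))
    if k_max == 0:
        return 0.0
    return k_max * nx.density(core)


def compute_weights(graph: nx.Graph, params: MCODEParams = MCODEParams()) -> dict:
    graph = _strip_loops(graph, params)
    return {v: vertex_weight(graph, v, params) for v in graph.nodes}


def predict_complexes(
    graph: nx.Graph,
    weights: dict,
    params: MCODEParams = MCODEParams(),
) -> list[list]:
    """Greedy seeded growth, highest-weight seeds first.

    Only vertices with positive weight seed a complex (a zero-weight seed
    would set the expansion threshold to zero and swallow its whole
    component).  Expansion is breadth-first over unassigned vertices up to
    ``max_depth`` levels from the seed; each vertex joins at most one
    complex.  Returned complexes are sorted member lists in seed order.
    """
    graph = _strip_loops(graph, params)
    order = sorted(weights, key=lambda v: (-weights[v], str(v)))
    assigned: set = set()
    complexes: list[list] = []
    for seed in order:
        if seed in assigned or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        assigned.add(seed)
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            nxt = []
            for u in frontier:
                for w in sorted(graph.neighbors(u), key=str):
                    if w in assigned or w in members:
                        continue
                    if weights.get(w, 0.0) >= threshold:
                        members.add(w)
                        assigned.add(w)
                        nxt.append(w)
            frontier = nxt
            depth += 1
        complexes.append(sorted(members, key=str))
    return complexes


def _haircut(sub: nx.Graph) -> nx.Graph:
    sub = sub.copy()
    while True:
        shave = [v for v, d in sub.degree() if d <= 1]
        if not shave:
            return sub
        sub.remove_nodes_from(shave)


def postprocess(
    complexes: list[list],
    graph: nx.Graph,
    params: MCODEParams = MCODEParams(),
) -> list[Community]:
    """Filter, trim and score raw complexes into final communities.

    A complex is discarded unless its induced subgraph contains a
    ``params.k_core``-core.  Haircut iteratively removes degree-1 vertices
    of the complex subgraph; fluff (off by default) adds boundary vertices
    whose closed-neighbourhood density exceeds ``fluff_cutoff`` (fluffed
    vertices may be shared between complexes).  The complex score is
    ``density * size`` of the final subgraph and communities are renumbered
    from 1 in decreasing score.
    """
    graph = _strip_loops(graph, params)
    results = []
    for members in complexes:
        seed = members[0] if members else None
        sub = graph.subgraph(members)
        if params.k_core > 0 and len(nx.k_core(sub, params.k_core)) == 0:
            continue
        if params.haircut:
            sub = _haircut(sub)
        final = set(sub.nodes)
        if params.fluff:
            boundary = set()
            for v in final:
                boundary.update(graph.neighbors(v))
            for v in sorted(boundary - final, key=str):
                closed = graph.subgraph([v, *graph.neighbors(v)])
                if nx.density(closed) > params.fluff_cutoff:
                    final.add(v)
        if len(final) < 2:
            continue
        fsub = graph.subgraph(final)
        score = nx.density(fsub) * len(final)
        results.append((score, sorted(final, key=str), seed))
    results.sort(key=lambda t: (-t[0], [str(m) for m in t[1]]))
    return [
        Community(id=i, members=frozenset(members), complex_score=score, seed=seed)
        for i, (score, members, seed) in enumerate(results, start=1)
    ]


def detect_communities(graph: nx.Graph,
                       params: MCODEParams = MCODEParams()) -> list[Community]:
    """Full MCODE run: weight, predict, post-process."""
    weights = compute_weights(graph, params)
    raw = predict_complexes(graph, weights, params)
    return postprocess(raw, graph, params)


def membership(communities: list[Community]) -> dict:
    """gene → community id map (fluffed overlaps resolve to the best score)."""
    out: dict = {}
    for c in sorted(communities, key=lambda c: c.id, reverse=True):
        for g in c.members:
            out[g] = c.id
    return out
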