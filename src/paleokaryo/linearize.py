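"""Greedy linearization of the weighted adjacency graph into CARs.

Edges are examined in deterministic order (weight descending, then
lexicographic canonical edge key).  Every oriented adjacency occupies one
"side" of each endpoint gene: reading the adjacency (u, su, v, sv) left to
right, it leaves u through its downstream end if su = +1 (upstream end if
su = -1) and enters v through its upstream end if sv = +1.  A valid oriented
simple path uses each side of each gene at most once, so an edge is accepted
iff the side it needs is free at both endpoints and it does not close a cycle
(union-find).  Rejecting an edge whose side is taken is exactly "drop the
lower-weight conflicting adjacency, keep both fragments": the occupying edge
has higher weight (or equal weight and a smaller key).

Accepted edges decompose into simple paths; each path is emitted as a CAR
whose gene strands are propagated from the orientation signatures, written
starting from the lexicographically smaller path end.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

from networkx.utils import UnionFind

from .adjacency import Adjacency, AdjacencyGraph
from .model import CAR, InvariantError


def sorted_edges(graph: AdjacencyGraph) -> List[Tuple[Adjacency, int]]:
    return sorted(graph.edges.items(), key=lambda kv: (-kv[1], kv[0]))


def linearize_graph(
    graph: AdjacencyGraph, node: str = "", id_prefix: str = "car"
) -> Tuple[List[CAR], Set[str]]:
    """Greedy top-down linearization; returns (CARs, singleton genes)."""
    uf = UnionFind()
    side_used: Set[Tuple[str, int]] = set()
    accepted: List[Adjacency] = []
    for (u, su, v, sv), _w in sorted_edges(graph):
        out_side = (u, su)   # u is left through this end
        in_side = (v, -sv)   # v is entered through this end
        if out_side in side_used or in_side in side_used:
            continue  # orientation conflict with a stronger adjacency
        if uf[u] == uf[v]:
            continue  # would close a cycle
        uf.union(u, v)
        side_used.add(out_side)
        side_used.add(in_side)
        accepted.append((u, su, v, sv))

    # Build the neighbor structure of accepted edges.
    neighbors: Dict[str, List[Adjacency]] = {}
    for adj in accepted:
        u, _, v, _ = adj
        neighbors.setdefault(u, []).append(adj)
        neighbors.setdefault(v, []).append(adj)

    paths = _extract_paths(neighbors)
    cars = []
    for i, genes in enumerate(paths):
        cars.append(CAR(f"{id_prefix}{i + 1:05d}", node, genes))
    placed = {g for car in cars for g in car.gene_ids()}
    singletons = set(graph.nodes) - placed
    return cars, singletons


def _traverse(adj: Adjacency, from_gene: str) -> Tuple[str, int, int]:
    """Cross ``adj`` starting at ``from_gene``.

    Returns (other_gene, strand_of_from_gene, strand_of_other) in traversal
    direction.
    """
    u, su, v, sv = adj
    if from_gene == u:
        return v, su, sv
    if from_gene == v:
        return u, -sv, -su
    raise InvariantError("edge does not touch gene")  # pragma: no cover


def _extract_paths(neighbors: Dict[str, List[Adjacency]]) -> List[List[Tuple[str, int]]]:
    """Decompose accepted edges into oriented gene paths.

    Each component is a simple path (degree <= 2, acyclic by construction).
    The walk starts at the lexicographically smaller endpoint, which fixes
    the emitted orientation deterministically.
    """
    endpoints = sorted(g for g, es in neighbors.items() if len(es) == 1)
    for g, es in neighbors.items():
        if len(es) > 2:  # pragma: no cover - guarded by acceptance rule
            raise InvariantError(f"gene {g!r} has degree > 2 after linearization")
    visited_edges: Set[Adjacency] = set()
    done_genes: Set[str] = set()
    paths: List[List[Tuple[str, int]]] = []
    for start in endpoints:
        if start in done_genes:
            continue
        genes: List[Tuple[str, int]] = []
        current = start
        prev_edge = None
        strand_of_current = None
        while True:
            done_genes.add(current)
            nxt = None
            for adj in neighbors[current]:
                if adj is not prev_edge and adj not in visited_edges:
                    nxt = adj
                    break
            if nxt is None:
                if strand_of_current is not None:
                    genes.append((current, strand_of_current))
                break
            visited_edges.add(nxt)
            other, s_cur, s_other = _traverse(nxt, current)
            if strand_of_current is not None and strand_of_current != s_cur:
                # Cannot happen: the side-occupancy acceptance rule forbids
                # contradictory signatures along a path.
                raise InvariantError(
                    f"orientation contradiction at gene {current!r}"
                )  # pragma: no cover
            genes.append((current, s_cur))
            current = other
            strand_of_current = s_other
            prev_edge = nxt
        if len(genes) >= 2:
            paths.append(genes)
    # Deterministic CAR order: longest first, then by leading gene id.
    paths.sort(key=lambda p: (-len(p), p[0][0]))
    return paths


def normalize_car(car: CAR) -> CAR:
    """Orient a CAR so its first gene id is the lexicographically smaller end."""
    if car.genes and car.genes[-1][0] < car.genes[0][0]:
        return car.reversed()
    return car
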