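"""Independent reference implementations used as test oracles.

These deliberately avoid the package's incremental data structures: the
greedy reference re-checks feasibility declaratively after every candidate
edge, Dollo presence is found by exhaustive enumeration over presence sets,
and the exact path cover enumerates all edge subsets.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

Adjacency = Tuple[str, int, str, int]


# --------------------------------------------------------------------------
# Oriented-path feasibility (declarative)
# --------------------------------------------------------------------------

def orientation_consistent(edges: Sequence[Adjacency]) -> bool:
    """Can each component be laid out as one oriented gene run?

    Assumes the edges already form simple paths (degree <= 2, acyclic).  A
    component is realizable iff, reading its node sequence in one of the two
    directions, every edge (u, su, v, sv) appears as a consecutive pair with
    matching strands: traversing u -> v imposes (f(u), f(v)) = (su, sv) and
    traversing v -> u imposes (f(v), f(u)) = (-sv, -su).  Both directions of
    every path are tried explicitly.
    """
    neighbors: Dict[str, List[Adjacency]] = {}
    for adj in edges:
        u, _, v, _ = adj
        neighbors.setdefault(u, []).append(adj)
        neighbors.setdefault(v, []).append(adj)

    def node_sequence(start: str) -> List[str]:
        seq = [start]
        prev = None
        while True:
            nxt = None
            for (u, _su, v, _sv) in neighbors[seq[-1]]:
                other = v if u == seq[-1] else u
                if other != prev:
                    nxt = other
                    break
            if nxt is None:
                return seq
            prev = seq[-1]
            seq.append(nxt)

    def realizable(seq: List[str]) -> bool:
        strand: Dict[str, int] = {}
        for a, b in zip(seq, seq[1:]):
            edge = None
            for (u, su, v, sv) in neighbors[a]:
                if {u, v} == {a, b}:
                    edge = (u, su, v, sv)
                    break
            u, su, v, sv = edge
            fa, fb = (su, sv) if u == a else (-sv, -su)
            if strand.setdefault(a, fa) != fa or strand.setdefault(b, fb) != fb:
                return False
        return True

    seen: Set[str] = set()
    endpoints = sorted(g for g, es in neighbors.items() if len(es) == 1)
    for start in endpoints:
        if start in seen:
            continue
        seq = node_sequence(start)
        seen.update(seq)
        if not (realizable(seq) or realizable(list(reversed(seq)))):
            return False
    return True


def is_path_union(edges: Sequence[Adjacency]) -> bool:
    """Do the edges form vertex-disjoint simple, consistently oriented paths?"""
    degree: Dict[str, int] = {}
    used_sides: Set[Tuple[str, int]] = set()
    for (u, su, v, sv) in edges:
        degree[u] = degree.get(u, 0) + 1
        degree[v] = degree.get(v, 0) + 1
        if degree[u] > 2 or degree[v] > 2:
            return False
    # acyclicity by union-find over plain pairs
    parent: Dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (u, _, v, _) in edges:
        ru, rv = find(u), find(v)
        if ru == rv:
            return False
        parent[ru] = rv
    return orientation_consistent(edges)


# --------------------------------------------------------------------------
# Reference greedy linearization
# --------------------------------------------------------------------------

def reference_greedy(edges: Dict[Adjacency, int]) -> List[Adjacency]:
    """Accept edges in (weight desc, canonical key) order whenever the
    accepted set remains a union of consistently oriented simple paths."""
    accepted: List[Adjacency] = []
    for adj, _w in sorted(edges.items(), key=lambda kv: (-kv[1], kv[0])):
        if is_path_union(accepted + [adj]):
            accepted.append(adj)
    return accepted


# --------------------------------------------------------------------------
# Exact maximum-weight path cover (exhaustive over edge subsets)
# --------------------------------------------------------------------------

def exact_max_path_cover_weight(edges: Dict[Adjacency, int]) -> int:
    items = list(edges.items())
    best = 0
    for r in range(len(items), 0, -1):
        for combo in combinations(items, r):
            subset = [adj for adj, _ in combo]
            weight = sum(w for _, w in combo)
            if weight > best and is_path_union(subset):
                best = weight
    return best


# --------------------------------------------------------------------------
# Exhaustive Dollo presence
# --------------------------------------------------------------------------

def exhaustive_dollo(tree, observed: Set[str]) -> List[Set]:
    """All minimal-loss single-origin presence assignments, by enumeration.

    ``tree`` is a paleokaryo SpeciesTree; returns the list of node-object
    sets achieving the minimal loss count (losses = present->absent edges)
    among assignments whose present set is connected (single origin) and
    whose present leaves are exactly ``observed``.
    """
    nodes = list(tree.postorder())
    best_loss = None
    best: List[Set] = []
    n = len(nodes)
    for mask in range(1, 1 << n):
        present = {nodes[i] for i in range(n) if mask >> i & 1}
        leaves = {x.name for x in present if x.is_leaf}
        if leaves != observed:
            continue
        # connectivity: exactly one present node has an absent/missing parent
        roots = [x for x in present if x.parent is None or x.parent not in present]
        if len(roots) != 1:
            continue
        losses = sum(
            1 for x in present for c in x.children if c not in present
        )
        if best_loss is None or losses < best_loss:
            best_loss = losses
            best = [present]
        elif losses == best_loss:
            best.append(present)
    return best
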