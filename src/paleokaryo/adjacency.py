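"""Conserved oriented gene adjacencies and the weighted adjacency graph.

An oriented adjacency (u, su, v, sv) means "gene u with strand su is
immediately followed by gene v with strand sv".  Reading the same pair from
the other DNA strand gives (v, -sv, u, -su); the two forms are equivalent and
are stored canonically as the lexicographically smaller tuple.  Adjacencies
are only formed within chromosomes; chromosome ends contribute none.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

from .content import AncestralGeneSet
from .model import Genome, InputError, SpeciesTree, TreeNode

Adjacency = Tuple[str, int, str, int]


def canonical_adjacency(u: str, su: int, v: str, sv: int) -> Adjacency:
    a = (u, su, v, sv)
    b = (v, -sv, u, -su)
    return a if a <= b else b


def informative_pairs(tree: SpeciesTree, node_name: str) -> List[Tuple[str, str]]:
    """Leaf pairs whose tree path crosses ``node_name``.

    These are the genome pairs whose gene-order comparison is informative for
    the ancestor: leaves drawn from two distinct children of the node, or a
    descendant leaf paired with a non-descendant leaf.
    """
    node = tree.node(node_name)
    if node.is_leaf:
        raise InputError(f"{node_name!r} is a leaf; informative pairs need an ancestor")
    child_groups = [sorted(tree.leaves_under(c)) for c in node.children]
    below = sorted(tree.leaves_under(node))
    outside = sorted(set(tree.leaf_names) - set(below))
    pairs: Set[Tuple[str, str]] = set()
    for i in range(len(child_groups)):
        for j in range(i + 1, len(child_groups)):
            for a in child_groups[i]:
                for b in child_groups[j]:
                    pairs.add(tuple(sorted((a, b))))
    for a in below:
        for b in outside:
            pairs.add(tuple(sorted((a, b))))
    return sorted(pairs)


@dataclass
class ReducedGenome:
    """A genome filtered to the gene content of one ancestor.

    Extant genes are mapped to ancestral gene ids through the content set's
    descendant map; unmapped genes are dropped, relative order and strand are
    inherited.  One ancestral gene may occur several times (paleopolyploids,
    tandem arrays).
    """

    species: str
    chromosomes: Dict[str, List[Tuple[str, int]]]

    @property
    def n_occurrences(self) -> int:
        return sum(len(v) for v in self.chromosomes.values())


def reduce_to_ancestral(genome: Genome, content: AncestralGeneSet) -> ReducedGenome:
    mapping = content.extant_to_ancestral(genome.species)
    chromosomes: Dict[str, List[Tuple[str, int]]] = {}
    for chrom, genes in genome.chromosomes.items():
        reduced = [
            (mapping[g.gene_id], g.strand) for g in genes if g.gene_id in mapping
        ]
        if reduced:
            chromosomes[chrom] = reduced
    out = ReducedGenome(genome.species, chromosomes)
    if not chromosomes:
        import logging

        logging.getLogger(__name__).warning(
            "genome %s shares no gene content with ancestor %s",
            genome.species,
            content.node,
        )
    return out


def _adjacency_set(rg: ReducedGenome) -> Set[Adjacency]:
    out: Set[Adjacency] = set()
    for genes in rg.chromosomes.values():
        for (u, su), (v, sv) in zip(genes, genes[1:]):
            out.add(canonical_adjacency(u, su, v, sv))
    return out


def conserved_adjacencies(ga: ReducedGenome, gb: ReducedGenome) -> Set[Adjacency]:
    """Oriented adjacencies present in both reduced genomes.

    An adjacency counts once per genome pair regardless of how many copy
    pairs exhibit it: edge weights measure phylogenetic support, not copy
    number.
    """
    return _adjacency_set(ga) & _adjacency_set(gb)


@dataclass
class AdjacencyGraph:
    """Weighted graph of oriented ancestral adjacencies.

    ``edges`` maps a canonical oriented adjacency to the number of informative
    genome pairs supporting it.  Self-adjacencies (tandem copies of one
    ancestral gene) are not stored: they cannot take part in a simple path.
    """

    nodes: Set[str] = field(default_factory=set)
    edges: Dict[Adjacency, int] = field(default_factory=dict)
    n_pairs: int = 0

    def add_support(self, adj: Adjacency) -> None:
        u, su, v, sv = adj
        if u == v:
            return
        self.nodes.add(u)
        self.nodes.add(v)
        self.edges[adj] = self.edges.get(adj, 0) + 1

    @property
    def max_weight(self) -> int:
        return max(self.edges.values(), default=0)


def build_adjacency_graph(
    tree: SpeciesTree,
    node_name: str,
    genomes: Dict[str, Genome],
    content: AncestralGeneSet,
) -> AdjacencyGraph:
    """Accumulate conserved adjacencies over all loaded informative pairs."""
    pairs = [
        (a, b)
        for a, b in informative_pairs(tree, node_name)
        if a in genomes and b in genomes
    ]
    reductions: Dict[str, ReducedGenome] = {}
    for sp in {s for p in pairs for s in p}:
        reductions[sp] = reduce_to_ancestral(genomes[sp], content)
    graph = AdjacencyGraph(nodes=set(content.genes), n_pairs=len(pairs))
    for a, b in pairs:
        for adj in conserved_adjacencies(reductions[a], reductions[b]):
            graph.add_support(adj)
    return graph
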