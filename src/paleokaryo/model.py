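"""Domain types for ancestral karyotype reconstruction.

Gene order is represented by integer rank within a chromosome, not by base
pairs: all downstream algorithms operate purely on gene adjacency.  Base-pair
coordinates are carried through readers and writers but never consulted.
Internal coordinates are 0-based; file formats emit 1-based ranks.
Strand is stored as +1 / -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

import dendropy


class InputError(ValueError):
    """Invalid user input (malformed file, unknown species/ancestor, ...)."""


class InvariantError(RuntimeError):
    """A structural invariant of a domain object was violated."""


# --------------------------------------------------------------------------
# Genes and genomes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    """One gene copy in one extant genome.

    ``rank`` is the 0-based index of the gene in its chromosome's gene order.
    ``strand`` is +1 (forward) or -1 (reverse).
    """

    gene_id: str
    family_id: str
    chromosome: str
    rank: int
    strand: int
    start_bp: Optional[int] = None
    end_bp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in (1, -1):
            raise InvariantError(
                f"gene {self.gene_id!r}: strand must be +1 or -1, got {self.strand!r}"
            )
        if (
            self.start_bp is not None
            and self.end_bp is not None
            and self.start_bp > self.end_bp
        ):
            raise InvariantError(f"gene {self.gene_id!r}: start_bp > end_bp")


class Genome:
    """One species' chromosomes as ordered, oriented gene lists.

    ``centromeres`` maps a chromosome name to a gap index ``g`` meaning the
    centromere sits between the genes of rank ``g - 1`` and ``g`` (so ``g``
    genes lie on the left arm).
    """

    def __init__(
        self,
        species: str,
        chromosomes: Dict[str, List[Gene]],
        centromeres: Optional[Dict[str, int]] = None,
    ) -> None:
        self.species = species
        self.chromosomes = chromosomes
        self.centromeres = dict(centromeres or {})
        self._by_id: Dict[str, Gene] = {}
        self._validate()

    def _validate(self) -> None:
        seen: Set[str] = set()
        for chrom, genes in self.chromosomes.items():
            if not genes:
                raise InvariantError(
                    f"genome {self.species!r}: chromosome {chrom!r} is empty"
                )
            for i, g in enumerate(genes):
                if g.rank != i:
                    raise InvariantError(
                        f"genome {self.species!r}: chromosome {chrom!r} ranks are "
                        f"not gapless 0..n-1 (gene {g.gene_id!r} at index {i} has "
                        f"rank {g.rank})"
                    )
                if g.chromosome != chrom:
                    raise InvariantError(
                        f"gene {g.gene_id!r} carries chromosome {g.chromosome!r} "
                        f"but is stored under {chrom!r}"
                    )
                if g.gene_id in seen:
                    raise InputError(
                        f"duplicate gene_id {g.gene_id!r} in genome {self.species!r}"
                    )
                seen.add(g.gene_id)
                self._by_id[g.gene_id] = g

    def gene(self, gene_id: str) -> Gene:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise InputError(
                f"unknown gene {gene_id!r} in genome {self.species!r}"
            ) from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __iter__(self) -> Iterator[Gene]:
        for chrom in self.chromosomes:
            yield from self.chromosomes[chrom]

    @property
    def n_genes(self) -> int:
        return len(self._by_id)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def gene_ids(self) -> Set[str]:
        return set(self._by_id)


class GeneFamilies:
    """family_id -> {species -> list of gene_ids}."""

    def __init__(self, members: Dict[str, Dict[str, List[str]]]) -> None:
        for fam, per_species in members.items():
            if not any(per_species.values()):
                raise InvariantError(f"family {fam!r} is empty")
        self.members = members
        self._gene_to_family: Dict[Tuple[str, str], str] = {}
        for fam, per_species in members.items():
            for sp, gids in per_species.items():
                for gid in gids:
                    key = (sp, gid)
                    if key in self._gene_to_family:
                        raise InvariantError(
                            f"gene {gid!r} of species {sp!r} occurs in more than "
                            f"one family"
                        )
                    self._gene_to_family[key] = fam

    def family_of(self, species: str, gene_id: str) -> Optional[str]:
        return self._gene_to_family.get((species, gene_id))

    def species_with_members(self, family_id: str) -> Set[str]:
        return {sp for sp, gids in self.members[family_id].items() if gids}

    def __iter__(self) -> Iterator[str]:
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def check_cover(self, genome: Genome) -> None:
        """Every gene of the genome must occur in exactly one family."""
        for g in genome:
            if self.family_of(genome.species, g.gene_id) is None:
                raise InvariantError(
                    f"gene {g.gene_id!r} of {genome.species!r} is in no family"
                )


# --------------------------------------------------------------------------
# Species tree
# --------------------------------------------------------------------------

class TreeNode:
    __slots__ = ("name", "length", "parent", "children")

    def __init__(self, name: Optional[str], length: Optional[float]) -> None:
        self.name = name
        self.length = length  # length of the branch above this node, in my
        self.parent: Optional["TreeNode"] = None
        self.children: List["TreeNode"] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        return f"TreeNode({self.name!r})"


class SpeciesTree:
    """Rooted species tree; named internal nodes are reconstruction targets."""

    def __init__(self, root: TreeNode) -> None:
        self.root = root
        self._by_name: Dict[str, TreeNode] = {}
        for node in self.postorder():
            if node.name is not None:
                if node.name in self._by_name:
                    raise InputError(f"duplicate node label {node.name!r} in tree")
                self._by_name[node.name] = node

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )

        def convert(dnode) -> TreeNode:
            if dnode.taxon is not None:
                name = dnode.taxon.label
            else:
                name = dnode.label
            node = TreeNode(name, dnode.edge.length)
            for child in dnode.child_nodes():
                cnode = convert(child)
                cnode.parent = node
                node.children.append(cnode)
            return node

        return cls(convert(dtree.seed_node))

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")" + (node.name or "")
            if node.length is not None:
                s += f":{node.length:g}"
            return s

        return fmt(self.root) + ";"

    # -- traversal and queries --------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        def walk(node: TreeNode) -> Iterator[TreeNode]:
            for c in node.children:
                yield from walk(c)
            yield node

        return walk(self.root)

    def preorder(self) -> Iterator[TreeNode]:
        def walk(node: TreeNode) -> Iterator[TreeNode]:
            yield node
            for c in node.children:
                yield from walk(c)

        return walk(self.root)

    def branches(self) -> Iterator[Tuple[TreeNode, TreeNode]]:
        """(parent, child) pairs in preorder."""
        for node in self.preorder():
            for child in node.children:
                yield node, child

    def node(self, name: str) -> TreeNode:
        try:
            return self._by_name[name]
        except KeyError:
            raise InputError(f"unknown ancestor {name!r}") from None

    @property
    def leaf_names(self) -> List[str]:
        return [n.name for n in self.postorder() if n.is_leaf]

    @property
    def internal_names(self) -> List[str]:
        return [
            n.name for n in self.postorder() if not n.is_leaf and n.name is not None
        ]

    def leaves_under(self, node: TreeNode) -> List[str]:
        def walk(n: TreeNode) -> Iterator[str]:
            if n.is_leaf:
                yield n.name
            for c in n.children:
                yield from walk(c)

        return list(walk(node))

    def mrca(self, leaf_names: Sequence[str]) -> TreeNode:
        if not leaf_names:
            raise InputError("mrca of an empty leaf set")
        paths = []
        for name in leaf_names:
            node = self.node(name)
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(list(reversed(path)))
        mrca = paths[0][0]
        for depth in range(min(len(p) for p in paths)):
            candidates = {id(p[depth]) for p in paths}
            if len(candidates) == 1:
                mrca = paths[0][depth]
            else:
                break
        return mrca

    def depth_of(self, node: TreeNode) -> float:
        """Sum of branch lengths from the root to ``node``."""
        total = 0.0
        while node.parent is not None:
            total += node.length or 0.0
            node = node.parent
        return total


# --------------------------------------------------------------------------
# CARs and ancestral karyotypes
# --------------------------------------------------------------------------

@dataclass
class CAR:
    """Contiguous ancestral region: an ordered, oriented run of ancestral genes."""

    car_id: str
    node: str
    genes: List[Tuple[str, int]]  # (ancestral_gene_id, strand)

    def __len__(self) -> int:
        return len(self.genes)

    def gene_ids(self) -> List[str]:
        return [g for g, _ in self.genes]

    def reversed(self) -> "CAR":
        return CAR(
            self.car_id,
            self.node,
            [(g, -s) for g, s in reversed(self.genes)],
        )

    def oriented(self, orientation: int) -> List[Tuple[str, int]]:
        if orientation == 1:
            return list(self.genes)
        return [(g, -s) for g, s in reversed(self.genes)]


@dataclass
class Protochromosome:
    """A scaffolded ancestral chromosome: an ordered, oriented list of CARs."""

    pc_id: str
    node: str
    cars: List[Tuple[CAR, int]]  # (car, orientation in the scaffold)

    def genes(self) -> List[Tuple[str, int]]:
        out: List[Tuple[str, int]] = []
        for car, orientation in self.cars:
            out.extend(car.oriented(orientation))
        return out

    def gene_ids(self) -> List[str]:
        return [g for g, _ in self.genes()]


@dataclass
class AncestralKaryotype:
    """Reconstruction result at one ancestor.

    ``ordered_protogenes`` are genes placed in protochromosomes; the total
    protogene set additionally contains small-CAR genes and singletons.  The
    three compartments are pairwise disjoint and together cover the ancestral
    gene content.
    """

    node: str
    protochromosomes: List[Protochromosome]
    small_cars: List[CAR]
    singletons: Set[str]

    @property
    def ordered_protogenes(self) -> Set[str]:
        out: Set[str] = set()
        for pc in self.protochromosomes:
            out.update(pc.gene_ids())
        return out

    @property
    def total_protogenes(self) -> Set[str]:
        out = self.ordered_protogenes
        for car in self.small_cars:
            out.update(car.gene_ids())
        out.update(self.singletons)
        return out

    def validate_partition(self) -> None:
        ordered = self.ordered_protogenes
        small: Set[str] = set()
        for car in self.small_cars:
            small.update(car.gene_ids())
        if ordered & small or ordered & self.singletons or small & self.singletons:
            raise InvariantError(
                f"karyotype {self.node!r}: protochromosome / small-CAR / singleton "
                f"compartments overlap"
            )


# --------------------------------------------------------------------------
# Interaction network
# --------------------------------------------------------------------------

class InteractionNetwork:
    """Undirected gene-gene interaction edges of one species."""

    def __init__(self, edges: Iterable[Tuple[str, str]]) -> None:
        import networkx as nx

        self.graph = nx.Graph()
        for a, b in edges:
            if a == b:
                continue  # self-loops carry no connectivity information
            self.graph.add_edge(a, b)

    def degree(self, gene_id: str) -> int:
        if gene_id not in self.graph:
            return 0
        return self.graph.degree[gene_id]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()
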