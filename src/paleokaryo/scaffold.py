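"""Second-round (contig-order) linearization and karyotype scaffolding.

After gene-level linearization, each informative genome is rewritten as a
sequence of oriented contig tokens (gene -> its CAR; genes outside all CARs
dropped; maximal runs of one CAR collapsed to a single token whose
orientation is the majority direction of the member genes' CAR positions,
ties resolved as forward).  Conserved contig adjacencies are accumulated over
the same informative pairs and linearized with the same greedy rule; accepted
contig chains are spliced into longer gene-level CARs.

Scaffolding then groups large CARs into protochromosomes by majority
chromosome profile across the reference descendants and orders them along a
guide genome.  This automates what is classically a manual super-scaffolding
step; reproducibility requires an algorithm, so the guide genome defaults to
the least-rearranged descendant (fewest contig runs) and is configurable.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from statistics import median
from typing import Dict, List, Optional, Sequence, Set, Tuple

from networkx.utils import UnionFind

from .adjacency import (
    AdjacencyGraph,
    ReducedGenome,
    build_adjacency_graph,
    conserved_adjacencies,
    informative_pairs,
    reduce_to_ancestral,
)
from .content import AncestralGeneSet, ancestral_gene_set
from .linearize import linearize_graph, normalize_car
from .model import (
    CAR,
    AncestralKaryotype,
    GeneFamilies,
    Genome,
    Protochromosome,
    SpeciesTree,
)

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Contig round
# --------------------------------------------------------------------------

def _car_index(cars: Sequence[CAR]) -> Dict[str, Tuple[str, int]]:
    index: Dict[str, Tuple[str, int]] = {}
    for car in cars:
        for pos, (gene, _strand) in enumerate(car.genes):
            index[gene] = (car.car_id, pos)
    return index


def _tokenize(
    rg: ReducedGenome, index: Dict[str, Tuple[str, int]]
) -> ReducedGenome:
    """Rewrite a reduced genome as oriented contig tokens."""
    chromosomes: Dict[str, List[Tuple[str, int]]] = {}
    for chrom, genes in rg.chromosomes.items():
        mapped = [
            (index[g][0], index[g][1]) for g, _s in genes if g in index
        ]
        tokens: List[Tuple[str, int]] = []
        i = 0
        while i < len(mapped):
            j = i
            while j + 1 < len(mapped) and mapped[j + 1][0] == mapped[i][0]:
                j += 1
            positions = [mapped[k][1] for k in range(i, j + 1)]
            votes = 0
            for a, b in zip(positions, positions[1:]):
                if b > a:
                    votes += 1
                elif b < a:
                    votes -= 1
            orient = -1 if votes < 0 else 1  # ties -> forward
            tokens.append((mapped[i][0], orient))
            i = j + 1
        if tokens:
            chromosomes[chrom] = tokens
    return ReducedGenome(rg.species, chromosomes)


def contig_round(
    cars: Sequence[CAR],
    tree: SpeciesTree,
    node_name: str,
    genomes: Dict[str, Genome],
    content: AncestralGeneSet,
    id_prefix: str = "car",
) -> List[CAR]:
    """Splice CARs that are adjacent, in conserved orientation, across pairs."""
    index = _car_index(cars)
    by_id = {car.car_id: car for car in cars}
    pairs = [
        (a, b)
        for a, b in informative_pairs(tree, node_name)
        if a in genomes and b in genomes
    ]
    tokenized: Dict[str, ReducedGenome] = {}
    for sp in {s for p in pairs for s in p}:
        tokenized[sp] = _tokenize(reduce_to_ancestral(genomes[sp], content), index)
    graph = AdjacencyGraph(nodes=set(by_id), n_pairs=len(pairs))
    for a, b in pairs:
        for adj in conserved_adjacencies(tokenized[a], tokenized[b]):
            graph.add_support(adj)

    chains, lone = linearize_graph(graph, node=node_name, id_prefix="chain")
    spliced: List[CAR] = []
    for chain in chains:
        genes: List[Tuple[str, int]] = []
        for car_id, orient in chain.genes:
            genes.extend(by_id[car_id].oriented(orient))
        spliced.append(normalize_car(CAR("tmp", node_name, genes)))
    for car_id in sorted(lone):
        spliced.append(normalize_car(by_id[car_id]))

    spliced.sort(key=lambda c: (-len(c), c.genes[0][0] if c.genes else ""))
    return [
        CAR(f"{id_prefix}{i + 1:05d}", node_name, car.genes)
        for i, car in enumerate(spliced)
    ]


# --------------------------------------------------------------------------
# Scaffolding into protochromosomes
# --------------------------------------------------------------------------

def _descendant_positions(
    car: CAR, species: str, content: AncestralGeneSet, genome: Genome
) -> List[Tuple[int, str, int]]:
    """(position_in_car, extant_chromosome, extant_rank) for each descendant."""
    out = []
    for pos, (anc, _s) in enumerate(car.genes):
        for gid in content.descendant_map.get(anc, {}).get(species, ()):
            if gid in genome:
                g = genome.gene(gid)
                out.append((pos, g.chromosome, g.rank))
    return out


def _majority_chromosome(
    positions: Sequence[Tuple[int, str, int]]
) -> Optional[str]:
    if not positions:
        return None
    counts = Counter(chrom for _p, chrom, _r in positions)
    best = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    # Deterministic tie-break: highest count, then lexicographically last name
    # would be arbitrary; prefer smallest name among maxima.
    top = max(counts.values())
    return min(c for c, n in counts.items() if n == top)


def _count_runs(rg: ReducedGenome, index: Dict[str, Tuple[str, int]]) -> int:
    tokens = _tokenize(rg, index)
    return sum(len(v) for v in tokens.chromosomes.values())


def scaffold_karyotype(
    cars: Sequence[CAR],
    genomes: Dict[str, Genome],
    tree: SpeciesTree,
    node_name: str,
    content: AncestralGeneSet,
    min_size: int = 50,
    guide: Optional[str] = None,
) -> AncestralKaryotype:
    """Group CARs of >= ``min_size`` genes into protochromosomes.

    CARs are grouped when their majority-chromosome profiles agree in a
    majority of the reference descendants, then ordered and oriented by
    median descendant rank in the guide genome.  Smaller CARs and genes in no
    CAR form the non-ordered protogene set.
    """
    large = [car for car in cars if len(car) >= min_size]
    small = [car for car in cars if len(car) < min_size]
    refs = sorted(sp for sp in tree.leaves_under(tree.node(node_name)) if sp in genomes)

    placed_genes: Set[str] = set()
    for car in cars:
        placed_genes.update(car.gene_ids())
    singletons = set(content.genes) - placed_genes

    if not large:
        return AncestralKaryotype(node_name, [], list(small), singletons)

    positions: Dict[Tuple[str, str], List[Tuple[int, str, int]]] = {}
    profiles: Dict[str, Dict[str, Optional[str]]] = {}
    for car in large:
        profiles[car.car_id] = {}
        for sp in refs:
            pos = _descendant_positions(car, sp, content, genomes[sp])
            positions[(car.car_id, sp)] = pos
            profiles[car.car_id][sp] = _majority_chromosome(pos)

    if not refs:
        logger.warning(
            "node %s: no reference genome resolvable; each large CAR becomes "
            "its own protochromosome",
            node_name,
        )
        groups = [[car] for car in large]
    else:
        uf = UnionFind(car.car_id for car in large)
        ids = sorted(profiles)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                agree = sum(
                    1
                    for sp in refs
                    if profiles[a][sp] is not None and profiles[a][sp] == profiles[b][sp]
                )
                if agree > len(refs) / 2:
                    uf.union(a, b)
        by_id = {car.car_id: car for car in large}
        groups = [
            [by_id[cid] for cid in sorted(comp)] for comp in uf.to_sets()
        ]

    # Guide genome: least-rearranged descendant = fewest contig runs.
    if guide is None and refs:
        index = _car_index(large)
        run_counts = []
        for sp in refs:
            rg = reduce_to_ancestral(genomes[sp], content)
            run_counts.append((_count_runs(rg, index), sp))
        guide = min(run_counts)[1]

    def car_order_key(car: CAR) -> Tuple:
        if guide is None:
            return ("", 0.0, car.car_id)
        pos = positions.get((car.car_id, guide), [])
        chrom = profiles.get(car.car_id, {}).get(guide)
        ranks = [r for _p, c, r in pos if c == chrom]
        med = median(ranks) if ranks else 0.0
        return (chrom or "", med, car.car_id)

    def car_orientation(car: CAR) -> int:
        if guide is None:
            return 1
        chrom = profiles.get(car.car_id, {}).get(guide)
        pos = [
            (p, r)
            for p, c, r in positions.get((car.car_id, guide), [])
            if c == chrom
        ]
        if len(pos) < 2:
            return 1
        pos.sort()
        first = pos[0][1]
        last = pos[-1][1]
        if last < first:
            return -1
        return 1  # ties -> forward

    ordered_groups = []
    for group in groups:
        members = sorted(group, key=car_order_key)
        ordered_groups.append([(car, car_orientation(car)) for car in members])
    ordered_groups.sort(
        key=lambda g: (-sum(len(car) for car, _o in g), g[0][0].car_id)
    )
    protochromosomes = [
        Protochromosome(f"{node_name}.pc{i + 1}", node_name, group)
        for i, group in enumerate(ordered_groups)
    ]
    karyotype = AncestralKaryotype(node_name, protochromosomes, list(small), singletons)
    karyotype.validate_partition()
    return karyotype


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------

def reconstruct_karyotype(
    tree: SpeciesTree,
    node_name: str,
    genomes: Dict[str, Genome],
    families: Optional[GeneFamilies] = None,
    content: Optional[AncestralGeneSet] = None,
    min_car_size: int = 50,
    guide: Optional[str] = None,
) -> Tuple[AncestralKaryotype, Dict[str, int]]:
    """Run the full reconstruction at one ancestor.

    Stages: ancestral gene content -> weighted adjacency graph -> greedy
    gene-level linearization -> contig-order round -> scaffolding.  Returns
    the karyotype and a per-stage count summary.
    """
    if content is None:
        if families is None:
            raise ValueError("either families or a precomputed content set is required")
        content = ancestral_gene_set(tree, families, node_name)
    graph = build_adjacency_graph(tree, node_name, genomes, content)
    cars1, _single1 = linearize_graph(graph, node=node_name, id_prefix="g")
    cars2 = contig_round(cars1, tree, node_name, genomes, content, id_prefix="car")
    karyotype = scaffold_karyotype(
        cars2, genomes, tree, node_name, content, min_size=min_car_size, guide=guide
    )
    summary = {
        "ancestral_genes": len(content.genes),
        "informative_pairs": graph.n_pairs,
        "graph_edges": len(graph.edges),
        "cars_round1": len(cars1),
        "cars_round2": len(cars2),
        "protochromosomes": len(karyotype.protochromosomes),
        "small_cars": len(karyotype.small_cars),
        "ordered_protogenes": len(karyotype.ordered_protogenes),
        "total_protogenes": len(karyotype.total_protogenes),
        "singletons": len(karyotype.singletons),
    }
    logger.info(
        "node %s: %d ordered / %d total protogenes in %d protochromosomes",
        node_name,
        summary["ordered_protogenes"],
        summary["total_protogenes"],
        summary["protochromosomes"],
    )
    return karyotype, summary
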