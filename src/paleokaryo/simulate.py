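"""Forward genome-evolution simulator along a species tree.

The simulator evolves an ancestral karyotype (by default eight chromosomes of
250 genes each, with mid-chromosome centromeres) down a dated species tree.
Structural events are drawn as Poisson processes per branch (count ~
Poisson(rate x branch length), placed uniformly in time) and applied in time
order: inversions (geometric length), reciprocal translocations, RTA fusions
(pericentric inversion + reciprocal translocation deleting the minor product
that carries one centromere), fissions (with a neo-centromere), gene gains
(half novel insertions, half tandem duplications) and gene losses.  One
branch may carry a two-step allohexaploidy: three subgenome copies are
created, MF1 and MF2 exchange chromosome tails (reciprocal recombination)
while they share a nucleus before LF joins, and each gene copy is then
deleted independently with its origin subgenome's fractionation
probability (LF < MF1 < MF2).

Every event is written to an event log with fully resolved parameters, so
replaying the log from the root genome reproduces every extant genome
exactly.  True ancestral karyotypes are snapshotted at each internal node,
and true ortholog maps are derived from the recorded gene parentage.

Codon sequences are optional: each root gene receives a random stop-free
sequence and substitutions accrue along branches at a configured per-site
rate (uniform nucleotide proposals, proposals creating stop codons
rejected).  Hexaploid copies diverge according to the configured progenitor
split offsets before merging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .model import (
    CAR,
    AncestralKaryotype,
    Gene,
    GeneFamilies,
    Genome,
    InputError,
    Protochromosome,
    SpeciesTree,
)

# Desk-scale Brassicaceae topology: Camelineae (At, Al, Cr) and Calepineae
# (Br, Tp) splitting from the Brassicaceae ancestor ABK, plus an outgroup.
DEFAULT_NEWICK = (
    "((((At:7,Al:7)A1:6,Cr:13)ACK:14,(Br:12,Tp:12)PCK:15)ABK:13,Out:40)ROOT;"
)

SUBGENOMES = ("LF", "MF1", "MF2")
_SENSE_CODONS = None


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass
class HexaploidySpec:
    """Two-step allohexaploidy on one branch.

    ``branch_fraction`` places the merge along the branch into
    ``branch_child``.  ``lf_split_my`` / ``mf_split_my`` are the progenitor
    divergence offsets before the merge (LF split first, then MF1/MF2), used
    by the sequence model.  ``loss_probs`` are the per-copy fractionation
    deletion probabilities for LF, MF1, MF2 (least to most fractionated).
    ``n_exchanges`` reciprocal MF1-MF2 tail exchanges are applied before
    fractionation, at least ``min_block_genes`` apart, emulating the large
    dominance/sensitivity exchange blocks seen in paleohexaploids.
    """

    branch_child: str = "Br"
    branch_fraction: float = 0.4
    lf_split_my: float = 6.0
    mf_split_my: float = 3.0
    loss_probs: Tuple[float, float, float] = (0.2, 0.45, 0.6)
    n_exchanges: int = 4
    min_block_genes: int = 100

    def __post_init__(self) -> None:
        lf, mf1, mf2 = self.loss_probs
        if not (0 <= lf <= mf1 <= mf2 < 1):
            raise InputError(
                f"fractionation probabilities must satisfy 0 <= LF <= MF1 <= MF2 < 1, "
                f"got {self.loss_probs}"
            )


@dataclass
class SequenceModel:
    n_codons: int = 100
    subs_per_site_per_my: float = 0.01


@dataclass
class SimulationConfig:
    seed: int
    newick: str = DEFAULT_NEWICK
    n_chromosomes: int = 8
    genes_per_chromosome: int = 250
    # Per-branch event rates, per million years (gain/loss are absolute
    # counts per my at the default 2000-gene root scale).
    inversion_rate: float = 1.0
    translocation_rate: float = 0.1
    fusion_rta_rate: float = 0.05
    fission_rate: float = 0.02
    gene_gain_rate: float = 20.0
    gene_loss_rate: float = 45.0
    inversion_geom_p: float = 0.2
    fusion_collateral_max: int = 2
    time_scale: float = 1.0
    hexaploidy: Optional[HexaploidySpec] = field(default_factory=HexaploidySpec)
    sequences: Optional[SequenceModel] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InputError("simulation seed is mandatory")
        for name in (
            "inversion_rate",
            "translocation_rate",
            "fusion_rta_rate",
            "fission_rate",
            "gene_gain_rate",
            "gene_loss_rate",
        ):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path, seed: Optional[int] = None) -> "SimulationConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        if seed is not None:
            data["seed"] = seed
        if "seed" not in data:
            raise InputError(f"{path}: simulation seed is mandatory")
        if "hexaploidy" in data and data["hexaploidy"] is not None:
            hx = data["hexaploidy"]
            if "loss_probs" in hx:
                hx["loss_probs"] = tuple(hx["loss_probs"])
            data["hexaploidy"] = HexaploidySpec(**hx)
        if data.get("sequences") is not None:
            data["sequences"] = SequenceModel(**data["sequences"])
        return cls(**data)


# --------------------------------------------------------------------------
# Mutable simulation genome
# --------------------------------------------------------------------------

@dataclass
class SimGene:
    gid: str
    family: str
    strand: int


class SimGenome:
    """Mutable genome state during simulation.

    ``centromeres[chrom]`` is a gap index: the number of genes on the left
    arm (the centromere sits between ranks ``c - 1`` and ``c``).
    """

    def __init__(self) -> None:
        self.chromosomes: Dict[str, List[SimGene]] = {}
        self.centromeres: Dict[str, int] = {}

    def clone(self) -> "SimGenome":
        g = SimGenome()
        g.chromosomes = {
            name: [SimGene(x.gid, x.family, x.strand) for x in genes]
            for name, genes in self.chromosomes.items()
        }
        g.centromeres = dict(self.centromeres)
        return g

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.chromosomes.values())

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def gene_ids(self) -> Set[str]:
        return {g.gid for genes in self.chromosomes.values() for g in genes}

    def locate(self, gid: str) -> Tuple[str, int]:
        for chrom, genes in self.chromosomes.items():
            for i, g in enumerate(genes):
                if g.gid == gid:
                    return chrom, i
        raise InputError(f"gene {gid!r} not in genome")


@dataclass
class EventRecord:
    branch_child: str
    time: float  # my from the start of the branch
    etype: str
    params: dict
    affected: Tuple[str, ...] = ()


@dataclass
class HexTruth:
    node_branch: str
    time: float  # my from the start of the branch
    copies: Dict[str, Dict[str, str]]  # pre-WGD gid -> {subgenome -> copy gid}
    labels: Dict[str, str]  # surviving copy gid -> origin subgenome (dominance label)
    breakpoints: List[Tuple[str, int]]  # (ancestral chromosome, gap index)
    lost: List[str]  # copy gids deleted by fractionation


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    tree: SpeciesTree
    root_genome: SimGenome
    genomes: Dict[str, Genome]
    families: GeneFamilies
    snapshots: Dict[str, SimGenome]  # named internal nodes
    events: List[EventRecord]
    parents: Dict[str, str]  # gid -> parent instance gid
    family_of_instance: Dict[str, str]
    hex_truth: Optional[HexTruth] = None
    sequences: Optional[Dict[str, str]] = None

    def true_karyotype(self, node: str, namespace: str = "instance") -> AncestralKaryotype:
        """The simulated truth at an internal node as a karyotype.

        ``namespace`` is "instance" (simulator gene ids) or "family"
        (``<family>@<node>`` ids comparable with reconstructions).
        """
        snap = self.snapshots[node]
        protochromosomes = []
        for chrom in snap.chromosomes:
            genes = []
            for g in snap.chromosomes[chrom]:
                gid = (
                    g.gid
                    if namespace == "instance"
                    else f"{g.family}@{node}"
                )
                genes.append((gid, g.strand))
            car = CAR(f"{node}.{chrom}", node, genes)
            protochromosomes.append(Protochromosome(f"{node}.{chrom}", node, [(car, 1)]))
        return AncestralKaryotype(node, protochromosomes, [], set())

    def ortholog_map(self, node: str, species: str) -> Dict[str, List[str]]:
        """True map ancestral instance gid -> descendant gene ids in one leaf."""
        snap_ids = self.snapshots[node].gene_ids()
        out: Dict[str, List[str]] = {}
        for g in self.genomes[species]:
            anc = _ancestor_in(g.gene_id, snap_ids, self.parents)
            if anc is not None:
                out.setdefault(anc, []).append(g.gene_id)
        return out

    def ortholog_map_all(self, node: str) -> Dict[str, Dict[str, List[str]]]:
        node_obj = self.tree.node(node)
        out: Dict[str, Dict[str, List[str]]] = {}
        for sp in self.tree.leaves_under(node_obj):
            if sp not in self.genomes:
                continue
            for anc, gids in self.ortholog_map(node, sp).items():
                out.setdefault(anc, {})[sp] = gids
        return out


def _ancestor_in(
    gid: str, snapshot_ids: Set[str], parents: Dict[str, str]
) -> Optional[str]:
    x: Optional[str] = gid
    while x is not None:
        if x in snapshot_ids:
            return x
        x = parents.get(x)
    return None


# --------------------------------------------------------------------------
# Event operators (pure, parameter-driven: used by simulate and by replay)
# --------------------------------------------------------------------------

def apply_inversion(genome: SimGenome, chrom: str, start: int, length: int) -> None:
    genes = genome.chromosomes[chrom]
    end = start + length
    if not (0 <= start < end <= len(genes)):
        raise InputError(f"inversion segment [{start},{end}) out of range on {chrom!r}")
    segment = [SimGene(g.gid, g.family, -g.strand) for g in reversed(genes[start:end])]
    genome.chromosomes[chrom] = genes[:start] + segment + genes[end:]
    cen = genome.centromeres.get(chrom)
    if cen is not None and start < cen < end:
        genome.centromeres[chrom] = start + (end - cen)


def apply_reciprocal_translocation(
    genome: SimGenome,
    chrom_a: str,
    pos_a: int,
    chrom_b: str,
    pos_b: int,
    side_left: bool,
) -> None:
    """Exchange the segments right of ``pos_a`` / ``pos_b``.

    Both breaks fall on the same side (``side_left``) of their centromeres so
    that the two products stay monocentric.
    """
    if chrom_a == chrom_b:
        raise InputError("reciprocal translocation needs two distinct chromosomes")
    ga = genome.chromosomes[chrom_a]
    gb = genome.chromosomes[chrom_b]
    cen_a = genome.centromeres[chrom_a]
    cen_b = genome.centromeres[chrom_b]
    if side_left and not (pos_a <= cen_a and pos_b <= cen_b):
        raise InputError("left-side translocation breaks beyond a centromere")
    if not side_left and not (pos_a >= cen_a and pos_b >= cen_b):
        raise InputError("right-side translocation breaks before a centromere")
    genome.chromosomes[chrom_a] = ga[:pos_a] + gb[pos_b:]
    genome.chromosomes[chrom_b] = gb[:pos_b] + ga[pos_a:]
    if side_left:  # centromeres travel with the exchanged right segments
        genome.centromeres[chrom_a] = pos_a + (cen_b - pos_b)
        genome.centromeres[chrom_b] = pos_b + (cen_a - pos_a)
    # else: centromeres stay on the retained left segments, indices unchanged


def apply_fusion_rta(
    genome: SimGenome, chrom_a: str, chrom_b: str, n_collateral: int
) -> List[str]:
    """Fuse two monocentric chromosomes, losing chromosome B's centromere.

    Stylized operator: a pericentric inversion mobilizes B's entire short arm
    and a reciprocal translocation joins A's end to the inverted arm; the
    minor product -- B's centromere plus ``n_collateral`` pericentric genes --
    is deleted.  Returns the lost gene ids.
    """
    if chrom_a == chrom_b:
        raise InputError("fusion requires two distinct chromosomes")
    if chrom_a not in genome.centromeres or chrom_b not in genome.centromeres:
        raise InputError("fusion requires centromeres on both chromosomes")
    gb = genome.chromosomes[chrom_b]
    cen_b = genome.centromeres[chrom_b]
    left, right = gb[:cen_b], gb[cen_b:]
    if len(left) > len(right):
        # Canonicalize so the short arm is the left arm (orientation flip).
        left, right = (
            [SimGene(g.gid, g.family, -g.strand) for g in reversed(right)],
            [SimGene(g.gid, g.family, -g.strand) for g in reversed(left)],
        )
    n_collateral = min(n_collateral, len(left))
    kept_short = left[: len(left) - n_collateral]
    lost = [g.gid for g in left[len(left) - n_collateral :]]
    inverted_short = [
        SimGene(g.gid, g.family, -g.strand) for g in reversed(kept_short)
    ]
    genome.chromosomes[chrom_a] = (
        genome.chromosomes[chrom_a] + inverted_short + right
    )
    del genome.chromosomes[chrom_b]
    del genome.centromeres[chrom_b]
    return lost


def apply_fission(genome: SimGenome, chrom: str, pos: int, new_name: str) -> None:
    genes = genome.chromosomes[chrom]
    if not (1 <= pos <= len(genes) - 1):
        raise InputError(f"fission position {pos} out of range on {chrom!r}")
    left, right = genes[:pos], genes[pos:]
    cen = genome.centromeres[chrom]
    genome.chromosomes[chrom] = left
    genome.chromosomes[new_name] = right
    if cen <= pos:
        genome.centromeres[chrom] = cen
        genome.centromeres[new_name] = max(1, len(right) // 2)  # neo-centromere
    else:
        genome.centromeres[chrom] = max(1, len(left) // 2)  # neo-centromere
        genome.centromeres[new_name] = cen - pos


def apply_gain_novel(
    genome: SimGenome, chrom: str, pos: int, gid: str, family: str, strand: int
) -> None:
    genes = genome.chromosomes[chrom]
    genes.insert(pos, SimGene(gid, family, strand))
    cen = genome.centromeres.get(chrom)
    if cen is not None and pos < cen:
        genome.centromeres[chrom] = cen + 1


def apply_gain_tandem(genome: SimGenome, parent_gid: str, gid: str) -> None:
    chrom, idx = genome.locate(parent_gid)
    parent = genome.chromosomes[chrom][idx]
    genome.chromosomes[chrom].insert(
        idx + 1, SimGene(gid, parent.family, parent.strand)
    )
    cen = genome.centromeres.get(chrom)
    if cen is not None and idx + 1 < cen:
        genome.centromeres[chrom] = cen + 1


def apply_loss(genome: SimGenome, gid: str) -> None:
    chrom, idx = genome.locate(gid)
    del genome.chromosomes[chrom][idx]
    cen = genome.centromeres.get(chrom)
    if cen is not None and idx < cen:
        genome.centromeres[chrom] = cen - 1
    if not genome.chromosomes[chrom]:
        del genome.chromosomes[chrom]
        genome.centromeres.pop(chrom, None)


def apply_wgd(genome: SimGenome, params: dict) -> None:
    """Apply a recorded two-step triplication: copy, exchange, fractionate."""
    copies: Dict[str, Dict[str, str]] = params["copies"]
    new_chroms: Dict[str, List[SimGene]] = {}
    new_cens: Dict[str, int] = {}
    for chrom, genes in genome.chromosomes.items():
        for sub in SUBGENOMES:
            new_chroms[f"{chrom}_{sub}"] = [
                SimGene(copies[g.gid][sub], g.family, g.strand) for g in genes
            ]
            if chrom in genome.centromeres:
                new_cens[f"{chrom}_{sub}"] = genome.centromeres[chrom]
    genome.chromosomes = new_chroms
    genome.centromeres = new_cens
    for chrom, pos in params["exchanges"]:
        a, b = f"{chrom}_MF1", f"{chrom}_MF2"
        ga, gb = genome.chromosomes[a], genome.chromosomes[b]
        genome.chromosomes[a] = ga[:pos] + gb[pos:]
        genome.chromosomes[b] = gb[:pos] + ga[pos:]
    lost = set(params["lost"])
    for chrom in list(genome.chromosomes):
        genes = genome.chromosomes[chrom]
        cen = genome.centromeres.get(chrom)
        if cen is not None:
            cen -= sum(1 for g in genes[:cen] if g.gid in lost)
        kept = [g for g in genes if g.gid not in lost]
        if kept:
            genome.chromosomes[chrom] = kept
            if cen is not None:
                genome.centromeres[chrom] = cen
        else:
            del genome.chromosomes[chrom]
            genome.centromeres.pop(chrom, None)


_APPLY = {
    "inversion": lambda g, p: apply_inversion(g, p["chrom"], p["start"], p["length"]),
    "translocation": lambda g, p: apply_reciprocal_translocation(
        g, p["chrom_a"], p["pos_a"], p["chrom_b"], p["pos_b"], p["side_left"]
    ),
    "fusion_rta": lambda g, p: apply_fusion_rta(
        g, p["chrom_a"], p["chrom_b"], p["n_collateral"]
    ),
    "fission": lambda g, p: apply_fission(g, p["chrom"], p["pos"], p["new_name"]),
    "gain_novel": lambda g, p: apply_gain_novel(
        g, p["chrom"], p["pos"], p["gid"], p["family"], p["strand"]
    ),
    "gain_tandem": lambda g, p: apply_gain_tandem(g, p["parent_gid"], p["gid"]),
    "loss": lambda g, p: apply_loss(g, p["gid"]),
    "wgd": apply_wgd,
}


def replay_events(
    root_genome: SimGenome, tree: SpeciesTree, events: Sequence[EventRecord]
) -> Dict[str, SimGenome]:
    """Re-apply the event log from the root; returns the leaf genomes."""
    by_branch: Dict[str, List[EventRecord]] = {}
    for ev in events:
        by_branch.setdefault(ev.branch_child, []).append(ev)
    leaves: Dict[str, SimGenome] = {}

    def walk(node, state: SimGenome) -> None:
        if node.is_leaf:
            leaves[node.name] = state
            return
        for child in node.children:
            cstate = state.clone()
            for ev in by_branch.get(child.name or "", ()):
                if ev.etype in ("resample", "skip"):
                    continue
                _APPLY[ev.etype](cstate, ev.params)
            walk(child, cstate)

    walk(tree.root, root_genome.clone())
    return leaves


# --------------------------------------------------------------------------
# The simulator
# --------------------------------------------------------------------------

class _IdFactory:
    def __init__(self) -> None:
        self.gene_counter = 0
        self.family_counter = 0

    def gene(self) -> str:
        self.gene_counter += 1
        return f"g{self.gene_counter:06d}"

    def family(self) -> str:
        self.family_counter += 1
        return f"fam{self.family_counter:05d}"


_STRUCTURAL_TYPES = (
    "fission",
    "fusion_rta",
    "gain",
    "inversion",
    "loss",
    "translocation",
)


def _applicable(etype: str, genome: SimGenome) -> bool:
    if etype == "gain":
        return genome.n_genes > 0  # insertions need a host chromosome
    if etype == "loss":
        return genome.n_genes > 0
    if etype == "inversion":
        return any(len(v) >= 2 for v in genome.chromosomes.values())
    if etype == "fission":
        return any(len(v) >= 2 for v in genome.chromosomes.values())
    if etype in ("translocation", "fusion_rta"):
        eligible = [
            c
            for c in genome.chromosomes
            if c in genome.centromeres and len(genome.chromosomes[c]) >= 2
        ]
        return len(eligible) >= 2
    raise ValueError(etype)  # pragma: no cover


def _pick_chromosome(
    rng: np.random.Generator, genome: SimGenome, min_len: int = 1
) -> str:
    names = sorted(c for c in genome.chromosomes if len(genome.chromosomes[c]) >= min_len)
    lengths = np.array([len(genome.chromosomes[c]) for c in names], dtype=float)
    return names[rng.choice(len(names), p=lengths / lengths.sum())]


def _draw_params(
    etype: str,
    genome: SimGenome,
    rng: np.random.Generator,
    config: SimulationConfig,
    ids: _IdFactory,
) -> Tuple[str, dict, Tuple[str, ...]]:
    """Resolve an event type into concrete, replayable parameters."""
    if etype == "gain":
        if genome.n_genes and rng.random() < 0.5:
            all_ids = sorted(genome.gene_ids())
            parent = all_ids[rng.integers(len(all_ids))]
            gid = ids.gene()
            return "gain_tandem", {"parent_gid": parent, "gid": gid}, (gid,)
        chrom = _pick_chromosome(rng, genome)
        pos = int(rng.integers(len(genome.chromosomes[chrom]) + 1))
        gid = ids.gene()
        fam = ids.family()
        strand = 1 if rng.random() < 0.5 else -1
        return (
            "gain_novel",
            {"chrom": chrom, "pos": pos, "gid": gid, "family": fam, "strand": strand},
            (gid,),
        )
    if etype == "loss":
        all_ids = sorted(genome.gene_ids())
        gid = all_ids[rng.integers(len(all_ids))]
        return "loss", {"gid": gid}, (gid,)
    if etype == "inversion":
        chrom = _pick_chromosome(rng, genome, min_len=2)
        n = len(genome.chromosomes[chrom])
        length = min(int(rng.geometric(config.inversion_geom_p)) + 1, n)
        start = int(rng.integers(n - length + 1))
        return "inversion", {"chrom": chrom, "start": start, "length": length}, ()
    if etype == "translocation":
        eligible = sorted(
            c
            for c in genome.chromosomes
            if c in genome.centromeres and len(genome.chromosomes[c]) >= 2
        )
        i, j = rng.choice(len(eligible), size=2, replace=False)
        a, b = eligible[int(i)], eligible[int(j)]
        # Break on the same centromere side in both chromosomes so products
        # stay monocentric.
        cen_a, cen_b = genome.centromeres[a], genome.centromeres[b]
        len_a, len_b = len(genome.chromosomes[a]), len(genome.chromosomes[b])

        def draw_pos(cen: int, ln: int, left: bool) -> Optional[int]:
            lo, hi = (1, min(cen, ln - 1)) if left else (max(cen, 1), ln - 1)
            if lo > hi:
                return None
            return int(rng.integers(lo, hi + 1))

        side_left = bool(rng.random() < 0.5)
        pos_a = draw_pos(cen_a, len_a, side_left)
        pos_b = draw_pos(cen_b, len_b, side_left)
        if pos_a is None or pos_b is None:
            side_left = not side_left
            pos_a = draw_pos(cen_a, len_a, side_left)
            pos_b = draw_pos(cen_b, len_b, side_left)
        if pos_a is None or pos_b is None:
            return "skip", {"reason": "no valid translocation break"}, ()
        return (
            "translocation",
            {
                "chrom_a": a,
                "pos_a": pos_a,
                "chrom_b": b,
                "pos_b": pos_b,
                "side_left": side_left,
            },
            (),
        )
    if etype == "fusion_rta":
        eligible = sorted(
            c
            for c in genome.chromosomes
            if c in genome.centromeres and len(genome.chromosomes[c]) >= 2
        )
        i, j = rng.choice(len(eligible), size=2, replace=False)
        a, b = eligible[int(i)], eligible[int(j)]
        k = int(rng.integers(config.fusion_collateral_max + 1))
        return "fusion_rta", {"chrom_a": a, "chrom_b": b, "n_collateral": k}, ()
    if etype == "fission":
        chrom = _pick_chromosome(rng, genome, min_len=2)
        n = len(genome.chromosomes[chrom])
        pos = int(rng.integers(1, n))
        return (
            "fission",
            {"chrom": chrom, "pos": pos, "new_name": f"{chrom}f"},
            (),
        )
    raise ValueError(etype)  # pragma: no cover


def _make_root_genome(config: SimulationConfig, ids: _IdFactory) -> SimGenome:
    genome = SimGenome()
    for c in range(config.n_chromosomes):
        name = f"chr{c + 1}"
        genes = []
        for _ in range(config.genes_per_chromosome):
            genes.append(SimGene(ids.gene(), ids.family(), 1))
        genome.chromosomes[name] = genes
        genome.centromeres[name] = config.genes_per_chromosome // 2
    return genome


def triplicate_two_step(
    genome: SimGenome,
    spec: HexaploidySpec,
    rng: np.random.Generator,
    ids: Optional[_IdFactory] = None,
) -> Tuple[dict, HexTruth, Dict[str, str]]:
    """Draw and apply a two-step triplication; returns (params, truth).

    The params dict is replayable with :func:`apply_wgd`.
    """
    ids = ids or _IdFactory()
    copies: Dict[str, Dict[str, str]] = {}
    parent_of: Dict[str, str] = {}
    for chrom in genome.chromosomes:
        for g in genome.chromosomes[chrom]:
            copies[g.gid] = {}
            for sub in SUBGENOMES:
                cid = ids.gene()
                copies[g.gid][sub] = cid
                parent_of[cid] = g.gid

    # MF1-MF2 reciprocal exchanges while they share a nucleus (before LF
    # joins): tail swaps at well-separated breakpoints.
    exchanges: List[Tuple[str, int]] = []
    chroms = sorted(genome.chromosomes)
    lengths = np.array([len(genome.chromosomes[c]) for c in chroms], dtype=float)
    taken: Dict[str, List[int]] = {c: [] for c in chroms}
    attempts = 0
    while len(exchanges) < spec.n_exchanges and attempts < 200 * max(1, spec.n_exchanges):
        attempts += 1
        chrom = chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]
        n = len(genome.chromosomes[chrom])
        lo, hi = spec.min_block_genes, n - spec.min_block_genes
        if hi <= lo:
            continue
        pos = int(rng.integers(lo, hi))
        if any(abs(pos - p) < spec.min_block_genes for p in taken[chrom]):
            continue
        taken[chrom].append(pos)
        exchanges.append((chrom, pos))
    exchanges.sort()

    # Dominance/sensitivity is a property of the progenitor block: a copy
    # keeps its origin subgenome's fractionation pressure even after a tail
    # swap moves it onto the homoeologous chromosome.  That is what makes an
    # exchange observable: retention counts flip along a physically
    # continuous extant chromosome.
    labels: Dict[str, str] = {}
    for orig, subs in copies.items():
        for sub, cid in subs.items():
            labels[cid] = sub
    # Fractionation: each copy deleted independently with its origin
    # subgenome's probability.
    probs = dict(zip(SUBGENOMES, spec.loss_probs))
    lost = []
    for chrom in chroms:
        for sub in SUBGENOMES:
            for g in genome.chromosomes[chrom]:
                cid = copies[g.gid][sub]
                if rng.random() < probs[labels[cid]]:
                    lost.append(cid)
    params = {"copies": copies, "exchanges": exchanges, "lost": lost}
    apply_wgd(genome, params)
    for cid in lost:
        labels.pop(cid, None)
    truth = HexTruth(
        node_branch="",
        time=0.0,
        copies=copies,
        labels=labels,
        breakpoints=exchanges,
        lost=lost,
    )
    return params, truth, parent_of


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run the forward simulation; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    ids = _IdFactory()
    tree = SpeciesTree.from_newick(config.newick)
    root = _make_root_genome(config, ids)
    events: List[EventRecord] = []
    parents: Dict[str, str] = {}
    snapshots: Dict[str, SimGenome] = {}
    leaf_states: Dict[str, SimGenome] = {}
    hex_truth: Optional[HexTruth] = None

    rates = {
        "inversion": config.inversion_rate,
        "translocation": config.translocation_rate,
        "fusion_rta": config.fusion_rta_rate,
        "fission": config.fission_rate,
        "gain": config.gene_gain_rate,
        "loss": config.gene_loss_rate,
    }

    if tree.root.name is not None:
        snapshots[tree.root.name] = root.clone()

    def process_branch(child, state: SimGenome) -> SimGenome:
        nonlocal hex_truth
        length = (child.length or 0.0) * config.time_scale
        schedule: List[Tuple[float, int, str]] = []
        seq = 0
        for etype in _STRUCTURAL_TYPES:
            rate = rates[etype]
            if rate <= 0 or length <= 0:
                continue
            n = int(rng.poisson(rate * length))
            for t in rng.uniform(0.0, length, size=n):
                schedule.append((float(t), seq, etype))
                seq += 1
        hx = config.hexaploidy
        if hx is not None and child.name == hx.branch_child:
            schedule.append((hx.branch_fraction * length, seq, "wgd"))
        schedule.sort()
        for t, _s, etype in schedule:
            if etype == "wgd":
                params, truth, parent_of = triplicate_two_step(
                    state, config.hexaploidy, rng, ids
                )
                parents.update(parent_of)
                truth.node_branch = child.name
                truth.time = t
                hex_truth = truth
                events.append(
                    EventRecord(child.name, t, "wgd", params, tuple(params["lost"]))
                )
                continue
            if not _applicable(etype, state):
                alts = [
                    e for e in _STRUCTURAL_TYPES
                    if rates[e] > 0 and _applicable(e, state)
                ]
                if not alts:
                    continue
                new_etype = alts[int(rng.integers(len(alts)))]
                events.append(
                    EventRecord(
                        child.name or "", t, "resample",
                        {"from": etype, "to": new_etype}, (),
                    )
                )
                etype = new_etype
            concrete, params, affected = _draw_params(etype, state, rng, config, ids)
            if concrete == "skip":
                events.append(EventRecord(child.name or "", t, "skip", params, ()))
                continue
            if concrete == "gain_tandem":
                parents[params["gid"]] = params["parent_gid"]
            if concrete == "fusion_rta":
                lost = apply_fusion_rta(
                    state, params["chrom_a"], params["chrom_b"], params["n_collateral"]
                )
                events.append(
                    EventRecord(child.name or "", t, concrete, params, tuple(lost))
                )
                continue
            _APPLY[concrete](state, params)
            events.append(EventRecord(child.name or "", t, concrete, params, affected))
        return state

    def walk(node, state: SimGenome) -> None:
        for child in node.children:
            cstate = process_branch(child, state.clone())
            if child.is_leaf:
                leaf_states[child.name] = cstate
            else:
                if child.name is not None:
                    snapshots[child.name] = cstate.clone()
                walk(child, cstate)

    walk(tree.root, root)

    genomes = {
        sp: sim_to_genome(sp, state) for sp, state in sorted(leaf_states.items())
    }
    family_of_instance: Dict[str, str] = {}
    for state in list(leaf_states.values()) + list(snapshots.values()) + [root]:
        for genes in state.chromosomes.values():
            for g in genes:
                family_of_instance[g.gid] = g.family
    members: Dict[str, Dict[str, List[str]]] = {}
    for sp, genome in genomes.items():
        for g in genome:
            members.setdefault(g.family_id, {}).setdefault(sp, []).append(g.gene_id)
    families = GeneFamilies(members)

    dataset = SyntheticDataset(
        config=config,
        tree=tree,
        root_genome=root.clone(),
        genomes=genomes,
        families=families,
        snapshots=snapshots,
        events=events,
        parents=parents,
        family_of_instance=family_of_instance,
        hex_truth=hex_truth,
    )
    if config.sequences is not None:
        dataset.sequences = evolve_sequences(
            dataset, config.sequences, np.random.default_rng(config.seed + 101)
        )
    return dataset


def sim_to_genome(species: str, state: SimGenome) -> Genome:
    chromosomes: Dict[str, List[Gene]] = {}
    for chrom in sorted(state.chromosomes):
        genes = []
        for i, g in enumerate(state.chromosomes[chrom]):
            genes.append(
                Gene(
                    gene_id=g.gid,
                    family_id=g.family,
                    chromosome=chrom,
                    rank=i,
                    strand=g.strand,
                    start_bp=(i + 1) * 1000,
                    end_bp=(i + 1) * 1000 + 500,
                )
            )
        chromosomes[chrom] = genes
    return Genome(species, chromosomes, dict(sorted(state.centromeres.items())))


# --------------------------------------------------------------------------
# Codon sequence evolution
# --------------------------------------------------------------------------

def _sense_codons() -> List[str]:
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        from Bio.Data.CodonTable import standard_dna_table

        _SENSE_CODONS = sorted(standard_dna_table.forward_table)
    return _SENSE_CODONS


_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


def random_codon_sequence(n_codons: int, rng: np.random.Generator) -> str:
    codons = _sense_codons()
    return "".join(codons[int(i)] for i in rng.integers(len(codons), size=n_codons))


def evolve_codon_sequence(
    seq: str, duration_my: float, rate: float, rng: np.random.Generator
) -> str:
    """Accrue substitutions; proposals creating stop codons are rejected."""
    if duration_my <= 0 or rate <= 0:
        return seq
    n = int(rng.poisson(rate * duration_my * len(seq)))
    s = list(seq)
    for _ in range(n):
        site = int(rng.integers(len(s)))
        old = s[site]
        new = _BASES[int(rng.integers(4))]
        if new == old:
            continue
        cstart = 3 * (site // 3)
        codon = s[cstart] + s[cstart + 1] + s[cstart + 2]
        mutated = codon[: site % 3] + new + codon[site % 3 + 1 :]
        if mutated in _STOPS:
            continue
        s[site] = new
    return "".join(s)


def evolve_sequences(
    dataset: SyntheticDataset,
    model: SequenceModel,
    rng: np.random.Generator,
) -> Dict[str, str]:
    """Simulate codon sequences for every extant gene along the tree.

    Root genes receive random stop-free sequences; each branch applies
    Poisson substitutions for its full (scaled) duration to every gene
    present at its end (genes born mid-branch thus accrue slightly more
    divergence than their exact age implies -- a deliberate simplification).
    On the hexaploidy branch the three copies diverge according to the
    progenitor split offsets before the merge.
    """
    config = dataset.config
    tree = dataset.tree
    rate = model.subs_per_site_per_my
    hx = config.hexaploidy
    root_ids = sorted(dataset.root_genome.gene_ids())
    node_seqs: Dict[str, Dict[str, str]] = {}
    root_key = tree.root.name or "<root>"
    node_seqs[root_key] = {
        gid: random_codon_sequence(model.n_codons, rng) for gid in root_ids
    }
    out: Dict[str, str] = {}

    def state_ids(node) -> Set[str]:
        if node.is_leaf:
            return dataset.genomes[node.name].gene_ids()
        return dataset.snapshots[node.name].gene_ids()

    def walk(node, parent_key: str) -> None:
        for child in node.children:
            length = (child.length or 0.0) * config.time_scale
            parent_seqs = node_seqs[parent_key]
            child_ids = state_ids(child)
            child_seqs: Dict[str, str] = {}
            is_wgd_branch = (
                hx is not None
                and dataset.hex_truth is not None
                and child.name == hx.branch_child
            )
            wgd_bases: Dict[str, str] = {}
            if is_wgd_branch:
                t_w = dataset.hex_truth.time
                post = max(0.0, length - t_w)
                for orig, subs in sorted(dataset.hex_truth.copies.items()):
                    base_anc = _ancestor_in(orig, set(parent_seqs), dataset.parents)
                    base = (
                        parent_seqs[base_anc]
                        if base_anc is not None
                        else random_codon_sequence(model.n_codons, rng)
                    )
                    base = evolve_codon_sequence(base, t_w, rate, rng)
                    lf = evolve_codon_sequence(base, hx.lf_split_my, rate, rng)
                    mf_base = evolve_codon_sequence(
                        base, max(0.0, hx.lf_split_my - hx.mf_split_my), rate, rng
                    )
                    mf1 = evolve_codon_sequence(mf_base, hx.mf_split_my, rate, rng)
                    mf2 = evolve_codon_sequence(mf_base, hx.mf_split_my, rate, rng)
                    for sub, seq0 in (("LF", lf), ("MF1", mf1), ("MF2", mf2)):
                        wgd_bases[subs[sub]] = evolve_codon_sequence(
                            seq0, post, rate, rng
                        )
            for gid in sorted(child_ids):
                if gid in wgd_bases:
                    child_seqs[gid] = wgd_bases[gid]
                    continue
                anc = _ancestor_in(gid, set(parent_seqs), dataset.parents)
                if anc is not None:
                    base = parent_seqs[anc]
                elif is_wgd_branch:
                    # Born after the merge from a WGD copy, or novel.
                    chain: Optional[str] = gid
                    base = None
                    while chain is not None:
                        if chain in wgd_bases:
                            base = wgd_bases[chain]
                            break
                        chain = dataset.parents.get(chain)
                    if base is None:
                        base = random_codon_sequence(model.n_codons, rng)
                else:
                    base = random_codon_sequence(model.n_codons, rng)
                child_seqs[gid] = evolve_codon_sequence(base, length, rate, rng)
            key = child.name or f"<{id(child)}>"
            node_seqs[key] = child_seqs
            if child.is_leaf:
                out.update(child_seqs)
            else:
                walk(child, key)
            del node_seqs[key]

    walk(tree.root, root_key)
    return out


# --------------------------------------------------------------------------
# Dataset serialization
# --------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, out_dir) -> None:
    """Write gene orders, families, tree, truth karyotypes, maps and the log."""
    from . import io as pio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sp, genome in dataset.genomes.items():
        pio.write_gene_orders(genome, out / f"genes.{sp}.tsv")
    pio.write_families(dataset.families, out / "families.tsv")
    pio.write_newick(dataset.tree, out / "tree.nwk")
    for node in sorted(dataset.snapshots):
        k = dataset.true_karyotype(node)
        pio.write_karyotype(k, out / f"true_karyotype.{node}.tsv")
        omap = dataset.ortholog_map_all(node)
        pio.write_ortholog_map(omap, out / f"true_orthologs.{node}.tsv")
    with (out / "events.tsv").open("w") as fh:
        fh.write("branch_child\ttime\tevent\tparams\taffected\n")
        for ev in dataset.events:
            fh.write(
                f"{ev.branch_child}\t{ev.time:.6f}\t{ev.etype}\t"
                f"{json.dumps(ev.params, sort_keys=True)}\t"
                f"{','.join(ev.affected) or '.'}\n"
            )
    if dataset.sequences is not None:
        with (out / "sequences.fasta").open("w") as fh:
            for gid in sorted(dataset.sequences):
                fh.write(f">{gid}\n{dataset.sequences[gid]}\n")
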