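"""Reconstruction-quality metrics against simulated truth.

Adjacency precision/recall compare oriented canonical adjacency sets.
Junctions between CARs that were merely scaffolded into the same
protochromosome (no gene-level adjacency evidence) are not counted as
gene-level adjacencies; grouping quality is scored separately by the
co-chromosome pair concordance (a Rand-index style statistic over gene
pairs placed in protochromosomes by both karyotypes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Set, Tuple

from .adjacency import Adjacency, canonical_adjacency
from .model import CAR, AncestralKaryotype, InputError, Protochromosome


def project_karyotype(
    karyotype: AncestralKaryotype, keep: Set[str]
) -> AncestralKaryotype:
    """Project a karyotype onto a gene namespace, preserving order and strand.

    Genes outside ``keep`` are dropped from every CAR.  Used to express a true
    ancestor in the inferable namespace before comparison: ancestral genes
    whose family left no extant descendants are invisible to any
    conservation-based method, so order quality is scored over the comparable
    marker set (content accuracy is reported separately).
    """
    protochromosomes = []
    for pc in karyotype.protochromosomes:
        genes = [
            (g, s)
            for car, orientation in pc.cars
            for g, s in car.oriented(orientation)
            if g in keep
        ]
        if genes:
            car = CAR(pc.pc_id, karyotype.node, genes)
            protochromosomes.append(
                Protochromosome(pc.pc_id, karyotype.node, [(car, 1)])
            )
    small = []
    for car in karyotype.small_cars:
        genes = [(g, s) for g, s in car.genes if g in keep]
        if genes:
            small.append(CAR(car.car_id, karyotype.node, genes))
    singletons = karyotype.singletons & keep
    return AncestralKaryotype(karyotype.node, protochromosomes, small, singletons)


def karyotype_adjacencies(karyotype: AncestralKaryotype) -> Set[Adjacency]:
    """Gene-level oriented adjacencies: consecutive pairs within each CAR."""
    out: Set[Adjacency] = set()

    def add_car(genes) -> None:
        for (u, su), (v, sv) in zip(genes, genes[1:]):
            if u == v:
                continue
            out.add(canonical_adjacency(u, su, v, sv))

    for pc in karyotype.protochromosomes:
        for car, orientation in pc.cars:
            add_car(car.oriented(orientation))
    for car in karyotype.small_cars:
        add_car(car.genes)
    return out


def adjacency_prf(
    true_karyotype: AncestralKaryotype, reconstructed: AncestralKaryotype
) -> Tuple[float, float, float]:
    """(precision, recall, F1) of oriented gene-level adjacencies."""
    t = karyotype_adjacencies(true_karyotype)
    r = karyotype_adjacencies(reconstructed)
    t_genes = true_karyotype.total_protogenes
    r_genes = reconstructed.total_protogenes
    if t_genes and r_genes and not (t_genes & r_genes):
        raise InputError(
            "true and reconstructed karyotypes share no ancestral gene namespace"
        )
    tp = len(t & r)
    precision = tp / len(r) if r else 0.0
    recall = tp / len(t) if t else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def _placements(karyotype: AncestralKaryotype) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for pc in karyotype.protochromosomes:
        for gid in pc.gene_ids():
            out[gid] = pc.pc_id
    return out


def co_chromosome_concordance(
    true_karyotype: AncestralKaryotype, reconstructed: AncestralKaryotype
) -> Optional[float]:
    """Fraction of gene pairs co-chromosomal in both or separated in both.

    Computed over ancestral genes placed in protochromosomes by both
    karyotypes; undefined (None) for fewer than two shared placed genes.
    """
    pt = _placements(true_karyotype)
    pr = _placements(reconstructed)
    shared = sorted(set(pt) & set(pr))
    n = len(shared)
    if n < 2:
        return None
    # Contingency-table pair counting (Rand index).
    table: Dict[Tuple[str, str], int] = {}
    rows: Dict[str, int] = {}
    cols: Dict[str, int] = {}
    for g in shared:
        key = (pt[g], pr[g])
        table[key] = table.get(key, 0) + 1
        rows[pt[g]] = rows.get(pt[g], 0) + 1
        cols[pr[g]] = cols.get(pr[g], 0) + 1

    def c2(x: int) -> int:
        return x * (x - 1) // 2

    total = c2(n)
    same_t = sum(c2(v) for v in rows.values())
    same_r = sum(c2(v) for v in cols.values())
    same_both = sum(c2(v) for v in table.values())
    concordant = same_both + (total - same_t - same_r + same_both)
    return concordant / total


@dataclass
class ReconstructionReport:
    node: str
    precision: float
    recall: float
    f1: float
    content_precision: float
    content_recall: float
    ordered_fraction: float
    protochromosome_delta: int
    concordance: Optional[float]

    def as_dict(self) -> dict:
        return {
            "node": self.node,
            "adjacency_precision": self.precision,
            "adjacency_recall": self.recall,
            "adjacency_f1": self.f1,
            "content_precision": self.content_precision,
            "content_recall": self.content_recall,
            "ordered_fraction": self.ordered_fraction,
            "protochromosome_delta": self.protochromosome_delta,
            "co_chromosome_concordance": self.concordance,
        }


def evaluate_reconstruction(
    true_karyotype: AncestralKaryotype,
    reconstructed: AncestralKaryotype,
    project_truth: bool = True,
) -> ReconstructionReport:
    """Score a reconstruction against the true ancestor.

    Content precision/recall compare the full gene sets.  Adjacency metrics
    and concordance are computed, by default, with the true ancestor
    projected onto the reconstruction's content namespace (see
    :func:`project_karyotype`); genes wrongly included by the reconstruction
    still count against adjacency precision.
    """
    t_content = true_karyotype.total_protogenes
    r_content = reconstructed.total_protogenes
    if t_content and r_content and not (t_content & r_content):
        raise InputError(
            "true and reconstructed karyotypes share no ancestral gene namespace"
        )
    cp = len(t_content & r_content) / len(r_content) if r_content else 0.0
    cr = len(t_content & r_content) / len(t_content) if t_content else 0.0
    if project_truth:
        true_karyotype = project_karyotype(true_karyotype, r_content)
    precision, recall, f1 = adjacency_prf(true_karyotype, reconstructed)
    total = len(r_content)
    ordered_fraction = (
        len(reconstructed.ordered_protogenes) / total if total else 0.0
    )
    report = ReconstructionReport(
        node=reconstructed.node,
        precision=precision,
        recall=recall,
        f1=f1,
        content_precision=cp,
        content_recall=cr,
        ordered_fraction=ordered_fraction,
        protochromosome_delta=len(reconstructed.protochromosomes)
        - len(true_karyotype.protochromosomes),
        concordance=co_chromosome_concordance(true_karyotype, reconstructed),
    )
    for value in (
        report.precision,
        report.recall,
        report.f1,
        report.content_precision,
        report.content_recall,
        report.ordered_fraction,
    ):
        assert 0.0 <= value <= 1.0
    return report
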