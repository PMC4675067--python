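"""Windowed subgenome assignment and retention analysis for a paleohexaploid.

The ordered protogenes of the pre-triplication ancestor are cut into disjoint
consecutive windows (default 100 genes).  Within each window the surviving
orthologous copies in the polyploid descendant are clustered into extant
regions (same chromosome, rank gaps below a threshold); the three regions
retaining the most ancestral genes are labeled LF (least fractionated), MF1
and MF2 (most fractionated) by descending retained count.  Each window is
labeled independently; label flips between physically continuing regions of
consecutive windows are read as dominance/sensitivity exchanges
(recombination between subgenomes), not smoothed away.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .model import AncestralKaryotype, Genome, InputError, InteractionNetwork

LABELS = ("LF", "MF1", "MF2")


@dataclass
class Region:
    """One extant cluster of window orthologs."""

    extant_chr: str
    start_rank: int
    end_rank: int
    retained: int  # distinct ancestral genes of the window with a copy here
    anc_to_extant: Dict[str, List[str]]
    label: Optional[str] = None


@dataclass
class Window:
    anc_chr: str
    index: int
    anc_genes: List[str]
    regions: List[Region]
    flagged: bool = False  # no extant region survived

    def region_by_label(self, label: str) -> Optional[Region]:
        for r in self.regions:
            if r.label == label:
                return r
        return None


@dataclass
class SubgenomeMap:
    windows: List[Window]
    window_size: int
    gap: int

    def check_label_ordering(self) -> None:
        """Re-assert count(LF) >= count(MF1) >= count(MF2) per window."""
        for w in self.windows:
            counts = [
                r.retained
                for label in LABELS
                for r in w.regions
                if r.label == label
            ]
            if counts != sorted(counts, reverse=True):
                from .model import InvariantError

                raise InvariantError(
                    f"window {w.anc_chr}:{w.index}: label counts not ordered"
                )


@dataclass
class GeneRetention:
    anc_id: str
    retention_class: str
    copies: List[Tuple[Optional[str], str]]  # (label or None, extant gene id)


def _ordered_genes_by_chromosome(
    karyotype: AncestralKaryotype,
) -> Dict[str, List[str]]:
    return {
        pc.pc_id: pc.gene_ids() for pc in karyotype.protochromosomes
    }


def assign_subgenome_windows(
    ancestral_karyotype: AncestralKaryotype,
    polyploid: Genome,
    ortholog_map: Dict[str, List[str]],
    window: int = 100,
    gap: int = 50,
) -> SubgenomeMap:
    """Label LF/MF1/MF2 regions per window of ancestral ordered protogenes.

    ``ortholog_map`` maps ancestral ordered protogenes to lists of polyploid
    gene ids (one-to-many).  The last window of a chromosome may be short.
    Two ortholog clusters on the same extant chromosome compete independently
    for the top three slots.
    """
    if window < 2:
        raise InputError(f"window must be >= 2, got {window}")
    windows: List[Window] = []
    for anc_chr, genes in _ordered_genes_by_chromosome(ancestral_karyotype).items():
        for idx in range(0, len(genes), window):
            chunk = genes[idx : idx + window]
            win = Window(anc_chr, idx // window, list(chunk), [])
            # Collect extant copies with their positions.
            located: List[Tuple[str, int, str, str]] = []  # (chr, rank, anc, extant)
            for anc in chunk:
                for gid in ortholog_map.get(anc, ()):
                    if gid in polyploid:
                        g = polyploid.gene(gid)
                        located.append((g.chromosome, g.rank, anc, gid))
            located.sort()
            # Cluster per chromosome with rank gaps <= gap.
            clusters: List[List[Tuple[str, int, str, str]]] = []
            for item in located:
                if (
                    clusters
                    and clusters[-1][-1][0] == item[0]
                    and item[1] - clusters[-1][-1][1] <= gap
                ):
                    clusters[-1].append(item)
                else:
                    clusters.append([item])
            regions = []
            for cl in clusters:
                anc_to_extant: Dict[str, List[str]] = {}
                for _c, _r, anc, gid in cl:
                    anc_to_extant.setdefault(anc, []).append(gid)
                regions.append(
                    Region(
                        extant_chr=cl[0][0],
                        start_rank=cl[0][1],
                        end_rank=cl[-1][1],
                        retained=len(anc_to_extant),
                        anc_to_extant=anc_to_extant,
                    )
                )
            # Top three by retained count; ties by (chromosome, start rank).
            regions.sort(key=lambda r: (-r.retained, r.extant_chr, r.start_rank))
            for label, region in zip(LABELS, regions):
                region.label = label
            win.regions = regions
            win.flagged = not regions
            windows.append(win)
    smap = SubgenomeMap(windows, window, gap)
    smap.check_label_ordering()
    return smap


def retention_classes(
    smap: SubgenomeMap,
    ortholog_map: Dict[str, List[str]],
) -> Tuple[Counter, List[GeneRetention]]:
    """Classify each ancestral gene by which labeled regions retain a copy.

    Classes: ``triplet``, pairs (``LF-MF1``, ``LF-MF2``, ``MF1-MF2``),
    singletons (``LF``, ``MF1``, ``MF2``), ``lost`` (no surviving copy) and
    ``unplaced`` (copies exist but only outside labeled regions).
    """
    retentions: List[GeneRetention] = []
    for win in smap.windows:
        extant_to_label: Dict[str, str] = {}
        for region in win.regions:
            if region.label is None:
                continue
            for gids in region.anc_to_extant.values():
                for gid in gids:
                    extant_to_label[gid] = region.label
        for anc in win.anc_genes:
            copies = [
                (extant_to_label.get(gid), gid) for gid in ortholog_map.get(anc, ())
            ]
            labels = sorted(
                {lab for lab, _g in copies if lab is not None},
                key=LABELS.index,
            )
            if not copies:
                cls = "lost"
            elif not labels:
                cls = "unplaced"
            elif len(labels) == 3:
                cls = "triplet"
            else:
                cls = "-".join(labels)
            retentions.append(GeneRetention(anc, cls, copies))
    counts = Counter(r.retention_class for r in retentions)
    return counts, retentions


@dataclass(frozen=True)
class Exchange:
    anc_chr: str
    boundary: int  # between window boundary-1 and boundary
    label_a: str
    label_b: str


def dominance_exchanges(smap: SubgenomeMap) -> List[Exchange]:
    """Label flips of physically continuing extant regions between windows.

    An exchange is recorded between consecutive windows when a region on the
    same extant chromosome, with abutting rank intervals (gap at most the
    clustering threshold), changes label.  Each unordered label pair is
    reported once per boundary.
    """
    by_chr: Dict[str, List[Window]] = {}
    for w in smap.windows:
        by_chr.setdefault(w.anc_chr, []).append(w)
    exchanges: Set[Exchange] = set()
    for anc_chr, wins in by_chr.items():
        wins.sort(key=lambda w: w.index)
        for w1, w2 in zip(wins, wins[1:]):
            for r1 in w1.regions:
                if r1.label is None:
                    continue
                for r2 in w2.regions:
                    if r2.label is None or r2.extant_chr != r1.extant_chr:
                        continue
                    if abs(r2.start_rank - r1.end_rank) <= smap.gap and r1.label != r2.label:
                        a, b = sorted((r1.label, r2.label), key=LABELS.index)
                        exchanges.add(Exchange(anc_chr, w2.index, a, b))
    return sorted(exchanges, key=lambda e: (e.anc_chr, e.boundary, e.label_a, e.label_b))


def connectivity_fraction(
    classes: Dict[str, List[str]], net: InteractionNetwork
) -> Dict[str, Optional[float]]:
    """Per class, the fraction of extant member genes with network degree >= 1.

    Empty classes are reported as None (undefined), not zero.
    """
    out: Dict[str, Optional[float]] = {}
    for cls, gene_ids in classes.items():
        if not gene_ids:
            out[cls] = None
            continue
        connected = sum(1 for g in gene_ids if net.degree(g) >= 1)
        out[cls] = connected / len(gene_ids)
    return out


def copies_by_class(retentions: Iterable[GeneRetention]) -> Dict[str, List[str]]:
    """Extant gene copies grouped by their ancestral gene's retention class."""
    out: Dict[str, List[str]] = {}
    for ret in retentions:
        for _label, gid in ret.copies:
            out.setdefault(ret.retention_class, []).append(gid)
    return out


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

def subgenome_map_frame(smap: SubgenomeMap) -> pd.DataFrame:
    rows = []
    for w in smap.windows:
        for r in w.regions:
            if r.label is None:
                continue
            rows.append(
                {
                    "anc_chr": w.anc_chr,
                    "window_index": w.index,
                    "anc_gene_start": w.anc_genes[0],
                    "anc_gene_end": w.anc_genes[-1],
                    "label": r.label,
                    "extant_chr": r.extant_chr,
                    "extant_start_rank": r.start_rank + 1,
                    "extant_end_rank": r.end_rank + 1,
                    "retained_count": r.retained,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "anc_chr",
            "window_index",
            "anc_gene_start",
            "anc_gene_end",
            "label",
            "extant_chr",
            "extant_start_rank",
            "extant_end_rank",
            "retained_count",
        ],
    )


def retention_frame(retentions: Sequence[GeneRetention]) -> pd.DataFrame:
    rows = [
        {
            "ancestral_gene_id": r.anc_id,
            "class": r.retention_class,
            "extant_copies": ",".join(g for _l, g in r.copies) or ".",
        }
        for r in retentions
    ]
    return pd.DataFrame(rows, columns=["ancestral_gene_id", "class", "extant_copies"])
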