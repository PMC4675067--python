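"""Readers and writers for the plain-text formats of record.

Gene-order TSV (one species per file)::

    species  chromosome  gene_id  start_bp  end_bp  strand  family_id

with ``#`` comment lines; centromere positions travel as structured comments
``#CENTROMERE <chromosome> <gap_index>`` (1-based gap index: number of genes
on the left arm).

CAR TSV (one ancestor per file)::

    node  record_type  container_id  rank  ancestral_gene_id  strand  descendant_gene_ids

where record_type is PROTOCHR, SMALL_CAR or SINGLETON, rank is 1-based within
the container, strand is "+"/"-", and descendant_gene_ids is a comma-separated
list of ``species|gene_id`` tokens ("." if absent).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

import pandas as pd

from .model import (
    CAR,
    AncestralKaryotype,
    Gene,
    GeneFamilies,
    Genome,
    InputError,
    InteractionNetwork,
    Protochromosome,
    SpeciesTree,
)

GENE_ORDER_COLUMNS = [
    "species",
    "chromosome",
    "gene_id",
    "start_bp",
    "end_bp",
    "strand",
    "family_id",
]

_STRAND_TO_INT = {"+": 1, "-": -1}
_INT_TO_STRAND = {1: "+", -1: "-"}


# --------------------------------------------------------------------------
# Gene orders
# --------------------------------------------------------------------------

def read_gene_orders(path) -> Genome:
    """Read one species' gene order from TSV; ranks are assigned in bp order."""
    path = Path(path)
    centromeres: Dict[str, int] = {}
    rows: List[dict] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split("\t")
                if parts and parts[0] == "CENTROMERE":
                    if len(parts) != 3:
                        raise InputError(
                            f"{path}:{lineno}: malformed CENTROMERE comment"
                        )
                    centromeres[parts[1]] = int(parts[2])
                continue
            fields = line.split("\t")
            if fields == GENE_ORDER_COLUMNS:
                continue  # optional header
            if len(fields) != len(GENE_ORDER_COLUMNS):
                raise InputError(
                    f"{path}:{lineno}: expected {len(GENE_ORDER_COLUMNS)} "
                    f"tab-separated fields, got {len(fields)}"
                )
            rec = dict(zip(GENE_ORDER_COLUMNS, fields))
            if rec["strand"] not in _STRAND_TO_INT:
                raise InputError(
                    f"{path}:{lineno}: unknown strand token {rec['strand']!r}"
                )
            rec["_lineno"] = lineno
            rows.append(rec)
    if not rows:
        raise InputError(f"{path}: no gene records")
    species = {r["species"] for r in rows}
    if len(species) != 1:
        raise InputError(f"{path}: expected one species per file, found {sorted(species)}")
    (species_name,) = species

    seen: Set[str] = set()
    per_chrom: Dict[str, List[dict]] = {}
    for r in rows:
        if r["gene_id"] in seen:
            raise InputError(f"{path}: duplicate gene_id {r['gene_id']!r}")
        seen.add(r["gene_id"])
        per_chrom.setdefault(r["chromosome"], []).append(r)

    chromosomes: Dict[str, List[Gene]] = {}
    for chrom, recs in per_chrom.items():
        recs.sort(key=lambda r: (int(r["start_bp"]), r["gene_id"]))
        chromosomes[chrom] = [
            Gene(
                gene_id=r["gene_id"],
                family_id=r["family_id"],
                chromosome=chrom,
                rank=i,
                strand=_STRAND_TO_INT[r["strand"]],
                start_bp=int(r["start_bp"]),
                end_bp=int(r["end_bp"]),
            )
            for i, r in enumerate(recs)
        ]
    return Genome(species_name, chromosomes, centromeres)


def write_gene_orders(genome: Genome, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(GENE_ORDER_COLUMNS) + "\n")
        for chrom in sorted(genome.centromeres):
            fh.write(f"#CENTROMERE\t{chrom}\t{genome.centromeres[chrom]}\n")
        for chrom in genome.chromosomes:
            for g in genome.chromosomes[chrom]:
                start = g.start_bp if g.start_bp is not None else (g.rank + 1) * 1000
                end = g.end_bp if g.end_bp is not None else start + 500
                fh.write(
                    "\t".join(
                        [
                            genome.species,
                            chrom,
                            g.gene_id,
                            str(start),
                            str(end),
                            _INT_TO_STRAND[g.strand],
                            g.family_id,
                        ]
                    )
                    + "\n"
                )


# --------------------------------------------------------------------------
# Gene families
# --------------------------------------------------------------------------

def read_families(path) -> GeneFamilies:
    """TSV with columns family_id, species, gene_id."""
    df = pd.read_csv(
        path, sep="\t", comment="#", names=["family_id", "species", "gene_id"],
        dtype=str, header=None,
    )
    if len(df) and list(df.iloc[0]) == ["family_id", "species", "gene_id"]:
        df = df.iloc[1:]
    members: Dict[str, Dict[str, List[str]]] = {}
    for fam, sp, gid in df.itertuples(index=False):
        members.setdefault(fam, {}).setdefault(sp, []).append(gid)
    return GeneFamilies(members)


def write_families(families: GeneFamilies, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("family_id\tspecies\tgene_id\n")
        for fam in sorted(families.members):
            for sp in sorted(families.members[fam]):
                for gid in families.members[fam][sp]:
                    fh.write(f"{fam}\t{sp}\t{gid}\n")


# --------------------------------------------------------------------------
# Trees
# --------------------------------------------------------------------------

def read_newick(path) -> SpeciesTree:
    return SpeciesTree.from_newick(Path(path).read_text())


def write_newick(tree: SpeciesTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# --------------------------------------------------------------------------
# Ancestral karyotypes (CAR TSV)
# --------------------------------------------------------------------------

CAR_COLUMNS = [
    "node",
    "record_type",
    "container_id",
    "rank",
    "ancestral_gene_id",
    "strand",
    "descendant_gene_ids",
]


def _format_descendants(
    descendant_map: Optional[Dict[str, Dict[str, List[str]]]], anc_gene: str
) -> str:
    if not descendant_map or anc_gene not in descendant_map:
        return "."
    tokens = []
    for sp in sorted(descendant_map[anc_gene]):
        for gid in descendant_map[anc_gene][sp]:
            tokens.append(f"{sp}|{gid}")
    return ",".join(tokens) if tokens else "."


def write_karyotype(
    karyotype: AncestralKaryotype,
    path,
    descendant_map: Optional[Dict[str, Dict[str, List[str]]]] = None,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(CAR_COLUMNS) + "\n")
        for pc in karyotype.protochromosomes:
            for rank, (gene, strand) in enumerate(pc.genes(), start=1):
                fh.write(
                    "\t".join(
                        [
                            karyotype.node,
                            "PROTOCHR",
                            pc.pc_id,
                            str(rank),
                            gene,
                            _INT_TO_STRAND[strand],
                            _format_descendants(descendant_map, gene),
                        ]
                    )
                    + "\n"
                )
        for car in karyotype.small_cars:
            for rank, (gene, strand) in enumerate(car.genes, start=1):
                fh.write(
                    "\t".join(
                        [
                            karyotype.node,
                            "SMALL_CAR",
                            car.car_id,
                            str(rank),
                            gene,
                            _INT_TO_STRAND[strand],
                            _format_descendants(descendant_map, gene),
                        ]
                    )
                    + "\n"
                )
        for gene in sorted(karyotype.singletons):
            fh.write(
                "\t".join(
                    [
                        karyotype.node,
                        "SINGLETON",
                        ".",
                        "1",
                        gene,
                        "+",
                        _format_descendants(descendant_map, gene),
                    ]
                )
                + "\n"
            )


def read_karyotype(path) -> AncestralKaryotype:
    """Read a CAR TSV.

    Protochromosomes come back as a single gene-level CAR each (the member-CAR
    boundaries of the writer are not serialized); writing the result again
    yields a byte-identical file.
    """
    path = Path(path)
    node: Optional[str] = None
    protochrom: Dict[str, List[Tuple[int, str, int]]] = {}
    small: Dict[str, List[Tuple[int, str, int]]] = {}
    singletons: Set[str] = set()
    membership: Set[str] = set()

    def claim(gene: str) -> None:
        if gene in membership:
            raise InputError(
                f"{path}: ancestral gene {gene!r} occurs in more than one record group"
            )
        membership.add(gene)

    with path.open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row == CAR_COLUMNS:
                continue
            if len(row) != len(CAR_COLUMNS):
                raise InputError(f"{path}: malformed CAR record {row!r}")
            nd, rtype, container, rank, gene, strand, _desc = row
            if node is None:
                node = nd
            elif nd != node:
                raise InputError(f"{path}: mixed ancestor nodes {node!r} and {nd!r}")
            if strand not in _STRAND_TO_INT:
                raise InputError(f"{path}: unknown strand token {strand!r}")
            s = _STRAND_TO_INT[strand]
            if rtype == "PROTOCHR":
                claim(gene)
                protochrom.setdefault(container, []).append((int(rank), gene, s))
            elif rtype == "SMALL_CAR":
                claim(gene)
                small.setdefault(container, []).append((int(rank), gene, s))
            elif rtype == "SINGLETON":
                claim(gene)
                singletons.add(gene)
            else:
                raise InputError(f"{path}: unknown record_type {rtype!r}")
    if node is None:
        raise InputError(f"{path}: empty karyotype file")

    protochromosomes = []
    for pc_id in protochrom:
        recs = sorted(protochrom[pc_id])
        car = CAR(pc_id, node, [(g, s) for _, g, s in recs])
        protochromosomes.append(Protochromosome(pc_id, node, [(car, 1)]))
    small_cars = []
    for car_id in small:
        recs = sorted(small[car_id])
        small_cars.append(CAR(car_id, node, [(g, s) for _, g, s in recs]))
    k = AncestralKaryotype(node, protochromosomes, small_cars, singletons)
    k.validate_partition()
    return k


# --------------------------------------------------------------------------
# Ortholog maps and interaction networks
# --------------------------------------------------------------------------

def read_ortholog_map(path) -> Dict[str, Dict[str, List[str]]]:
    """TSV ancestral_gene_id, species, gene_id -> nested dict."""
    out: Dict[str, Dict[str, List[str]]] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields == ["ancestral_gene_id", "species", "gene_id"]:
                continue
            anc, sp, gid = fields
            out.setdefault(anc, {}).setdefault(sp, []).append(gid)
    return out


def write_ortholog_map(omap: Dict[str, Dict[str, List[str]]], path) -> None:
    with Path(path).open("w") as fh:
        fh.write("ancestral_gene_id\tspecies\tgene_id\n")
        for anc in sorted(omap):
            for sp in sorted(omap[anc]):
                for gid in omap[anc][sp]:
                    fh.write(f"{anc}\t{sp}\t{gid}\n")


def read_interactions(path) -> InteractionNetwork:
    edges = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields == ["gene_a", "gene_b"]:
                continue
            a, b = fields[:2]
            edges.append((a, b))
    return InteractionNetwork(edges)


# --------------------------------------------------------------------------
# GFF3 convenience converter
# --------------------------------------------------------------------------

def gff3_to_gene_orders(gff_path, species: str, out_tsv, family_attr: str = "family") -> None:
    """Convert gene features of a GFF3 file to the canonical gene-order TSV.

    Only ``gene`` features are used; the GFF3 ``ID`` attribute becomes the
    gene_id and the attribute named by ``family_attr`` (default ``family``)
    the family_id (falling back to the gene_id when absent, i.e., one
    single-member family per gene).
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", force=True
    )
    with Path(out_tsv).open("w") as fh:
        fh.write("\t".join(GENE_ORDER_COLUMNS) + "\n")
        for feat in db.features_of_type("gene", order_by=("seqid", "start")):
            gid = feat.attributes.get("ID", [feat.id])[0]
            fam = feat.attributes.get(family_attr, [gid])[0]
            strand = feat.strand if feat.strand in ("+", "-") else "+"
            fh.write(
                "\t".join(
                    [species, feat.seqid, gid, str(feat.start), str(feat.end), strand, fam]
                )
                + "\n"
            )
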