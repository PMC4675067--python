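"""Ancestral gene content by Dollo parsimony, and branch-wise gain/loss.

A gene family is assumed to arise once on the tree (single origin) and to be
lost independently any number of times.  Under that model the nodes at which
the family was present form exactly the minimal spanning (Steiner) subtree
connecting the leaves that still carry members.  Ancestral copy number is
fixed at one per family per node; post-polyploidy multiplicity is handled
downstream through ortholog maps, not here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .model import GeneFamilies, Genome, InputError, SpeciesTree, TreeNode


def dollo_presence(tree: SpeciesTree, leaf_set: Set[str]) -> Set[TreeNode]:
    """Nodes of the minimal spanning subtree connecting ``leaf_set``.

    This is the Dollo-parsimony presence set: a single origin at the MRCA with
    the fewest possible losses below it.
    """
    if not leaf_set:
        raise InputError("dollo_presence: empty leaf set")
    leaf_nodes = []
    for name in sorted(leaf_set):
        node = tree.node(name)
        if not node.is_leaf:
            raise InputError(f"{name!r} is not a leaf of the tree")
        leaf_nodes.append(node)

    mrca = tree.mrca(sorted(leaf_set))
    present: Set[TreeNode] = set()
    for leaf in leaf_nodes:
        node: Optional[TreeNode] = leaf
        while node is not None and node not in present:
            present.add(node)
            if node is mrca:
                break
            node = node.parent
    return present


@dataclass
class AncestralGeneSet:
    """Inferred gene content at one ancestor.

    One ancestral gene per present family, named ``<family_id>@<node>``.
    ``descendant_map`` lists the extant family members per species -- for all
    species carrying the family, including species outside the node's subtree,
    so that outgroup genomes can be reduced through the same content set.
    """

    node: str
    genes: Set[str]
    descendant_map: Dict[str, Dict[str, List[str]]]
    family_of: Dict[str, str] = field(default_factory=dict)

    def extant_to_ancestral(self, species: str) -> Dict[str, str]:
        out: Dict[str, str] = {}
        for anc, per_species in self.descendant_map.items():
            for gid in per_species.get(species, ()):
                out[gid] = anc
        return out

    @property
    def families(self) -> Set[str]:
        return set(self.family_of.values())


def ancestral_gene_set(
    tree: SpeciesTree, families: GeneFamilies, node_name: str
) -> AncestralGeneSet:
    """Infer which families existed at ``node_name`` (Dollo parsimony)."""
    target = tree.node(node_name)
    if target.is_leaf:
        raise InputError(f"{node_name!r} is a leaf, not an ancestor")
    tree_leaves = set(tree.leaf_names)

    genes: Set[str] = set()
    descendant_map: Dict[str, Dict[str, List[str]]] = {}
    family_of: Dict[str, str] = {}
    # Cache presence per leaf pattern: many families share a pattern.
    cache: Dict[FrozenSet[str], bool] = {}
    for fam in sorted(families.members):
        species = frozenset(families.species_with_members(fam) & tree_leaves)
        if not species:
            continue
        present = cache.get(species)
        if present is None:
            present = target in dollo_presence(tree, set(species))
            cache[species] = present
        if present:
            anc = f"{fam}@{node_name}"
            genes.add(anc)
            family_of[anc] = fam
            descendant_map[anc] = {
                sp: list(gids)
                for sp, gids in sorted(families.members[fam].items())
                if gids
            }
    return AncestralGeneSet(node_name, genes, descendant_map, family_of)


def branch_gain_loss(parent: Set[str], child: Set[str]) -> Tuple[int, int]:
    """(gains, losses) between two gene sets in the same identity space."""
    return len(child - parent), len(parent - child)


def _families_at(
    tree: SpeciesTree,
    families: GeneFamilies,
    node: TreeNode,
    cache: Dict[int, Set[str]],
) -> Set[str]:
    if id(node) in cache:
        return cache[id(node)]
    tree_leaves = set(tree.leaf_names)
    if node.is_leaf:
        fams = {
            fam
            for fam in families.members
            if families.members[fam].get(node.name)
        }
    else:
        fams = set()
        for fam in families.members:
            species = families.species_with_members(fam) & tree_leaves
            if species and node in dollo_presence(tree, species):
                fams.add(fam)
    cache[id(node)] = fams
    return fams


def gain_loss_report(tree: SpeciesTree, families: GeneFamilies) -> pd.DataFrame:
    """Per-branch gene gains/losses (family-lineage identity) and rates.

    Gains above the root cannot be placed by Dollo parsimony; they are
    reported on a synthetic ``origin -> <root>`` row.
    """
    cache: Dict[int, Set[str]] = {}
    rows = []
    root = tree.root
    root_fams = _families_at(tree, families, root, cache)
    rows.append(
        {
            "parent": "origin",
            "child": root.name or "root",
            "gains": len(root_fams),
            "losses": 0,
            "duration_my": None,
        }
    )
    for parent, child in tree.branches():
        pset = _families_at(tree, families, parent, cache)
        cset = _families_at(tree, families, child, cache)
        gains, losses = branch_gain_loss(pset, cset)
        rows.append(
            {
                "parent": parent.name or "root",
                "child": child.name or "?",
                "gains": gains,
                "losses": losses,
                "duration_my": child.length,
            }
        )
    df = pd.DataFrame(rows)
    df["gain_rate"] = df.apply(
        lambda r: r["gains"] / r["duration_my"] if r["duration_my"] else None, axis=1
    )
    df["loss_rate"] = df.apply(
        lambda r: r["losses"] / r["duration_my"] if r["duration_my"] else None, axis=1
    )
    return df


def write_gain_loss_report(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
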