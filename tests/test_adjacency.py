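"""Informative pairs, genome reduction, and conserved oriented adjacencies."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleokaryo.adjacency import (
    AdjacencyGraph,
    ReducedGenome,
    build_adjacency_graph,
    canonical_adjacency,
    conserved_adjacencies,
    informative_pairs,
    reduce_to_ancestral,
)
from paleokaryo.content import ancestral_gene_set
from paleokaryo.model import InputError, SpeciesTree

SIX_TAXON = "(((((At,Al)A1,Cr)ACK,(Br,Tp)PCK)ABK,Out))Root;"


def chromosome(genes):
    return ReducedGenome("X", {"chr1": genes})


class TestCanonicalization:
    def test_reverse_reading_is_same_adjacency(self):
        assert canonical_adjacency("a", 1, "b", 1) == canonical_adjacency("b", -1, "a", -1)
        assert canonical_adjacency("c", -1, "b", -1) == canonical_adjacency("b", 1, "c", 1)

    @given(
        u=st.sampled_from("abcd"),
        v=st.sampled_from("efgh"),
        su=st.sampled_from([1, -1]),
        sv=st.sampled_from([1, -1]),
    )
    @settings(max_examples=64, derandomize=True)
    def test_involution_and_idempotence(self, u, v, su, sv):
        c = canonical_adjacency(u, su, v, sv)
        assert canonical_adjacency(*c) == c
        assert canonical_adjacency(c[2], -c[3], c[0], -c[1]) == c


class TestInformativePairs:
    def test_cherry(self):
        tree = SpeciesTree.from_newick("(A,B)R;")
        assert informative_pairs(tree, "R") == [("A", "B")]

    def test_six_taxon_root_side_count(self):
        tree = SpeciesTree.from_newick(SIX_TAXON)
        pairs = informative_pairs(tree, "ABK")
        # oracle: enumerate all leaf pairs, keep those whose path crosses ABK
        assert len(pairs) == 11
        assert ("At", "Br") in pairs and ("Al", "Out") in pairs
        assert ("At", "Al") not in pairs

    def test_nested_node_with_outside_leaves(self):
        tree = SpeciesTree.from_newick("(((At,Al)A1,Cr)ACK,(Br,Tp)PCK)ABK;")
        pairs = set(informative_pairs(tree, "A1"))
        expected = {("Al", "At")} | {
            tuple(sorted((a, b)))
            for a in ("At", "Al")
            for b in ("Cr", "Br", "Tp")
        }
        assert pairs == expected and len(pairs) == 7

    def test_leaf_rejected(self):
        tree = SpeciesTree.from_newick("(A,B)R;")
        with pytest.raises(InputError):
            informative_pairs(tree, "A")

    def test_matches_path_membership_oracle(self, brassica_tree):
        """Pair selection equals brute-force path-crossing for every node."""
        tree = brassica_tree
        leaves = tree.leaf_names
        for node_name in tree.internal_names:
            target = tree.node(node_name)
            expected = set()
            for i, a in enumerate(leaves):
                for b in leaves[i + 1 :]:
                    # path a..b = a..mrca..b
                    path = set()
                    for leaf in (a, b):
                        n = tree.node(leaf)
                        mrca = tree.mrca([a, b])
                        while n is not mrca:
                            path.add(n)
                            n = n.parent
                        path.add(mrca)
                    if target in path:
                        expected.add(tuple(sorted((a, b))))
            assert set(informative_pairs(tree, node_name)) == expected


class TestConservedAdjacencies:
    def test_identical_single_chromosome(self):
        g = chromosome([("a", 1), ("b", 1), ("c", 1), ("d", 1)])
        assert conserved_adjacencies(g, g) == {
            canonical_adjacency("a", 1, "b", 1),
            canonical_adjacency("b", 1, "c", 1),
            canonical_adjacency("c", 1, "d", 1),
        }

    def test_inversion_preserves_only_internal_adjacency(self):
        ga = chromosome([("a", 1), ("b", 1), ("c", 1), ("d", 1)])
        gb = chromosome([("a", 1), ("c", -1), ("b", -1), ("d", 1)])
        assert conserved_adjacencies(ga, gb) == {canonical_adjacency("b", 1, "c", 1)}

    def test_orientation_must_be_conserved(self):
        ga = chromosome([("a", 1), ("b", 1)])
        gb = chromosome([("a", 1), ("b", -1)])
        assert conserved_adjacencies(ga, gb) == set()

    def test_counts_once_per_pair_despite_multiplicity(self):
        ga = ReducedGenome(
            "X", {"c1": [("u", 1), ("v", 1)], "c2": [("u", 1), ("v", 1)]}
        )
        gb = chromosome([("u", 1), ("v", 1)])
        graph = AdjacencyGraph()
        for adj in conserved_adjacencies(ga, gb):
            graph.add_support(adj)
        assert graph.edges[canonical_adjacency("u", 1, "v", 1)] == 1


class TestReduction:
    def test_drops_unmapped_and_keeps_order(self, quiet_dataset):
        content = ancestral_gene_set(quiet_dataset.tree, quiet_dataset.families, "ABK")
        genome = quiet_dataset.genomes["At"]
        reduced = reduce_to_ancestral(genome, content)
        # zero-rate run: every gene is ancestral, order preserved
        for chrom, genes in genome.chromosomes.items():
            assert len(reduced.chromosomes[chrom]) == len(genes)

    def test_multiplicity_preserved_in_polyploid(self, busy_dataset):
        content = ancestral_gene_set(busy_dataset.tree, busy_dataset.families, "PCK")
        reduced = reduce_to_ancestral(busy_dataset.genomes["Br"], content)
        from collections import Counter

        counts = Counter(g for genes in reduced.chromosomes.values() for g, _s in genes)
        assert max(counts.values()) >= 2  # triplicated ancestral genes survive

    def test_empty_intersection_gives_empty_reduction(self, quiet_dataset):
        content = ancestral_gene_set(quiet_dataset.tree, quiet_dataset.families, "ABK")
        from paleokaryo.model import Gene, Genome

        alien = Genome(
            "At",  # right species name, but unknown genes
            {"chr9": [Gene("zz1", "zfam", "chr9", 0, 1)]},
        )
        assert reduce_to_ancestral(alien, content).n_occurrences == 0


class TestGraph:
    def test_weight_bounded_by_informative_pairs(self, busy_dataset):
        content = ancestral_gene_set(busy_dataset.tree, busy_dataset.families, "ABK")
        graph = build_adjacency_graph(
            busy_dataset.tree, "ABK", busy_dataset.genomes, content
        )
        assert graph.n_pairs == 11
        assert graph.max_weight <= graph.n_pairs
        assert all(w >= 1 for w in graph.edges.values())

    def test_zero_rearrangement_graph_is_union_of_paths(self, quiet_dataset):
        content = ancestral_gene_set(quiet_dataset.tree, quiet_dataset.families, "ABK")
        graph = build_adjacency_graph(
            quiet_dataset.tree, "ABK", quiet_dataset.genomes, content
        )
        degree = {}
        for (u, _su, v, _sv) in graph.edges:
            degree[u] = degree.get(u, 0) + 1
            degree[v] = degree.get(v, 0) + 1
        assert max(degree.values()) <= 2
        # one path per root chromosome: edges = genes - chromosomes
        root = quiet_dataset.root_genome
        assert len(graph.edges) == root.n_genes - root.n_chromosomes
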