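"""Contig-order round, scaffolding and the orchestrated reconstruction."""

import pytest

from paleokaryo.adjacency import ReducedGenome
from paleokaryo.content import ancestral_gene_set
from paleokaryo.model import CAR
from paleokaryo.scaffold import _tokenize, _car_index, contig_round, reconstruct_karyotype


class TestTokenization:
    def test_runs_collapse_with_majority_orientation(self):
        cars = [
            CAR("c1", "N", [("a", 1), ("b", 1), ("c", 1)]),
            CAR("c2", "N", [("d", 1), ("e", 1)]),
        ]
        index = _car_index(cars)
        rg = ReducedGenome(
            "X",
            {
                "chr1": [("c", -1), ("b", -1), ("a", -1), ("d", 1), ("e", 1)],
                "chr2": [("b", 1)],
            },
        )
        tokens = _tokenize(rg, index)
        assert tokens.chromosomes["chr1"] == [("c1", -1), ("c2", 1)]
        # single-gene run: tie -> forward
        assert tokens.chromosomes["chr2"] == [("c1", 1)]

    def test_non_car_genes_dropped_before_tokenizing(self):
        cars = [CAR("c1", "N", [("a", 1), ("b", 1)])]
        index = _car_index(cars)
        rg = ReducedGenome("X", {"chr1": [("a", 1), ("zz", 1), ("b", 1)]})
        tokens = _tokenize(rg, index)
        # the interrupting singleton does not split the run
        assert tokens.chromosomes["chr1"] == [("c1", 1)]


class TestContigRound:
    def two_car_setup(self, order_b):
        """Two CARs; genomes agree on a-b-c-d order (or a permuted one)."""
        from paleokaryo.model import GeneFamilies, SpeciesTree

        tree = SpeciesTree.from_newick("(X,Y)R;")
        fams = {
            g: {"X": [f"X.{g}"], "Y": [f"Y.{g}"]} for g in ("a", "b", "c", "d")
        }
        families = GeneFamilies(fams)
        content = ancestral_gene_set(tree, families, "R")

        def genome(species, order):
            from paleokaryo.model import Gene, Genome

            genes = [
                Gene(f"{species}.{g}", g, "chr1", i, s)
                for i, (g, s) in enumerate(order)
            ]
            return Genome(species, {"chr1": genes})

        order_a = [("a", 1), ("b", 1), ("c", 1), ("d", 1)]
        genomes = {"X": genome("X", order_a), "Y": genome("Y", order_b)}
        cars = [
            CAR("car1", "R", [("a@R", 1), ("b@R", 1)]),
            CAR("car2", "R", [("c@R", 1), ("d@R", 1)]),
        ]
        return cars, tree, genomes, content

    def test_conserved_contig_order_is_spliced(self):
        cars, tree, genomes, content = self.two_car_setup(
            [("a", 1), ("b", 1), ("c", 1), ("d", 1)]
        )
        merged = contig_round(cars, tree, "R", genomes, content)
        assert len(merged) == 1
        assert merged[0].genes == [("a@R", 1), ("b@R", 1), ("c@R", 1), ("d@R", 1)]

    def test_opposite_relative_order_is_not_conserved(self):
        # genome Y shows C2 then C1 in forward orientation: canonically that
        # is (C1-, C2-), which genome X (C1+, C2+) does not support
        cars, tree, genomes, content = self.two_car_setup(
            [("c", 1), ("d", 1), ("a", 1), ("b", 1)]
        )
        merged = contig_round(cars, tree, "R", genomes, content)
        assert sorted(len(c) for c in merged) == [2, 2]

    def test_zero_rate_simulation_recovers_whole_chromosomes(self, quiet_dataset):
        content = ancestral_gene_set(quiet_dataset.tree, quiet_dataset.families, "ABK")
        from paleokaryo.adjacency import build_adjacency_graph
        from paleokaryo.linearize import linearize_graph

        graph = build_adjacency_graph(
            quiet_dataset.tree, "ABK", quiet_dataset.genomes, content
        )
        cars1, _ = linearize_graph(graph, node="ABK")
        merged = contig_round(cars1, quiet_dataset.tree, "ABK", quiet_dataset.genomes, content)
        root = quiet_dataset.root_genome
        assert sorted(len(c) for c in merged) == sorted(
            len(v) for v in root.chromosomes.values()
        )


class TestReconstruction:
    def test_identical_genomes_reproduce_input_karyotype(self, quiet_dataset):
        k, summary = reconstruct_karyotype(
            quiet_dataset.tree, "ABK", quiet_dataset.genomes,
            families=quiet_dataset.families, min_car_size=10,
        )
        root = quiet_dataset.root_genome
        assert len(k.protochromosomes) == root.n_chromosomes
        assert not k.small_cars and not k.singletons
        chrom_sizes = sorted(len(pc.gene_ids()) for pc in k.protochromosomes)
        assert chrom_sizes == sorted(len(v) for v in root.chromosomes.values())

    def test_partition_invariant(self, busy_dataset):
        k, _ = reconstruct_karyotype(
            busy_dataset.tree, "ABK", busy_dataset.genomes,
            families=busy_dataset.families,
        )
        k.validate_partition()
        content = ancestral_gene_set(busy_dataset.tree, busy_dataset.families, "ABK")
        assert k.total_protogenes == content.genes

    def test_min_size_threshold_is_monotone(self, busy_dataset):
        """Lowering the protochromosome size threshold can only move genes
        into the ordered set, never out of it."""
        k50, _ = reconstruct_karyotype(
            busy_dataset.tree, "PCK", busy_dataset.genomes,
            families=busy_dataset.families, min_car_size=50,
        )
        k2, _ = reconstruct_karyotype(
            busy_dataset.tree, "PCK", busy_dataset.genomes,
            families=busy_dataset.families, min_car_size=2,
        )
        assert len(k2.ordered_protogenes) >= len(k50.ordered_protogenes)
        # a 49-gene CAR can never sit in a protochromosome at min_size 50
        for pc in k50.protochromosomes:
            for car, _o in pc.cars:
                assert len(car) >= 50

    def test_deterministic_car_files(self, busy_dataset, tmp_path):
        from paleokaryo import io as pio

        for run in (1, 2):
            k, _ = reconstruct_karyotype(
                busy_dataset.tree, "ACK", busy_dataset.genomes,
                families=busy_dataset.families,
            )
            pio.write_karyotype(k, tmp_path / f"k{run}.tsv")
        assert (tmp_path / "k1.tsv").read_bytes() == (tmp_path / "k2.tsv").read_bytes()
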