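"""Windowed LF/MF1/MF2 assignment, retention classes, exchanges, networks."""

from collections import Counter

import pytest

from paleokaryo.fractionation import (
    LABELS,
    assign_subgenome_windows,
    connectivity_fraction,
    copies_by_class,
    dominance_exchanges,
    retention_classes,
)
from paleokaryo.model import (
    CAR,
    AncestralKaryotype,
    Gene,
    Genome,
    InputError,
    InteractionNetwork,
    Protochromosome,
)


def toy_karyotype(n_genes, window_chr="anc1"):
    genes = [(f"a{i:03d}", 1) for i in range(n_genes)]
    car = CAR(window_chr, "ANC", genes)
    return AncestralKaryotype(
        "ANC", [Protochromosome(window_chr, "ANC", [(car, 1)])], [], set()
    )


def extant_genome(placements):
    """placements: {chrom: [gene ids in order]} -> Genome."""
    chromosomes = {}
    for chrom, gids in placements.items():
        chromosomes[chrom] = [
            Gene(g, g, chrom, i, 1) for i, g in enumerate(gids)
        ]
    return Genome("poly", chromosomes)


class TestWindowAssignment:
    def test_counting_example(self):
        """Six ancestral genes; clusters of 5/3/1 orthologs on three extant
        chromosomes get LF/MF1/MF2 in descending retained order."""
        k = toy_karyotype(6)
        genome = extant_genome(
            {
                "chr1": [f"c1.{i}" for i in range(5)],
                "chr2": [f"c2.{i}" for i in range(3)],
                "chr3": ["c3.0"],
            }
        )
        omap = {f"a{i:03d}": [f"c1.{i}"] for i in range(5)}
        for i in range(3):
            omap.setdefault(f"a{i:03d}", []).append(f"c2.{i}")
        omap["a000"].append("c3.0")
        smap = assign_subgenome_windows(k, genome, omap, window=6, gap=10)
        (win,) = smap.windows
        by_label = {r.label: r for r in win.regions if r.label}
        assert by_label["LF"].extant_chr == "chr1" and by_label["LF"].retained == 5
        assert by_label["MF1"].extant_chr == "chr2" and by_label["MF1"].retained == 3
        assert by_label["MF2"].extant_chr == "chr3" and by_label["MF2"].retained == 1

    def test_unfractionated_triplication_ties_break_by_chromosome_name(self):
        k = toy_karyotype(4)
        genome = extant_genome(
            {s: [f"{s}.{i}" for i in range(4)] for s in ("chrA", "chrB", "chrC")}
        )
        omap = {
            f"a{i:03d}": [f"chrA.{i}", f"chrB.{i}", f"chrC.{i}"] for i in range(4)
        }
        smap = assign_subgenome_windows(k, genome, omap, window=4, gap=10)
        (win,) = smap.windows
        labels = {r.extant_chr: r.label for r in win.regions}
        assert labels == {"chrA": "LF", "chrB": "MF1", "chrC": "MF2"}

    def test_window_below_two_rejected(self):
        k = toy_karyotype(4)
        genome = extant_genome({"chr1": ["x"]})
        with pytest.raises(InputError):
            assign_subgenome_windows(k, genome, {}, window=1, gap=10)

    def test_gap_splits_clusters_on_same_chromosome(self):
        k = toy_karyotype(4)
        # orthologs on one chromosome but in two distant clusters: the two
        # clusters compete independently
        genome = extant_genome({"chr1": [f"g{i}" for i in range(200)]})
        omap = {
            "a000": ["g0"], "a001": ["g1"],
            "a002": ["g150"], "a003": ["g151"],
        }
        smap = assign_subgenome_windows(k, genome, omap, window=4, gap=50)
        (win,) = smap.windows
        assert len(win.regions) == 2
        assert all(r.retained == 2 for r in win.regions)

    def test_label_count_ordering_invariant(self, busy_dataset):
        ds = busy_dataset
        true_k = ds.true_karyotype("PCK")
        omap = {
            anc: gids
            for anc, per_sp in ds.ortholog_map_all("PCK").items()
            for sp, gids in per_sp.items()
            if sp == "Br"
        }
        smap = assign_subgenome_windows(true_k, ds.genomes["Br"], omap)
        smap.check_label_ordering()
        for w in smap.windows:
            counts = [r.retained for r in w.regions if r.label]
            assert counts == sorted(counts, reverse=True)


class TestRetentionClasses:
    def setup_map(self):
        k = toy_karyotype(6)
        genome = extant_genome(
            {
                "chr1": [f"c1.{i}" for i in range(6)],
                "chr2": [f"c2.{i}" for i in range(4)],
                "chr3": [f"c3.{i}" for i in range(2)],
            }
        )
        omap = {
            "a000": ["c1.0", "c2.0", "c3.0"],   # triplet
            "a001": ["c1.1", "c3.1"],            # LF-MF2 pair
            "a002": ["c1.2", "c2.1"],            # LF-MF1 pair
            "a003": ["c2.2"],                    # MF1 singleton
            "a004": ["c1.3"],                    # LF singleton
            "a005": [],                          # lost
        }
        smap = assign_subgenome_windows(k, genome, omap, window=6, gap=10)
        return smap, omap

    def test_classification(self):
        smap, omap = self.setup_map()
        counts, retentions = retention_classes(smap, omap)
        by_gene = {r.anc_id: r.retention_class for r in retentions}
        assert by_gene == {
            "a000": "triplet",
            "a001": "LF-MF2",
            "a002": "LF-MF1",
            "a003": "MF1",
            "a004": "LF",
            "a005": "lost",
        }
        assert sum(counts.values()) == 6  # partition of the ancestral set

    def test_simulated_truth_table(self, busy_dataset):
        """Class counts agree with the simulator's per-copy survival truth."""
        ds = busy_dataset
        hx = ds.hex_truth
        true_k = ds.true_karyotype("PCK")
        omap = {
            anc: gids
            for anc, per_sp in ds.ortholog_map_all("PCK").items()
            for sp, gids in per_sp.items()
            if sp == "Br"
        }
        smap = assign_subgenome_windows(true_k, ds.genomes["Br"], omap)
        counts, retentions = retention_classes(smap, omap)
        # "lost" must mean exactly: no extant descendant in the polyploid
        # (copies may die yet leave post-triplication tandem children, which
        # the descendant closure keeps); a triplet needs >= 3 extant copies.
        for r in retentions:
            descendants = omap.get(r.anc_id, [])
            if r.retention_class == "lost":
                assert not descendants
            else:
                assert descendants
            if r.retention_class == "triplet":
                assert len(descendants) >= 3
        assert counts["lost"] > 0 and counts["triplet"] > 0

    def test_connectivity_fractions(self):
        smap, omap = self.setup_map()
        _counts, retentions = retention_classes(smap, omap)
        classes = copies_by_class(retentions)
        empty_net = InteractionNetwork([])
        fr = connectivity_fraction(classes, empty_net)
        assert fr["triplet"] == 0.0
        full_net = InteractionNetwork(
            [("c1.0", "c2.0"), ("c1.1", "c3.1"), ("c1.2", "c2.1"),
             ("c2.2", "c1.3"), ("c3.0", "c1.0")]
        )
        fr = connectivity_fraction(copies_by_class(retentions), full_net)
        assert fr["triplet"] == 1.0
        one_third = connectivity_fraction(
            {"cls": ["g1", "g2", "g3"]}, InteractionNetwork([("g1", "g9")])
        )
        assert one_third["cls"] == pytest.approx(1 / 3)
        assert connectivity_fraction({"none": []}, empty_net)["none"] is None


class TestDominanceExchanges:
    def two_window_map(self, swap_second):
        k = toy_karyotype(8)
        genome = extant_genome(
            {
                "chrL": [f"L{i}" for i in range(8)],
                "chrM1": [f"m{i}" for i in range(8)],
                "chrM2": [f"n{i}" for i in range(8)],
            }
        )
        omap = {}
        for i in range(8):
            anc = f"a{i:03d}"
            copies = [f"L{i}"]
            # LF keeps everything; MF1 keeps 3/4; MF2 keeps 1/2
            if i % 4 != 0:
                copies.append(f"m{i}")
            if i % 2 == 0:
                copies.append(f"n{i}")
            omap[anc] = copies
        if swap_second:
            # second window: the chrM1 region thins out, chrM2 fills in
            for i in range(4, 8):
                anc = f"a{i:03d}"
                omap[anc] = [f"L{i}"]
                if i % 2 == 0:
                    omap[anc].append(f"m{i}")
                if i % 4 != 0:
                    omap[anc].append(f"n{i}")
        smap = assign_subgenome_windows(k, genome, omap, window=4, gap=10)
        return smap

    def test_constant_labels_no_exchange(self):
        smap = self.two_window_map(swap_second=False)
        assert dominance_exchanges(smap) == []

    def test_single_swap_detected_with_pair(self):
        smap = self.two_window_map(swap_second=True)
        exchanges = dominance_exchanges(smap)
        assert len(exchanges) == 1
        e = exchanges[0]
        assert (e.label_a, e.label_b) == ("MF1", "MF2")
        assert e.boundary == 1

    def test_simulated_exchanges_found_at_correct_boundaries(self, busy_dataset):
        ds = busy_dataset
        hx = ds.hex_truth
        assert hx is not None and hx.breakpoints
        true_k = ds.true_karyotype("PCK")
        omap = {
            anc: gids
            for anc, per_sp in ds.ortholog_map_all("PCK").items()
            for sp, gids in per_sp.items()
            if sp == "Br"
        }
        smap = assign_subgenome_windows(true_k, ds.genomes["Br"], omap)
        detected = {
            (e.anc_chr.split(".")[-1], e.boundary)
            for e in dominance_exchanges(smap)
            if (e.label_a, e.label_b) == ("MF1", "MF2")
        }
        # map each injected breakpoint (pre-WGD chromosome coordinates) to
        # its nearest window boundary; every one must be found within +-1
        for chrom, pos in hx.breakpoints:
            boundary = round(pos / smap.window_size)
            assert any(
                c == chrom and abs(b - boundary) <= 1 for c, b in detected
            ), (chrom, pos, detected)
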