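"""Forward-simulator operators, ledgers, determinism and replay."""

import numpy as np
import pytest

from paleokaryo.model import InputError
from paleokaryo.simulate import (
    HexaploidySpec,
    SequenceModel,
    SimGene,
    SimGenome,
    SimulationConfig,
    _IdFactory,
    apply_fusion_rta,
    apply_inversion,
    apply_loss,
    replay_events,
    sim_to_genome,
    simulate_dataset,
    triplicate_two_step,
)


def two_chromosome_genome():
    g = SimGenome()
    g.chromosomes["A"] = [SimGene(f"a{i}", f"fa{i}", 1) for i in range(1, 9)]
    g.chromosomes["B"] = [SimGene(f"b{i}", f"fb{i}", 1) for i in range(1, 9)]
    g.centromeres = {"A": 4, "B": 4}
    return g


class TestOperators:
    def test_inversion_reverses_and_flips(self):
        g = two_chromosome_genome()
        apply_inversion(g, "A", 2, 3)
        assert [x.gid for x in g.chromosomes["A"]] == [
            "a1", "a2", "a5", "a4", "a3", "a6", "a7", "a8",
        ]
        assert [x.strand for x in g.chromosomes["A"][2:5]] == [-1, -1, -1]

    def test_inversion_moves_spanned_centromere(self):
        g = two_chromosome_genome()
        apply_inversion(g, "A", 3, 3)  # spans the gap at 4
        assert g.centromeres["A"] == 3 + (6 - 4)

    def test_fusion_rta_conserves_genes_without_collateral(self):
        """Equal-armed worked case: all 16 genes kept, only A's centromere."""
        g = two_chromosome_genome()
        lost = apply_fusion_rta(g, "A", "B", 0)
        assert lost == []
        assert g.n_chromosomes == 1
        fused = [x.gid for x in g.chromosomes["A"]]
        assert fused == [
            "a1", "a2", "a3", "a4", "a5", "a6", "a7", "a8",
            "b4", "b3", "b2", "b1", "b5", "b6", "b7", "b8",
        ]
        assert [x.strand for x in g.chromosomes["A"][8:12]] == [-1, -1, -1, -1]
        assert g.centromeres == {"A": 4}

    def test_fusion_rta_collateral_losses_logged(self):
        g = two_chromosome_genome()
        lost = apply_fusion_rta(g, "A", "B", 2)
        assert len(lost) == 2
        assert g.n_genes == 14

    def test_fusion_requires_two_distinct_centromeric_chromosomes(self):
        g = two_chromosome_genome()
        with pytest.raises(InputError):
            apply_fusion_rta(g, "A", "A", 0)
        apply_fusion_rta(g, "A", "B", 0)
        with pytest.raises(Exception):
            apply_fusion_rta(g, "A", "B", 0)  # B no longer exists

    def test_loss_updates_centromere_gap(self):
        g = two_chromosome_genome()
        apply_loss(g, "a1")
        assert g.centromeres["A"] == 3
        apply_loss(g, "a8")
        assert g.centromeres["A"] == 3


class TestTriplication:
    def ancestor(self, n=300):
        g = SimGenome()
        g.chromosomes["c1"] = [SimGene(f"g{i}", f"f{i}", 1) for i in range(n)]
        g.centromeres["c1"] = n // 2
        return g

    def test_lossless_triplication_makes_perfect_triplets(self):
        g = self.ancestor()
        spec = HexaploidySpec(loss_probs=(0.0, 0.0, 0.0), n_exchanges=0)
        rng = np.random.default_rng(0)
        params, truth, _ = triplicate_two_step(g, spec, rng)
        assert g.n_genes == 900 and g.n_chromosomes == 3
        assert not truth.lost and not truth.breakpoints
        assert all(len(subs) == 3 for subs in truth.copies.values())

    def test_retained_fractions_within_binomial_error(self):
        g = self.ancestor(n=2000)
        g.centromeres["c1"] = 1000
        spec = HexaploidySpec(loss_probs=(0.2, 0.45, 0.6), n_exchanges=0)
        rng = np.random.default_rng(1)
        _params, truth, _ = triplicate_two_step(g, spec, rng)
        survivors = {s: 0 for s in ("LF", "MF1", "MF2")}
        for label in truth.labels.values():
            survivors[label] += 1
        for sub, expected in zip(("LF", "MF1", "MF2"), (0.8, 0.55, 0.4)):
            frac = survivors[sub] / 2000
            sd = np.sqrt(expected * (1 - expected) / 2000)
            assert abs(frac - expected) < 3 * sd

    def test_exchange_blocks_respect_spacing(self):
        g = self.ancestor(n=500)
        spec = HexaploidySpec(n_exchanges=3, min_block_genes=100)
        rng = np.random.default_rng(2)
        _p, truth, _ = triplicate_two_step(g, spec, rng)
        assert len(truth.breakpoints) == 3
        positions = sorted(p for _c, p in truth.breakpoints)
        assert positions[0] >= 100 and positions[-1] <= 400
        assert all(b - a >= 100 for a, b in zip(positions, positions[1:]))


class TestDatasetContracts:
    def test_zero_rates_give_root_everywhere(self, quiet_dataset):
        root = quiet_dataset.root_genome
        for sp, genome in quiet_dataset.genomes.items():
            assert genome.n_genes == root.n_genes
            assert genome.n_chromosomes == root.n_chromosomes
        for node in quiet_dataset.snapshots:
            snap = quiet_dataset.snapshots[node]
            assert snap.gene_ids() == root.gene_ids()

    def test_same_seed_runs_are_identical(self):
        cfg = dict(seed=9, n_chromosomes=2, genes_per_chromosome=60, time_scale=0.2,
                   gene_gain_rate=1.5, gene_loss_rate=3.0)
        a = simulate_dataset(SimulationConfig(**cfg))
        b = simulate_dataset(SimulationConfig(**cfg))
        for sp in a.genomes:
            ga, gb = a.genomes[sp], b.genomes[sp]
            assert [
                (g.gene_id, g.chromosome, g.rank, g.strand) for g in ga
            ] == [(g.gene_id, g.chromosome, g.rank, g.strand) for g in gb]
        assert [(e.etype, e.params) for e in a.events] == [
            (e.etype, e.params) for e in b.events
        ]

    def test_event_log_replay_reproduces_extant_genomes(self, busy_dataset):
        ds = busy_dataset
        leaves = replay_events(ds.root_genome, ds.tree, ds.events)
        for sp, genome in ds.genomes.items():
            replayed = sim_to_genome(sp, leaves[sp])
            assert [
                (g.gene_id, g.chromosome, g.rank, g.strand) for g in genome
            ] == [(g.gene_id, g.chromosome, g.rank, g.strand) for g in replayed]
            assert genome.centromeres == replayed.centromeres

    def test_gene_count_ledger(self, busy_dataset):
        """root + gains - losses = extant count, along every root-leaf path."""
        ds = busy_dataset
        for leaf in ds.tree.leaf_names:
            path_names = set()
            node = ds.tree.node(leaf)
            while node.parent is not None:
                path_names.add(node.name)
                node = node.parent
            gains = losses = wgd_added = 0
            for e in ds.events:
                if e.branch_child not in path_names:
                    continue
                if e.etype in ("gain_novel", "gain_tandem"):
                    gains += 1
                elif e.etype == "loss":
                    losses += 1
                elif e.etype == "fusion_rta":
                    losses += len(e.affected)
                elif e.etype == "wgd":
                    n_copies = 3 * len(e.params["copies"])
                    wgd_added += n_copies - len(e.params["copies"])
                    losses += len(e.params["lost"])
            expected = ds.root_genome.n_genes + gains + wgd_added - losses
            assert ds.genomes[leaf].n_genes == expected

    def test_centromere_ledger(self, busy_dataset):
        """centromeres = chromosomes, and fusions/fissions change both by one."""
        ds = busy_dataset
        for leaf in ds.tree.leaf_names:
            genome = ds.genomes[leaf]
            assert set(genome.centromeres) == set(genome.chromosomes)
            path_names = set()
            node = ds.tree.node(leaf)
            while node.parent is not None:
                path_names.add(node.name)
                node = node.parent
            n = ds.root_genome.n_chromosomes
            for e in ds.events:
                if e.branch_child not in path_names:
                    continue
                if e.etype == "fusion_rta":
                    n -= 1
                elif e.etype == "fission":
                    n += 1
                elif e.etype == "wgd":
                    n *= 3
            assert genome.n_chromosomes == n

    def test_every_gene_traces_to_root_or_gain(self, busy_dataset):
        ds = busy_dataset
        root_ids = ds.root_genome.gene_ids()
        born = {
            e.params["gid"]
            for e in ds.events
            if e.etype in ("gain_novel", "gain_tandem")
        }
        for e in ds.events:
            if e.etype == "wgd":
                for subs in e.params["copies"].values():
                    born.update(subs.values())
        for sp, genome in ds.genomes.items():
            for g in genome:
                assert g.gene_id in root_ids or g.gene_id in born


class TestSequences:
    def test_rate_zero_homologs_identical(self):
        cfg = SimulationConfig(
            seed=4, n_chromosomes=2, genes_per_chromosome=30, time_scale=0.2,
            gene_gain_rate=1.0, gene_loss_rate=2.0, hexaploidy=None,
            sequences=SequenceModel(n_codons=20, subs_per_site_per_my=0.0),
        )
        ds = simulate_dataset(cfg)
        # all descendants of one root gene share its sequence
        for fam, per_sp in ds.families.members.items():
            seqs = {
                ds.sequences[gid] for sp, gids in per_sp.items() for gid in gids
            }
            assert len(seqs) == 1

    def test_divergence_monotone_in_time(self):
        from paleokaryo.ks import ks_ng86
        from paleokaryo.simulate import evolve_codon_sequence, random_codon_sequence

        rng = np.random.default_rng(3)
        med = []
        for t in (3.0, 6.0):
            vals = []
            for _ in range(100):
                root = random_codon_sequence(60, rng)
                a = evolve_codon_sequence(root, t, 0.01, rng)
                b = evolve_codon_sequence(root, t, 0.01, rng)
                est = ks_ng86(a, b)
                if est.valid:
                    vals.append(est.Ks)
            med.append(np.median(vals))
        assert med[1] > med[0]

    def test_two_step_hexaploidy_ks_ordering(self):
        """MF1-MF2 homoeologs are younger than either LF pair, so their Ks
        median is the smallest; the two LF pairs are comparable."""
        cfg = SimulationConfig(
            seed=12, time_scale=0.2,
            sequences=SequenceModel(n_codons=100, subs_per_site_per_my=0.01),
        )
        ds = simulate_dataset(cfg)
        from paleokaryo.ks import ks_ng86

        hx = ds.hex_truth
        br = ds.genomes["Br"].gene_ids()
        groups = {"LF-MF1": [], "LF-MF2": [], "MF1-MF2": []}
        for orig, subs in hx.copies.items():
            alive = {s: cid for s, cid in subs.items() if cid in br}
            for a in alive:
                for b in alive:
                    if a < b:
                        est = ks_ng86(ds.sequences[alive[a]], ds.sequences[alive[b]])
                        if est.valid:
                            groups[f"{a}-{b}"].append(est.Ks)
        med = {k: np.median(v) for k, v in groups.items()}
        assert med["MF1-MF2"] < med["LF-MF1"]
        assert med["MF1-MF2"] < med["LF-MF2"]
        assert abs(med["LF-MF1"] - med["LF-MF2"]) < 0.35 * max(
            med["LF-MF1"], med["LF-MF2"]
        )
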