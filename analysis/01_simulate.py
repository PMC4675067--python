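#!/usr/bin/env python
"""Simulate the desk-scale Brassicaceae-like dataset used by all analyses.

Five ingroup genomes plus an outgroup evolve from an eight-chromosome,
2000-gene ancestor at the default event rates (time scale 0.2), with the
two-step triplication and biased fractionation on the Brassica-like lineage
and codon sequences for Ks work.  Writes gene orders, families, the tree,
truth karyotypes (instance- and family-namespace), ortholog maps, the event
log and sequences under results/data/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DATA_DIR, SEED, make_dataset

import paleokaryo.io as pio
from paleokaryo.simulate import write_dataset


def main() -> None:
    dataset = make_dataset()
    write_dataset(dataset, DATA_DIR)
    # family-namespace truth karyotypes for direct comparison with
    # reconstructions (02/06); tandem copies of one family collapse to the
    # first occurrence, since family-level reconstruction has one ancestral
    # gene per family and the CAR format requires unique membership
    from paleokaryo.model import CAR, AncestralKaryotype, Protochromosome

    for node in sorted(dataset.snapshots):
        k = dataset.true_karyotype(node, namespace="family")
        seen = set()
        pcs = []
        for pc in k.protochromosomes:
            genes = []
            for g, s in pc.genes():
                if g not in seen:
                    seen.add(g)
                    genes.append((g, s))
            car = CAR(pc.pc_id, node, genes)
            pcs.append(Protochromosome(pc.pc_id, node, [(car, 1)]))
        deduped = AncestralKaryotype(node, pcs, [], set())
        pio.write_karyotype(deduped, DATA_DIR / f"true_karyotype.{node}.family.tsv")
    print(f"seed {SEED}; wrote {DATA_DIR}")
    for sp in sorted(dataset.genomes):
        g = dataset.genomes[sp]
        print(f"  {sp}: {g.n_chromosomes} chromosomes, {g.n_genes} genes")
    print(f"  events logged: {len(dataset.events)}")


if __name__ == "__main__":
    main()
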