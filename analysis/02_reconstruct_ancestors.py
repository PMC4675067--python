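#!/usr/bin/env python
"""Reconstruct the three ancestral karyotypes from the simulated genomes.

Reads the extant gene orders, families and tree written by 01, runs the
full CAR pipeline (content -> adjacency graph -> greedy linearization ->
contig round -> scaffolding) at ABK, ACK and PCK, and writes the CAR files
plus a per-node stage summary under results/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DATA_DIR, NODES, RESULTS, load_genomes

import paleokaryo.io as pio
from paleokaryo.content import ancestral_gene_set
from paleokaryo.scaffold import reconstruct_karyotype


def main() -> None:
    tree = pio.read_newick(DATA_DIR / "tree.nwk")
    families = pio.read_families(DATA_DIR / "families.tsv")
    genomes = load_genomes()
    summaries = {}
    for node in NODES:
        content = ancestral_gene_set(tree, families, node)
        karyotype, summary = reconstruct_karyotype(
            tree, node, genomes, content=content
        )
        pio.write_karyotype(
            karyotype, RESULTS / f"karyotype.{node}.tsv", content.descendant_map
        )
        summaries[node] = summary
        print(
            f"{node}: {summary['ordered_protogenes']} ordered / "
            f"{summary['total_protogenes']} total protogenes in "
            f"{summary['protochromosomes']} protochromosomes "
            f"({summary['small_cars']} small CARs, {summary['singletons']} singletons)"
        )
    with (RESULTS / "reconstruction_summary.json").open("w") as fh:
        json.dump(summaries, fh, indent=2, sort_keys=True)
        fh.write("\n")


if __name__ == "__main__":
    main()
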