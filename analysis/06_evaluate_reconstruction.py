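#!/usr/bin/env python
"""Score the reconstructed karyotypes against the simulated truth.

Compares each reconstruction (02) with the family-namespace truth
karyotype (01): oriented adjacency precision/recall/F1, content
precision/recall, ordered fraction, protochromosome count delta and
co-chromosome concordance.  Writes results/evaluation.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DATA_DIR, NODES, RESULTS

import paleokaryo.io as pio
from paleokaryo.evaluate import evaluate_reconstruction


def main() -> None:
    reports = {}
    for node in NODES:
        truth = pio.read_karyotype(DATA_DIR / f"true_karyotype.{node}.family.tsv")
        recon = pio.read_karyotype(RESULTS / f"karyotype.{node}.tsv")
        report = evaluate_reconstruction(truth, recon)
        reports[node] = report.as_dict()
        print(
            f"{node}: precision {report.precision:.3f}, recall {report.recall:.3f}, "
            f"F1 {report.f1:.3f}, ordered fraction {report.ordered_fraction:.3f}, "
            f"concordance {report.concordance if report.concordance is None else round(report.concordance, 3)}"
        )
    with (RESULTS / "evaluation.json").open("w") as fh:
        json.dump(reports, fh, indent=2, sort_keys=True)
        fh.write("\n")


if __name__ == "__main__":
    main()
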