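#!/usr/bin/env python
"""Branch-wise gene gain and loss from Dollo family presence.

Writes results/gain_loss.tsv (parent, child, gains, losses, duration_my,
gain_rate, loss_rate) and prints the tree-wide totals and rates.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DATA_DIR, RESULTS

import paleokaryo.io as pio
from paleokaryo.content import gain_loss_report


def main() -> None:
    tree = pio.read_newick(DATA_DIR / "tree.nwk")
    families = pio.read_families(DATA_DIR / "families.tsv")
    df = gain_loss_report(tree, families)
    df.to_csv(RESULTS / "gain_loss.tsv", sep="\t", index=False, float_format="%.6g")
    branches = df[df.parent != "origin"]
    total_my = branches.duration_my.sum()
    print(f"wrote {RESULTS / 'gain_loss.tsv'}")
    print(
        f"tree-wide: {branches.gains.sum()} gains, {branches.losses.sum()} losses "
        f"over {total_my:.1f} my "
        f"({branches.gains.sum() / total_my:.1f} gained and "
        f"{branches.losses.sum() / total_my:.1f} lost per my)"
    )


if __name__ == "__main__":
    main()
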