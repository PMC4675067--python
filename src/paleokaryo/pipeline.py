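"""End-to-end pipeline: simulate -> reconstruct -> gain/loss -> fractionate
-> Ks -> evaluate, with all artifacts written to disk.

The pipeline config is a flat YAML file::

    seed: 42
    out: results/run1          # overridden by the --out flag
    simulation: {...}          # SimulationConfig fields (seed filled in)
    nodes: [ABK, ACK, PCK]     # reconstruction targets
    min_car_size: 50
    fractionation:
      ancestor: PCK
      polyploid: Br
      window: 100
      gap: 50
    ks: true                   # needs simulation.sequences

Reruns with the same config are byte-identical: every output is sorted and
floats are formatted deterministically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import yaml

from . import io as pio
from .content import ancestral_gene_set, gain_loss_report
from .evaluate import evaluate_reconstruction
from .fractionation import (
    assign_subgenome_windows,
    dominance_exchanges,
    retention_classes,
    retention_frame,
    subgenome_map_frame,
)
from .ks import ks_by_pair_class
from .model import InputError
from .scaffold import reconstruct_karyotype
from .simulate import SimulationConfig, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(type(o))


def run_pipeline(config: dict, out_dir, seed: Optional[int] = None) -> dict:
    """Run all configured stages; returns (and writes) the summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    sim_cfg = dict(config.get("simulation") or {})
    if seed is not None:
        sim_cfg["seed"] = seed
    elif "seed" in config and "seed" not in sim_cfg:
        sim_cfg["seed"] = config["seed"]
    if "seed" not in sim_cfg:
        raise InputError("pipeline: a seed is required (config `seed` or --seed)")
    if "hexaploidy" in sim_cfg and isinstance(sim_cfg["hexaploidy"], dict):
        from .simulate import HexaploidySpec

        hx = dict(sim_cfg["hexaploidy"])
        if "loss_probs" in hx:
            hx["loss_probs"] = tuple(hx["loss_probs"])
        sim_cfg["hexaploidy"] = HexaploidySpec(**hx)
    if isinstance(sim_cfg.get("sequences"), dict):
        from .simulate import SequenceModel

        sim_cfg["sequences"] = SequenceModel(**sim_cfg["sequences"])

    logger.info("pipeline: simulate")
    dataset = simulate_dataset(SimulationConfig(**sim_cfg))
    data_dir = out / "data"
    write_dataset(dataset, data_dir)
    summary["simulate"] = {
        "species": {sp: g.n_genes for sp, g in sorted(dataset.genomes.items())},
        "events": len(dataset.events),
    }

    nodes = config.get("nodes", ["ABK", "ACK", "PCK"])
    min_car_size = int(config.get("min_car_size", 50))
    karyotypes = {}
    contents = {}
    summary["reconstruct"] = {}
    summary["evaluate"] = {}
    for node in nodes:
        logger.info("pipeline: reconstruct %s", node)
        content = ancestral_gene_set(dataset.tree, dataset.families, node)
        karyotype, stage_counts = reconstruct_karyotype(
            dataset.tree,
            node,
            dataset.genomes,
            content=content,
            min_car_size=min_car_size,
        )
        karyotypes[node] = karyotype
        contents[node] = content
        pio.write_karyotype(
            karyotype, out / f"karyotype.{node}.tsv", content.descendant_map
        )
        summary["reconstruct"][node] = stage_counts
        if node in dataset.snapshots:
            truth = dataset.true_karyotype(node, namespace="family")
            report = evaluate_reconstruction(truth, karyotype)
            summary["evaluate"][node] = report.as_dict()

    logger.info("pipeline: gain/loss")
    gl = gain_loss_report(dataset.tree, dataset.families)
    gl.to_csv(out / "gain_loss.tsv", sep="\t", index=False, float_format="%.6g")
    summary["gain_loss"] = {
        "total_gains": int(gl["gains"].sum()),
        "total_losses": int(gl["losses"].sum()),
    }

    frac_cfg = config.get("fractionation")
    if frac_cfg:
        anc_node = frac_cfg.get("ancestor", "PCK")
        polyploid_sp = frac_cfg.get("polyploid", "Br")
        logger.info("pipeline: fractionate %s against %s", polyploid_sp, anc_node)
        if anc_node not in dataset.snapshots:
            raise InputError(f"fractionation: no truth snapshot for {anc_node!r}")
        true_k = dataset.true_karyotype(anc_node)
        omap = {
            anc: gids
            for anc, per_sp in dataset.ortholog_map_all(anc_node).items()
            for sp, gids in per_sp.items()
            if sp == polyploid_sp
        }
        smap = assign_subgenome_windows(
            true_k,
            dataset.genomes[polyploid_sp],
            omap,
            window=int(frac_cfg.get("window", 100)),
            gap=int(frac_cfg.get("gap", 50)),
        )
        subgenome_map_frame(smap).to_csv(
            out / "subgenome_windows.tsv", sep="\t", index=False
        )
        counts, retentions = retention_classes(smap, omap)
        retention_frame(retentions).to_csv(
            out / "retention_classes.tsv", sep="\t", index=False
        )
        exchanges = dominance_exchanges(smap)
        with (out / "dominance_exchanges.tsv").open("w") as fh:
            fh.write("anc_chr\tboundary\tlabel_a\tlabel_b\n")
            for e in exchanges:
                fh.write(f"{e.anc_chr}\t{e.boundary}\t{e.label_a}\t{e.label_b}\n")
        summary["fractionation"] = {
            "windows": len(smap.windows),
            "classes": {k: int(v) for k, v in sorted(counts.items())},
            "exchanges": len(exchanges),
        }
        if config.get("ks") and dataset.sequences:
            logger.info("pipeline: Ks by pair class")
            groups, n_invalid = ks_by_pair_class(retentions, dataset.sequences)
            rows = []
            for cls in sorted(groups):
                vals = groups[cls]
                if vals:
                    rows.append(
                        {
                            "class": cls,
                            "n": len(vals),
                            "median_ks": float(np.median(vals)),
                            "mean_ks": float(np.mean(vals)),
                        }
                    )
            import pandas as pd

            pd.DataFrame(rows, columns=["class", "n", "median_ks", "mean_ks"]).to_csv(
                out / "ks_by_class.tsv", sep="\t", index=False, float_format="%.6g"
            )
            summary["ks"] = {
                r["class"]: round(r["median_ks"], 6) for r in rows
            }
            summary["ks_invalid_pairs"] = n_invalid

    with (out / "summary.json").open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return summary


def load_pipeline_config(path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise InputError(f"{path}: pipeline config must be a mapping")
    return data
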