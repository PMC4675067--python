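"""Shared configuration for the numbered analysis drivers.

One seeded dataset (seed 42, time scale 0.2, default rates, sequences on)
is the study object of every script; 01 writes it to results/data/ and the
later scripts read those files back.
"""

from pathlib import Path

from paleokaryo.simulate import SequenceModel, SimulationConfig, simulate_dataset

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATA_DIR = RESULTS / "data"

SEED = 42
NODES = ("ABK", "ACK", "PCK")


def make_config() -> SimulationConfig:
    return SimulationConfig(
        seed=SEED,
        time_scale=0.2,
        sequences=SequenceModel(n_codons=100, subs_per_site_per_my=0.01),
    )


def make_dataset():
    return simulate_dataset(make_config())


def load_genomes():
    import paleokaryo.io as pio

    genomes = {}
    for path in sorted(DATA_DIR.glob("genes.*.tsv")):
        genome = pio.read_gene_orders(path)
        genomes[genome.species] = genome
    if not genomes:
        raise SystemExit("no gene orders under results/data -- run 01_simulate.py first")
    return genomes
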