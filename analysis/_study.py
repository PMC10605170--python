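"""Shared paths and study conditions for the numbered analysis drivers.

The drivers run the survey on a mid-scale synthetic study: large enough for
every planted signal to be comfortably detectable, small enough that each
step completes in seconds. All outputs land under ``results/``.
"""

from pathlib import Path

from regscan.intervals import GenomicInterval
from regscan.synthetic import SimulationConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
STUDY_DIR = RESULTS / "synthetic_study"


def study_config(seed: int = 0) -> SimulationConfig:
    return SimulationConfig(
        n_cohorts=6,
        samples_per_cohort=80,
        n_genes=800,
        planted_regulators=[
            ("REG_POS1", 0.7), ("REG_POS2", 0.6), ("REG_POS3", 0.5),
            ("REG_NEG1", -0.7), ("REG_NEG2", -0.6),
        ],
        window=GenomicInterval("chr5", 90_000_000, 90_200_000),
        bin_size=100,
        atac_samples=150,
        planted_bins=[(400, 0.8), (410, 0.8), (1_500, -0.8), (1_510, -0.8)],
        n_factors=12,
        experiments_per_factor=4,
        peaks_per_experiment=60,
        planted_factors=[("TF000", 3.0), ("TF001", 2.0)],
        co_membership=0.8,
        target_set_size=60,
        n_loops=40,
        seed=seed,
    )
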