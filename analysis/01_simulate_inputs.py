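"""Generate the synthetic study: cohorts, accessibility, peaks, targets, loops.

Writes every pipeline input plus the planted truth under
results/synthetic_study/ and reports what was planted.

    python analysis/01_simulate_inputs.py [--seed 0]
"""

import argparse

from regscan import io
from regscan.pipeline import write_simulation

from _study import STUDY_DIR, study_config


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    cfg = study_config(args.seed)
    run_cfg_path = write_simulation(cfg, STUDY_DIR)
    truth = io.read_json(STUDY_DIR / "truth.json")
    print(f"wrote synthetic study to {STUDY_DIR}")
    print(f"  cohorts: {cfg.n_cohorts} x {cfg.samples_per_cohort} samples x {cfg.n_genes} genes")
    print(f"  planted regulators: {truth['regulators']}")
    print(f"  window {cfg.window} in {cfg.bin_size} bp bins "
          f"({cfg.grid().n_bins} bins, {cfg.atac_samples} samples)")
    print(f"  planted bins: {truth['bins']}")
    print(f"  factors: {cfg.n_factors} x {cfg.experiments_per_factor} experiments; "
          f"planted folds: {truth['factors']}")
    print(f"  run config: {run_cfg_path}")


if __name__ == "__main__":
    main()
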