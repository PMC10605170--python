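import numpy as np
import pandas as pd
import pytest

from regscan.intervals import GenomicInterval
from regscan.synthetic import SimulationConfig, fixture_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_window():
    return GenomicInterval("chr1", 0, 100_000)


@pytest.fixture(scope="session")
def fixture_run(tmp_path_factory):
    """One full pipeline run on the packaged small study, shared by tests."""
    from regscan.pipeline import RunConfig, run_pipeline, write_simulation

    root = tmp_path_factory.mktemp("fixture_run")
    cfg_path = write_simulation(fixture_config(seed=11), root)
    run_config = RunConfig.from_yaml(cfg_path)
    manifest = run_pipeline(run_config)
    return root, run_config, manifest


def toy_cohort(n_genes=30, n_samples=40, seed=0, focal="FOCAL"):
    """Independent lognormal expression with a focal gene, for unit tests."""
    r = np.random.default_rng(seed)
    genes = [focal] + [f"G{i:03d}" for i in range(n_genes - 1)]
    mat = pd.DataFrame(
        np.exp(r.normal(2, 1, size=(n_genes, n_samples))),
        index=genes,
        columns=[f"S{i:03d}" for i in range(n_samples)],
    )
    from regscan.coexpression import CohortExpression

    return CohortExpression("TOY", mat)
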