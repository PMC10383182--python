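import numpy as np
import pytest

from uevphos.pipeline import PipelineConfig, run_pipeline
from uevphos.synthetic_data import SimConfig, generate_experiment


@pytest.fixture(scope="session")
def small_experiment(tmp_path_factory):
    """A small seeded synthetic experiment shared by fast pipeline tests."""
    out = tmp_path_factory.mktemp("sim_small")
    config = SimConfig(seed=11, n_proteins=80, n_phosphopeptides=300, n_regulated=10)
    return generate_experiment(config, out)


@pytest.fixture(scope="session")
def small_bundle(small_experiment, tmp_path_factory):
    """Pipeline results on the small experiment."""
    out = tmp_path_factory.mktemp("run_small")
    config = PipelineConfig(
        mgf=small_experiment.mgf_path,
        psm_table=small_experiment.psm_path,
        purity=small_experiment.purity_path,
        reference_totals=small_experiment.mgf_path.parent / "reference_totals.csv",
        output_dir=out,
        seed=11,
    )
    return run_pipeline(config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
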