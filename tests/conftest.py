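import numpy as np
import pytest

import breathomics as b


@pytest.fixture(scope="session")
def small_cohort():
    """Noiseless 6-participant cohort with the default 30 exhaled + 10
    ambient compounds (plus background run) and its ground truth."""
    cfg = b.SimulationConfig(n_participants=6, duration=90.0, scans_per_second=2.0,
                             seed=1)
    runs, truth = b.simulate_cohort(cfg)
    return cfg, runs, truth


@pytest.fixture(scope="session")
def small_result(small_cohort):
    """Full-pipeline result on the noiseless small cohort (SNR gating off:
    a noise-free acquisition has no noise floor)."""
    _, runs, _ = small_cohort
    params = b.PipelineParams(min_snr=0)
    return params, b.process_cohort(runs, b.default_compound_db(), params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
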