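import numpy as np
import pytest

from methylaging import SimulationTruth, make_clock, simulate_methylation
from methylaging.pipeline import simulate_bundle


@pytest.fixture(scope="session")
def small_clock():
    return make_clock(n_cpgs=20, seed=11)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Noiseless two-tissue cohort: reference at rate 1, cerebellum at 0.6."""
    clock = make_clock(n_cpgs=50, seed=3)
    truth = SimulationTruth(
        clock=clock,
        tissue_rate={"cerebellum": 0.6, "cortex": 1.0},
        noise_sd_beta=0.0,
        seed=3,
    )
    ages = np.linspace(5.0, 110.0, 30)
    subjects = [(float(a), ["cerebellum", "cortex"], 1) for a in ages]
    beta, sheet = simulate_methylation(truth, subjects, n_filler_cpgs=20)
    return truth, beta, sheet


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Full synthetic input bundle on disk (seed 1)."""
    out = tmp_path_factory.mktemp("bundle")
    return simulate_bundle(out, seed=1)
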