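import numpy as np
import pytest

from torporlab import ArtifactRates, SimulationConfig, TskTrace


def make_trace(tsk, valid=None, dt=15.0, bat_id="b", treatment="humid"):
    tsk = np.asarray(tsk, dtype=float)
    return TskTrace(
        bat_id=bat_id,
        treatment=treatment,
        times=np.arange(tsk.size) * dt,
        tsk=tsk,
        valid=valid,
    )


def random_quantized_trace(rng, max_len=80):
    """A short random 0.5 °C-quantized trace with a random validity mask."""
    n = int(rng.integers(2, max_len))
    tsk = rng.integers(16, 61, n) * 0.5  # 8.0 .. 30.0 °C
    valid = rng.random(n) > 0.1
    if not valid.any():
        valid[int(rng.integers(0, n))] = True
    return make_trace(tsk, valid=valid)


@pytest.fixture(scope="session")
def clean_config():
    """Small artifact-free cohort: fast, with exact detector recovery."""
    return SimulationConfig(
        seed=11,
        n_bats_per_treatment=3,
        study_days=40.0,
        artifact_rates=ArtifactRates.none(),
    )


@pytest.fixture(scope="session")
def clean_cohort(clean_config):
    from torporlab import simulate_cohort

    return simulate_cohort(clean_config)
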