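"""Shared fixtures: schedules and small dictionaries reused across tests."""

import numpy as np
import pytest

import mrfepi as m


@pytest.fixture(scope="session")
def schedule():
    """Default 35-point linear-ramp acquisition schedule."""
    return m.make_schedule()


@pytest.fixture(scope="session")
def small_dict(schedule):
    """Coarse T1 x T2* dictionary (~120 entries) over well-encoded ranges."""
    grid = m.GridSpec(
        t1_min_ms=500, t1_max_ms=2500, t2s_min_ms=30, t2s_max_ms=300,
        increment_frac=0.2, b1_min=1.0, b1_max=1.0,
    )
    return m.generate_dictionary(schedule, grid)


@pytest.fixture(scope="session")
def medium_dict(schedule):
    """~2000-entry dictionary used by the training smoke/efficacy tests."""
    grid = m.GridSpec(
        t1_min_ms=500, t1_max_ms=2500, t2s_min_ms=30, t2s_max_ms=300,
        increment_frac=0.045, b1_min=1.0, b1_max=1.0,
    )
    return m.generate_dictionary(schedule, grid)


@pytest.fixture(scope="session")
def gaussian_bank_20db():
    """Synthetic white-Gaussian residual bank at 20 dB for unit-norm signals."""
    rng = np.random.default_rng(42)
    sd = np.sqrt(10 ** (-20 / 10) / 35)
    return m.NoiseBank(rng.normal(0.0, sd, size=(1000, 35)), source_meta={"synthetic": "gaussian-20dB"})


def heldout_signals(schedule, n, seed):
    """Random off-grid fingerprints (log-uniform T1/T2* inside the reduced ranges)."""
    rng = np.random.default_rng(seed)
    t1 = np.exp(rng.uniform(np.log(500), np.log(2500), n))
    t2s = np.exp(rng.uniform(np.log(30), np.log(300), n))
    clean = m.simulate_fingerprints(schedule, t1, t2s, np.ones(n))
    clean /= np.linalg.norm(clean, axis=1, keepdims=True)
    return clean, np.column_stack([t1, t2s])
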