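"""Shared fixtures: small simulator runs and validation scenarios."""

import numpy as np
import pytest

from h2sinks import (KineticParams, ReactorConfig, generate_asv_table,
                     sample_observations, simulate_reactor)

WEEKLY = 7.0


def closed_system_config(c0: float = 105.0, duration: float = 49.0) -> ReactorConfig:
    """Closed reactor (no flow, no gypsum, no iron) for estimator validation.

    The initial sulfate pool is large enough that a 1.75 umol/(day*cm3)
    zero-order rate stays in its linear regime across eight weekly samples.
    """
    return ReactorConfig(duration=duration, flow_profile=0.0, h2_schedule=10.0,
                         c0_sulfate=c0, c_in_sulfate=0.0, gypsum0=0.0,
                         c0_fe=0.0, c_in_fe=0.0)


def zero_order_params(vmax: float = 1.75) -> KineticParams:
    return KineticParams(vmax_sr=vmax, k_so4=1e-3, k_gyp=0.0, vmax_meth=0.0)


@pytest.fixture(scope="session")
def default_sim():
    """Study-condition reactor run: 15 mM porewater, gypsum, daily H2."""
    return simulate_reactor(ReactorConfig(duration=60.0), step=0.02, seed=0)


@pytest.fixture(scope="session")
def zero_order_sim():
    """Noise-free constant-rate closed-system run, truth ~1.75."""
    return simulate_reactor(closed_system_config(), zero_order_params(),
                            step=0.01, seed=0)


@pytest.fixture(scope="session")
def weekly_schedule():
    return np.arange(0.0, 49.0 + 1e-9, WEEKLY)


@pytest.fixture(scope="session")
def noiseless_obs(zero_order_sim, weekly_schedule):
    return sample_observations(zero_order_sim, weekly_schedule, noise_sd=0.0,
                               n_reps=3, seed=1)


@pytest.fixture(scope="session")
def asv_table():
    return generate_asv_table(seed=11)
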