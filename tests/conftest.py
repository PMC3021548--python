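"""Shared fixtures: reference environment, warmed kernels, cached ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from polbd.engine import IntegratorConfig
from polbd.flexible_model import FlexibleModelParams, run_flexible_experiment
from polbd.physics import PhysicalEnvironment


@pytest.fixture(scope="session")
def env298() -> PhysicalEnvironment:
    """Reference conditions: T = 298 K, η = 1e-3 Pa·s."""
    return PhysicalEnvironment.from_temperature(298.0)


@pytest.fixture(scope="session")
def warm_kernels():
    """Trigger JIT compilation once so timings elsewhere are meaningful."""
    from polbd import _kernels

    buf = np.empty((4, 5))
    _kernels.rigid_fpt(np.uint64(1), 1.0, 0.5, 0, 4.11, 0.06, 1e-4, 10, 7.0,
                       0.25, 10.0, 0.0, 0.0, 0.0, 0)
    _kernels.flexible_fpt(np.uint64(1), 1.0, 0.5, 0.143, 3.5, 2.0, 8.56, 4.8,
                          0.0, True, 1, False, 4.11, 0.066, 1.078, 1e-4, 10,
                          0.5, 0)
    _kernels.flexible_trajectory(np.uint64(1), 1.0, 0.5, 0.143, 3.5, 2.0,
                                 8.56, 4.8, 0.0, True, 1, 4.11, 0.066, 1.078,
                                 1e-4, 10, 0.5, 2, buf)
    _kernels.double_well_fpt_1d(np.uint64(1), 2.0, 1.0, 1.0, 1e-3, 10)
    _kernels.harmonic_positions_1d(np.uint64(1), 1.0, 1.0, 1.0, 1e-2, 10, 5, 2)
    _kernels.boltzmann_histogram_1d(np.uint64(1), 3.0, 0.5, 2.5, 1.0, 1.0,
                                    1e-3, 10, 20, 2, np.linspace(-2.5, 2.5, 11))
    _kernels.normal_stream(1, 4)
    return _kernels


@pytest.fixture(scope="session")
def flexible_fpt_samples(warm_kernels):
    """Transition-time ensembles at d = 2 and 2.5 nm, shared across tests.

    Used both for the single-exponential distribution checks and as generic
    T_m ensembles; computed once per session.
    """
    out = {}
    cfg = IntegratorConfig(seed=2024, max_time=500.0)
    for d in (2.0, 2.5):
        params = FlexibleModelParams(d=d)
        summary, times = run_flexible_experiment(params, 300, cfg)
        out[d] = (summary, times)
    return out
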