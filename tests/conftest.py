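"""Shared fixtures.

The expensive fixtures (the full default synthetic run and its image
analysis) are session-scoped and built lazily so the whole suite pays for
them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from dictyosc import (
    SimulationConfig,
    forward_impedance,
    render_bf_stack,
    render_tirf_stack,
    simulate_ensemble,
)
from dictyosc.pipeline import analyze_images, run_simulation


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(rng_seed=1)


@pytest.fixture(scope="session")
def default_truth(default_config):
    return simulate_ensemble(default_config)


@pytest.fixture(scope="session")
def default_impedance(default_truth, default_config):
    return forward_impedance(default_truth, default_config)


@pytest.fixture(scope="session")
def default_stacks(default_truth, default_config):
    bf = render_bf_stack(default_truth, default_config)
    tirf = render_tirf_stack(default_truth, default_config)
    return bf, tirf


@pytest.fixture(scope="session")
def default_image_traces(default_stacks):
    bf, tirf = default_stacks
    return analyze_images(bf, tirf)


@pytest.fixture(scope="session")
def quiet_bridge_config() -> SimulationConfig:
    """Quiescent-motility, noise-free scenario for the bridging workflow."""
    return SimulationConfig(
        rng_seed=1,
        noise_sd=0.0,
        motility_sd_um=0.15,
        attraction_um=0.0,
        duration_s=7200.0,
    )


@pytest.fixture(scope="session")
def bridge_run_dirs(tmp_path_factory, quiet_bridge_config):
    """Two same-seed synthetic runs written to disk (ECIS side, TIRF side)."""
    base = tmp_path_factory.mktemp("bridge")
    run_simulation(quiet_bridge_config, base / "ecis")
    run_simulation(quiet_bridge_config, base / "tirf")
    return base / "ecis", base / "tirf"


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
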