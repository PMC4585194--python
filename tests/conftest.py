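"""Shared fixtures: default parameters and a cache of full-model runs.

The mismatch-sweep trajectories are expensive (10,000 h horizons), so a
session-scoped factory memoises them across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from graftdyn import ModelParameters, Trajectory, integrate, make_subsystem_rhs


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def full_run(params):
    """Memoised full-model integration: full_run(alpha, ic, horizon, graft_present)."""
    cache: dict = {}

    def run(
        alpha: float,
        ic=(0, 2, 1, 0.125, 0, 0),
        horizon: float = 10_000.0,
        graft_present: bool = True,
    ) -> Trajectory:
        key = (alpha, tuple(ic), horizon, graft_present)
        if key not in cache:
            p = params.replace(alpha=alpha)
            rhs = make_subsystem_rhs("full", p, alpha=alpha, graft_present=graft_present)
            cache[key] = integrate(rhs, ic, horizon, p, graft_present=graft_present)
        return cache[key]

    return run


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20150925)
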