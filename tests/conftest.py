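"""Shared fixtures: parameter sets and cached simulation ensembles.

The expensive Brownian-dynamics ensembles are session-scoped so the
acceptance-level checks and the qualitative-ordering checks reuse the
same runs.  Ensemble sizes are reduced relative to a production study
(hundreds of runs) but large enough for the stated statistical
tolerances; see docs/methods.md for the problem sizes used.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import fluidcargo as fc


@pytest.fixture(scope="session")
def default_params() -> fc.ParameterSet:
    return fc.default_kinesin_parameters()


def _ensemble_params(params: fc.ParameterSet, D: float, **motor_kw):
    """Free-transport ensemble protocol: rotation off, forces recorded."""
    return params.with_overrides(
        motor={"surface_diffusion": D, **motor_kw},
        cargo={"rotation_enabled": False},
        run={
            "max_time": 60.0,
            "record_anchors": False,
            "record_orientation": False,
        },
    )


def _run(params, n_runs, seed):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return fc.run_ensemble(params, n_runs, seed)


@pytest.fixture(scope="session")
def rigid_n16_ensemble(default_params):
    """30 rigid-cargo runs, N = 16, 2 mM ATP, rotation off."""
    return _run(_ensemble_params(default_params, 0.0), 30, 2024)


@pytest.fixture(scope="session")
def lipid_n16_ensemble(default_params):
    """20 fluid-cargo (D = 1 μm²/s) runs, N = 16, 2 mM ATP."""
    return _run(_ensemble_params(default_params, 1.0), 20, 2025)


@pytest.fixture(scope="session")
def low_atp_n4_ensembles(default_params):
    """Rigid and fluid N = 4 ensembles at 4.9 μM ATP with >= 150
    completed motor engagements each (runs capped at 60 s)."""
    out = {}
    for name, D, seed in (("rigid", 0.0, 31), ("lipid", 1.0, 32)):
        ps = _ensemble_params(default_params, D).with_overrides(
            cargo={"motor_count": 4},
            environment={"ATP": 4.9},
        )
        runs = []
        seeds = fc.engine.child_seeds(seed, 200)
        total = 0
        for s in seeds:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                tr, ev = fc.run_single_cargo(ps, int(s))
            runs.append((tr, ev))
            total += ev.engagement_durations()[0].size
            if total >= 150:
                break
        out[name] = runs
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
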