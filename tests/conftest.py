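"""Shared fixtures.

The calibrated canine baseline and the full delay sweep are expensive
(tens of seconds / a few minutes), so they are built once per session and
shared by the integration and acceptance tests.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gen_params():
    from crtsim.activation import GeneratorParams
    return GeneratorParams()


@pytest.fixture(scope="session")
def geometry(gen_params):
    from crtsim.activation import build_geometry
    return build_geometry(gen_params)


@pytest.fixture(scope="session")
def quiet_params(gen_params):
    """Jitter-free generator for deterministic single-map checks."""
    import dataclasses
    return dataclasses.replace(gen_params, jitter_sd=0.0)


@pytest.fixture(scope="session")
def study_maps(gen_params):
    """Generic activation maps for the baseline, both single-site
    patterns and the full 100-setting grid."""
    from crtsim.activation import generic_maps
    from crtsim.protocol import BASELINE_SETTING, build_grid
    keys = ([BASELINE_SETTING.key(), (125.0, None)]
            + [s.key() for s in build_grid()])
    return generic_maps(keys, gen_params)


@pytest.fixture(scope="session")
def calibrated_baseline(gen_params, study_maps):
    """(config, steady state, steady summary, maps) of the tuned and
    contractility-calibrated canine baseline."""
    from crtsim.protocol import baseline_canine
    return baseline_canine(gen_params=gen_params, maps=study_maps)


@pytest.fixture(scope="session")
def sweep_result(calibrated_baseline):
    """The full 100-setting pacing-delay sweep."""
    from crtsim.protocol import run_grid
    cfg, state, summary, maps = calibrated_baseline
    res = run_grid(cfg, maps, state, summary)
    assert not res.failures, f"sweep failures: {res.failures}"
    return res


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
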