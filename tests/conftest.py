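"""Shared fixtures: synthetic datasets generated once per session."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ecgnets import synthetic

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """All five classes, 24 records each, plus the planted rule-breakers."""
    out = tmp_path_factory.mktemp("fixture_small")
    spec = synthetic.FixtureSpec(
        counts={c: 24 for c in synthetic.CLASS_RECIPES}, seed=0)
    synthetic.generate_dataset(spec, out)
    return out


@pytest.fixture(scope="session")
def binary_fixture(tmp_path_factory):
    """Larger NORM/MI/CD set used by the end-to-end training acceptance test."""
    out = tmp_path_factory.mktemp("fixture_binary")
    spec = synthetic.FixtureSpec(
        counts={"NORM": 256, "MI": 128, "CD": 128}, seed=7)
    synthetic.generate_dataset(spec, out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
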