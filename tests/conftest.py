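"""Shared fixtures: one synthetic bundle and rubric per test session."""

import pytest
from hypothesis import HealthCheck, settings

from cnvclassify.fixtures import FixtureSpec, build_bundle, generate_bundle
from cnvclassify.rubric_config import load_rubric

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(seed=1)


@pytest.fixture(scope="session")
def bundle(spec):
    return build_bundle(spec)


@pytest.fixture(scope="session")
def rubric():
    return load_rubric()


@pytest.fixture(scope="session")
def db_dir(spec, tmp_path_factory):
    root = tmp_path_factory.mktemp("db")
    generate_bundle(spec, root, build="GRCh38")
    return root
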