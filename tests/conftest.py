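import numpy as np
import pytest
from hypothesis import settings

from memstab.core import ProteinTarget
from memstab.simulate import (
    FixtureSpec,
    generate_ddg_tables,
    generate_plasmid,
    generate_stability_dataset,
    _random_sequence,
    _rng,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=1)


@pytest.fixture(scope="session")
def stability_dataset(fixture_spec):
    """records, features_by_target, truth_by_target, targets (seed 1)."""
    return generate_stability_dataset(fixture_spec)


@pytest.fixture(scope="session")
def small_target(fixture_spec):
    return ProteinTarget("SYN1", _random_sequence(_rng(fixture_spec, 9), 120))


@pytest.fixture(scope="session")
def ddg_fixture(fixture_spec, small_target):
    """tables, scan, planted sites for the 120-residue session target."""
    return generate_ddg_tables(fixture_spec, small_target)


@pytest.fixture(scope="session")
def plasmid_fixture(fixture_spec, small_target):
    return generate_plasmid(fixture_spec, small_target)
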