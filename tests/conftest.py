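"""Shared fixtures: synthetic assets are generated once per session."""

import pytest

from cdpsmine import fixtures, pipeline


@pytest.fixture(scope="session")
def family_spec():
    return fixtures.FamilySpec(seed=0)


@pytest.fixture(scope="session")
def family(family_spec):
    """(sequences, truth) for the default 20-member synthetic family."""
    return fixtures.gen_family(family_spec)


@pytest.fixture(scope="session")
def demo(family_spec):
    """Full demo asset tuple (spec, sequences, truth, subfamily seeds,
    domain seeds, reference db, training)."""
    return pipeline.demo_assets(seed=0, spec=family_spec)


@pytest.fixture(scope="session")
def bundle(family_spec):
    return pipeline.demo_bundle(seed=0, spec=family_spec)


@pytest.fixture(scope="session")
def validation_report(family_spec):
    return pipeline.validate(seed=0, spec=family_spec)
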