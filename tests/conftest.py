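import pytest

from oscimotif import GeneStage, canonical_profile
from oscimotif.io import generate_fixtures
from oscimotif.signals import CANONICAL_LABELS


@pytest.fixture(scope="session")
def profiles():
    """The three canonical input shapes, keyed by label."""
    return {lbl: canonical_profile(lbl) for lbl in CANONICAL_LABELS}


@pytest.fixture(scope="session")
def fixtures():
    """The canonical figure-level scenario set (deterministic, seed-free)."""
    return generate_fixtures()


@pytest.fixture
def stage():
    """A normalized activator gene stage: basal 0, induced 1 conc/h, alpha 1/h."""
    return GeneStage(name="Y", synth_off=0.0, synth_on=1.0, degradation=1.0)
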