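import pytest

from tfx import build_master_frame, classify_records, load_registry
from tfx.synthdata import generate_cohort


@pytest.fixture(scope="session")
def frame():
    return build_master_frame()


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def cohort(frame, registry):
    """One fixture per leaf (seed 1) with its classification results."""
    records, truth = generate_cohort(seed=1)
    results = classify_records(records, frame=frame, registry=registry)
    return records, truth, results
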