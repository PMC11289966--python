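import pytest

from slnatlas import preprocess, reference_contingency, reconstruct_reference_cohort


@pytest.fixture(scope="session")
def reference_table():
    return reference_contingency()


@pytest.fixture(scope="session")
def reference_cohort():
    """The 869-record marginal-matching reconstruction, preprocessed."""
    return preprocess(reconstruct_reference_cohort(reflected=False))
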