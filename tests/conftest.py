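import pytest

from dmdspectrum import load_cohort_table, load_gene_model, make_synthetic_model


@pytest.fixture(scope="session")
def model():
    """Packaged 79-exon Dp427m coding-exon model."""
    return load_gene_model()


@pytest.fixture(scope="session")
def cohort():
    """Packaged 43-patient cohort table."""
    return load_cohort_table()


@pytest.fixture()
def tiny_model():
    """10-exon synthetic model with hand-checkable phase structure."""
    return make_synthetic_model(10, [31, 62, 93, 78, 100, 173, 119, 182, 129, 92])
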