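import pytest
from hypothesis import settings

from a3pop import synthetic_data as sd

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cds():
    """Synthetic CDS per transcript, faithful at the study's codons."""
    return sd.cds_fixtures()


@pytest.fixture(scope="session")
def defs_by_label():
    return {(v.gene, v.label): v for v in sd.variant_defs()}


@pytest.fixture(scope="session")
def tally_fixture():
    """Per-gene cohorts with genotype counts exactly equal to the study's."""
    return sd.tally_cohorts()


@pytest.fixture(scope="session")
def category_fixture():
    """Per-gene cohorts expanded from the per-individual haplotype categories."""
    return sd.category_cohorts()
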