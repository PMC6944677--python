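import pytest

from mitoscreen import data as bundled
from mitoscreen.simulate import SimulationConfig, generate_reference


@pytest.fixture(scope="session")
def gene_map():
    return bundled.gene_map()


@pytest.fixture(scope="session")
def variant_records():
    return bundled.variant_table()


@pytest.fixture(scope="session")
def reference():
    """Seed-fixed synthetic surrogate reference consistent with the variant table."""
    return generate_reference(SimulationConfig(seed=20))


@pytest.fixture(scope="session")
def alignment():
    return bundled.trna_cys_alignment()


@pytest.fixture(scope="session")
def marker_db():
    return bundled.demo_marker_db()


@pytest.fixture(scope="session")
def bmi_cutoffs():
    return bundled.demo_bmi_cutoffs()


@pytest.fixture(scope="session")
def subjects():
    return bundled.family_subjects()


@pytest.fixture(scope="session")
def pedigree():
    return bundled.demo_pedigree()
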