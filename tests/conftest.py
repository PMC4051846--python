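import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from paleomorph.logshape import shape_matrix
from paleomorph.morphodata import Clade
from paleomorph.reference import TRINIL_RECORD
from paleomorph.synthetic_data import clade_spec_from_reference, gen_measurements


@pytest.fixture(scope="session")
def trinil():
    return TRINIL_RECORD


@pytest.fixture(scope="session")
def calibrated_records():
    """Four-clade synthetic sample at the published clade sizes, plus the
    fossil record (fixed seed: shared across the suite)."""
    records = []
    for i, clade in enumerate(Clade.comparative()):
        records.extend(gen_measurements(clade_spec_from_reference(clade), seed=100 + i))
    records.append(TRINIL_RECORD)
    return records


@pytest.fixture(scope="session")
def calibrated_matrix(calibrated_records):
    return shape_matrix(calibrated_records)


@pytest.fixture
def rng():
    return np.random.default_rng(20140610)
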