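import numpy as np
import pytest

from gfam.core_io import ProteinRecord
from gfam.domain_annotation import default_profiles
from gfam.promoter_cre import load_catalog


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def ap2_profile(profiles):
    return next(p for p in profiles if p.name == "AP2")


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture()
def random_protein(rng):
    from gfam.domain_annotation import AA_ALPHABET

    def make(length, pid="random"):
        return ProteinRecord(
            id=pid, sequence="".join(rng.choice(list(AA_ALPHABET), size=length))
        )

    return make
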