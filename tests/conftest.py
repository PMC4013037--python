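import numpy as np
import pytest

from protomito import cox3_pl, operon_classifier, similarity_scoring


@pytest.fixture(scope="session")
def cox3_reference():
    return operon_classifier.load_cox3_reference()


@pytest.fixture(scope="session")
def pl_sites():
    return cox3_pl.load_site_map()


@pytest.fixture(scope="session")
def cox4_tm1_refs():
    return {
        k: v.residues
        for k, v in similarity_scoring.load_reference_blocks().items()
        if "TM1" in k
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240507)
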