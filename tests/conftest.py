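import numpy as np
import pytest

import traitlearn as tl


@pytest.fixture(scope="session")
def lexicon():
    return tl.build_default_lexicon()


@pytest.fixture(scope="session")
def block_sim(lexicon):
    return tl.block_similarity(lexicon)


@pytest.fixture(scope="session")
def small_study():
    """A reduced study (3 + 3 participants) shared by read-only tests."""
    return tl.make_study(design=tl.StudyDesign(n_bpd=3, n_con=3, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
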