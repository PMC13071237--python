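import numpy as np
import pytest

from phrasetrack import melody


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def regular_seq():
    structure = melody.generate_phrase_structure("regular", 3, 74.4, 7)
    return melody.render_melody(structure, seed=7, melody_id="reg-0")


@pytest.fixture(scope="session")
def irregular_seq():
    structure = melody.generate_phrase_structure("irregular", 6, 74.4, 11)
    return melody.render_melody(structure, seed=11, melody_id="irr-0")
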