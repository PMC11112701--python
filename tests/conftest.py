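import numpy as np
import pytest

from srtsim.corpus import generate_corpus
from srtsim.listeners import CONDITIONS, ListenerModel


@pytest.fixture(scope="session")
def corpus():
    return generate_corpus(12345)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_listener(srt=-5.0, slope=2.0, rho=0.0, subject_id="S001", age=10.0):
    return ListenerModel(
        subject_id=subject_id,
        age_years=age,
        true_srt_db={c: srt for c in CONDITIONS},
        slope_db=slope,
        keyword_rho=rho,
    )


@pytest.fixture()
def listener():
    return make_listener()
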