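import numpy as np
import pytest

from suldex.bbm import BBMData
from suldex.binding_core import OligoSet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_oligo_set():
    """3 oligos with 2 references; counts drawn once and frozen."""
    return OligoSet(
        sequences=["AAAA", "CCCC", "GGGG"],
        pre_counts=np.array([108, 105, 87]),
        bound_counts=np.array([207, 33, 60]),
        reference_kds={"AAAA": 2.0, "CCCC": 20.0},
    )


@pytest.fixture
def toy_data(toy_oligo_set):
    return BBMData(oligo_set=toy_oligo_set)


def exact_system(kds, tf_free, P=None):
    """Noise-free (P, B) for given Kds and tf (independent of binding_core)."""
    kds = np.asarray(kds, dtype=float)
    if P is None:
        P = np.full(len(kds), 1.0 / len(kds))
    P = np.asarray(P, dtype=float)
    theta = tf_free / (tf_free + kds)
    w = P * theta
    return P, w / w.sum(), theta
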