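import numpy as np
import pytest

from pmfesn.io import MODALITIES
from pmfesn.preprocess import PreparedSample


def make_sample(case_id, mrs, shape=(8, 8, 3), rng=None, offset=0.0):
    """Random prepared sample; ``offset`` shifts all slabs (class signal)."""
    rng = rng or np.random.default_rng(0)
    slabs = {m: rng.normal(0.0, 1.0, size=shape) + offset for m in MODALITIES}
    return PreparedSample(case_id=case_id, slabs=slabs, mrs=mrs)


def make_class_samples(counts, shape=(8, 8, 3), seed=0, effect=0.0, noise=1.0):
    """One sample set with ``counts[m]`` members of class m.

    Each class has a distinct mean level ``effect * (1 + m)`` on all slabs,
    so ``effect >> noise`` gives linearly separable classes.
    """
    rng = np.random.default_rng(seed)
    out = []
    for m, k in enumerate(counts):
        for j in range(k):
            slabs = {
                mod: rng.normal(0.0, noise, size=shape) + effect * (1 + m)
                for mod in MODALITIES
            }
            out.append(PreparedSample(case_id=f"c{m}_{j}", slabs=slabs, mrs=m))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
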