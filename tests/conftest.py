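import numpy as np
import pytest

from captor.scan import TargetSite

BASES = np.array(list("ACGT"))


@pytest.fixture
def s1():
    return TargetSite("S1", "GCTCCCTACGCATGCGTCCC")


@pytest.fixture
def s2():
    return TargetSite("S2", "AATGGCTCAGGTTTGTCGCG")


def random_seq(rng, n, p=None):
    return "".join(BASES[rng.choice(4, size=n, p=p)])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
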