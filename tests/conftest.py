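import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rsdlite.evodist import build_rate_model
from rsdlite.pairwise import ScoringScheme
from rsdlite.seqio import AMINO_ACIDS, ProteinSequence

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme.blosum62()


@pytest.fixture(scope="session")
def jtt():
    return build_rate_model("JTT", alpha=1.0, K=4)


@pytest.fixture(scope="session")
def jtt_plain():
    return build_rate_model("JTT", alpha=math.inf, K=1)


@pytest.fixture(scope="session")
def poisson_plain():
    return build_rate_model("Poisson", alpha=math.inf, K=1)


def random_protein(rng: np.random.Generator, length: int, name: str = "p") -> ProteinSequence:
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return ProteinSequence(name, seq)
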