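import numpy as np
import pytest

from mitocomp.synthetic import SyntheticSpec, generate_mitogenome


@pytest.fixture(scope="session")
def default_genome():
    """One synthetic genome + truth shared across read-only tests."""
    return generate_mitogenome(SyntheticSpec(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240706)


def random_dna(rng, n, at=0.7):
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
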