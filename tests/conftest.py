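import warnings

import numpy as np
import pytest

from hgga import make_fixture

warnings.filterwarnings("ignore", message="pruned .* markers")


@pytest.fixture(scope="session")
def tiny_fixture():
    """Small single-chromosome bundle for fast pipeline tests."""
    return make_fixture("tiny", seed=7)


@pytest.fixture(scope="session")
def standard_fixture():
    """2 x 100 kb chromosomes, 30x error-free 8 kb reads, dense map."""
    return make_fixture("standard", seed=11)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
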