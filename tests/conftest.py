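import numpy as np
import pytest

from divrep.alphabet import recode_sequence
from divrep.pwm import NormalizedWeightMatrix, build_probe


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tandem_matrix():
    """Hand-crafted 3-periodic matrix: +10 on the pair categories realised by
    the tandem sequence 1,2,3,1,2,3,..., -10 elsewhere."""
    n = 3
    mt = np.full((n, 25), -10.0)
    pattern = [1, 2, 3]
    for j in range(n):  # probe position j+1 holds pattern[j]
        prev = pattern[(j - 1) % n]
        cur = pattern[j]
        mt[j, (prev - 1) + 5 * (cur - 1)] = 10.0
    return NormalizedWeightMatrix(n=n, matrix=mt)


def make_recode(symbols):
    """Wrap raw 1..5 symbols as a recoded sequence (via group letters)."""
    from divrep.alphabet import GROUPS, GROUP_LETTERS

    letters = "".join(GROUPS[GROUP_LETTERS[s - 1]][0] for s in symbols)
    return recode_sequence(letters, id="raw")


@pytest.fixture
def probe12():
    return build_probe(3, 12)
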