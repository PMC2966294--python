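import itertools

import numpy as np
import pytest

from aakernels import (
    Alphabet,
    SubstringKernelSpec,
    get_encoding,
    load_builtin_encoding,
    standardize_encoding,
)

ABCD = Alphabet("ABCD")


@pytest.fixture(scope="session")
def abcd():
    return ABCD


@pytest.fixture(scope="session")
def abcd_unit():
    return load_builtin_encoding("unit", ABCD)


@pytest.fixture(scope="session")
def abcd_toy_encoding():
    """Injective 2-D encoding of a 4-letter alphabet with varied geometry."""
    from aakernels import AAEncoding

    vectors = {
        "A": np.array([1.0, 0.2]),
        "B": np.array([0.9, 0.3]),  # close to A
        "C": np.array([-1.0, 1.5]),
        "D": np.array([0.0, -2.0]),
    }
    return AAEncoding("toy2d", ABCD, vectors)


@pytest.fixture(scope="session")
def unit20():
    return load_builtin_encoding("unit")


@pytest.fixture(scope="session")
def zscale_std():
    return get_encoding("zscale")


@pytest.fixture(scope="session")
def blosum50_std():
    return get_encoding("blosum50")


def random_seqs(rng, n, length, alphabet, var_length=None):
    """n random sequences over `alphabet` (fixed or variable length)."""
    letters = np.array(list(alphabet.letters))
    out = []
    for _ in range(n):
        L = length if var_length is None else int(rng.integers(*var_length))
        out.append("".join(rng.choice(letters, size=L)))
    return out


def all_lmers(alphabet, l):
    return ["".join(t) for t in itertools.product(alphabet.letters, repeat=l)]
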