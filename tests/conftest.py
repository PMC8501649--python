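import numpy as np
import pytest

from vlmc import encode_corpus


@pytest.fixture
def cacac_corpus():
    """The worked-example string CACAC, encoded as C A C A C $."""
    return encode_corpus(["CACAC"])


@pytest.fixture
def random_sequence():
    """Factory for reproducible random DNA, optionally with ambiguity codes."""

    def make(seed: int, n: int, n_fraction: float = 0.0) -> str:
        rng = np.random.default_rng(seed)
        if n_fraction > 0:
            p = [(1 - n_fraction) / 4] * 4 + [n_fraction]
            return "".join(rng.choice(list("ACGTN"), size=n, p=p))
        return "".join(rng.choice(list("ACGT"), size=n))

    return make
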