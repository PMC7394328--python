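import numpy as np
import pytest

from mddsite.alphabet import AA20
from mddsite.seqio import Fragment


def make_fragment(sequence: str, protein_id: str = "p", center: int = 11,
                  label: str = "unlabeled") -> Fragment:
    return Fragment(protein_id, center, sequence, label)


def random_fragments(rng: np.random.Generator, count: int, n: int = 10,
                     label: str = "unlabeled") -> list[Fragment]:
    """i.i.d. uniform-background windows with centre K."""
    out = []
    for i in range(count):
        window = list(rng.choice(list(AA20), size=2 * n + 1))
        window[n] = "K"
        out.append(Fragment(f"r{i}", n + 1, "".join(window), label))
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
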