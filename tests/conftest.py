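import numpy as np
import pytest

from lsgkit.motifscan import PWM


@pytest.fixture
def toy_pwm() -> PWM:
    """Width-4 matrix f = [(A:1),(C:1),(G:.5,T:.5),(T:1)] from a depth of 10."""
    counts = 10 * np.array(
        [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 0.5, 0.5], [0, 0, 0, 1]]
    )
    return PWM("TOY", counts)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_pwm(rng, width: int, depth: int = 12) -> PWM:
    """A random informative PWM for oracle comparisons."""
    counts = np.zeros((width, 4))
    for pos in range(width):
        major = int(rng.integers(4))
        m = int(rng.integers(int(0.6 * depth), depth + 1))
        counts[pos, major] = m
        counts[pos] += rng.multinomial(depth - m, [0.25] * 4)
    return PWM(f"R{rng.integers(1e6)}", counts)


def random_seq(rng, length: int, n_frac: float = 0.0) -> str:
    bases = np.array(list("ACGT"))
    s = bases[rng.integers(0, 4, size=length)]
    if n_frac > 0:
        mask = rng.random(length) < n_frac
        s[mask] = "N"
    return "".join(s)
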