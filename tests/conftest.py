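import numpy as np
import pytest

from kfmindex import Sequence, SyntheticSpec, generate_sequence

MODES = ("uniform_random", "self_concatenated", "tandem_repeat")
K_GRID = (1, 2, 4, 8, 16, 32, None)


def seq_of(s: str, name: str = "t") -> Sequence:
    return Sequence.from_string(s, name=name)


def fuzz_sequences(n_cases: int, seed: int = 0, max_len: int = 600, min_len: int = 10):
    """Deterministic stream of (sequence, k) pairs cycling modes and k values."""
    rng = np.random.default_rng(seed)
    for i in range(n_cases):
        mode = MODES[i % len(MODES)]
        unit = ("AT", "ACG", "A")[i % 3]
        spec = SyntheticSpec(
            length=int(rng.integers(min_len, max_len)),
            mode=mode,
            seed=int(rng.integers(0, 2**31 - 1)),
            repeat_unit=unit,
        )
        yield generate_sequence(spec), K_GRID[i % len(K_GRID)]


@pytest.fixture
def cattag() -> Sequence:
    return seq_of("CATTAG")
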