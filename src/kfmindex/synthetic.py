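"""Deterministic synthetic genomes for testing and self-validation.

Three generation modes cover the regimes that matter for k-ordered suffix
sorting: ``uniform_random`` (i.i.d. ACGT, the easy case with few long shared
prefixes), ``self_concatenated`` (a random genome followed by an exact copy
of itself — the worst case for direct prefix sorting, every suffix in the
first half shares a huge prefix with its twin), and ``tandem_repeat`` (a
short unit cycled to length, maximal local periodicity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reference_io import SENTINEL, Sequence

__all__ = ["SyntheticSpec", "generate_sequence"]

_MODES = ("uniform_random", "self_concatenated", "tandem_repeat")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic genome; same spec + seed → identical sequence.

    ``length`` counts ACGT symbols (the sentinel is appended on top).
    """

    length: int
    mode: str = "uniform_random"
    seed: int = 0
    repeat_unit: str = "AT"

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.length < 1:
            raise ValueError("length must be >= 1")


def generate_sequence(spec: SyntheticSpec) -> Sequence:
    """Materialize a :class:`SyntheticSpec` into a sentinel-terminated Sequence."""
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "uniform_random":
        body = rng.integers(1, 5, size=spec.length).astype(np.uint8)
    elif spec.mode == "self_concatenated":
        half = spec.length // 2
        if half < 1:
            raise ValueError("self_concatenated needs length >= 2")
        unit = rng.integers(1, 5, size=half).astype(np.uint8)
        body = np.concatenate([unit, unit])
    else:  # tandem_repeat
        unit = Sequence.from_string(spec.repeat_unit).text[:-1]
        if unit.size == 0:
            raise ValueError("repeat_unit must be non-empty")
        reps = -(-spec.length // unit.size)
        body = np.tile(unit, reps)[: spec.length]
    text = np.concatenate([body, np.array([SENTINEL], dtype=np.uint8)])
    name = f"synthetic_{spec.mode}_{spec.length}_{spec.seed}"
    return Sequence(text=text, name=name)
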