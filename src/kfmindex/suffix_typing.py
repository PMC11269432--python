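"""L/S suffix classification and LMS position identification.

A suffix is S-type when it is lexicographically smaller than the suffix
starting one position to its right, L-type when larger; on equal leading
characters the type is inherited from the right neighbour.  The sentinel
suffix is S-type by convention.  An LMS (left-most S) position is an S-type
position whose left neighbour is L-type; the sentinel position always
qualifies and position 0 never does.
"""

from __future__ import annotations

import numpy as np

from .reference_io import Sequence

__all__ = ["classify_ls_types", "find_lms_positions"]


def classify_ls_types(seq: Sequence) -> np.ndarray:
    """Boolean array over text positions, ``True`` = S-type.

    Vectorized equivalent of the right-to-left recurrence: a position with
    ``text[i] != text[i+1]`` is decided locally; runs of equal characters
    inherit the decision of the first differing position to their right.
    """
    text = seq.text
    n = len(text)
    val = np.empty(n, dtype=np.int8)
    val[-1] = 1  # sentinel is S
    lt = text[:-1] < text[1:]
    gt = text[:-1] > text[1:]
    val[:-1] = 0
    val[:-1][lt] = 1
    decided = np.empty(n, dtype=bool)
    decided[:-1] = lt | gt
    decided[-1] = True
    # backward fill from the nearest decided position on the right
    rev_val = val[::-1]
    rev_dec = decided[::-1]
    idx = np.where(rev_dec, np.arange(n), 0)
    np.maximum.accumulate(idx, out=idx)
    return rev_val[idx][::-1].astype(bool)


def find_lms_positions(is_s: np.ndarray) -> np.ndarray:
    """Strictly increasing LMS positions (S-type with an L-type left neighbour)."""
    is_s = np.asarray(is_s, dtype=bool)
    return (np.flatnonzero(is_s[1:] & ~is_s[:-1]) + 1).astype(np.int64)
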