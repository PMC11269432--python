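"""Independent brute-force oracles.

Everything here is deliberately naive — direct comparisons and scans with
no shared machinery with the construction pipeline — so the main algorithms
can be validated against first principles.  Guards keep the quadratic work
bounded.
"""

from __future__ import annotations

import numpy as np

from .reference_io import Sequence

__all__ = [
    "naive_korder_sa",
    "naive_suffix_types",
    "naive_find",
    "kprefix_group_ids",
]

_GUARD = 20_000


def naive_korder_sa(seq: Sequence, k=None, guard: int = _GUARD) -> np.ndarray:
    """Reference k-ordered suffix array: stable sort by (first-k chars, position)."""
    n = seq.n
    if n > guard:
        raise ValueError(f"text length {n} exceeds the oracle guard {guard}")
    tb = seq.text.tobytes()
    if k is None:
        order = sorted(range(n), key=lambda i: tb[i:])
    else:
        order = sorted(range(n), key=lambda i: tb[i : i + k])
    return np.asarray(order, dtype=np.int64)


def naive_suffix_types(seq: Sequence) -> np.ndarray:
    """True = S-type, by direct lexicographic comparison of adjacent suffixes."""
    tb = seq.text.tobytes()
    n = seq.n
    out = np.empty(n, dtype=bool)
    out[-1] = True
    for i in range(n - 2, -1, -1):
        out[i] = tb[i:] < tb[i + 1 :]
    return out


def naive_find(seq: Sequence, pattern: str) -> np.ndarray:
    """All occurrence positions of ``pattern`` in the text body, by direct scan."""
    pat = Sequence.from_string(pattern).text[:-1].tobytes()
    tb = seq.text[:-1].tobytes()
    hits = []
    start = tb.find(pat)
    while start != -1:
        hits.append(start)
        start = tb.find(pat, start + 1)
    return np.asarray(hits, dtype=np.int64)


def kprefix_group_ids(seq: Sequence, order: np.ndarray, k) -> np.ndarray:
    """Group id per row of ``order``: rows with equal first-k characters share an id.

    Used to compare equal-k-prefix partitions between arrays whose
    intra-group tie order may legitimately differ.
    """
    tb = seq.text.tobytes()
    order = np.asarray(order)
    ids = np.empty(len(order), dtype=np.int64)
    gid = 0
    prev = None
    for i, p in enumerate(order.tolist()):
        key = tb[p:] if k is None else tb[p : p + k]
        if prev is not None and key != prev:
            gid += 1
        ids[i] = gid
        prev = key
    return ids
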