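"""Induced sorting: from ordered LMS suffixes to the k-ordered suffix array.

Standard two-scan induction (induced copying): the ordered LMS positions are
placed at the tails of their first-character buckets, a left-to-right scan
induces L-type predecessors into bucket heads, and a right-to-left scan
induces S-type predecessors into bucket tails (rewriting the provisional LMS
placements).  When the LMS input is fully sorted the result is the exact
suffix array; when it is k-ordered the result is k-ordered: induction
extends each placed suffix's decided prefix by one character.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lms_sort import (
    UNBOUNDED,
    encode_reduced_reference,
    prefix_double_ranks,
    sort_lms_bucket_split,
    sort_lms_direct,
)
from .reference_io import Sequence
from .suffix_typing import classify_ls_types, find_lms_positions

__all__ = ["KOrderedSuffixArray", "induce_from_lms", "build_korder_sa", "stabilize"]

_SIGMA = 5  # $ACGT


@dataclass
class KOrderedSuffixArray:
    """Permutation of text positions ordered by first-k characters.

    ``k is None`` means unbounded (a true suffix array).  ``meta`` records
    build provenance (strategy, parameters, doubling rounds).
    """

    order: np.ndarray
    k: int | None
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.order)


def _bucket_bounds(text: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    counts = np.bincount(text, minlength=_SIGMA)
    starts = np.zeros(_SIGMA + 1, dtype=np.int64)
    np.cumsum(counts, out=starts[1:])
    return starts[:-1].copy(), starts[1:].copy()


def induce_from_lms(
    seq: Sequence, is_s: np.ndarray, sorted_lms: np.ndarray, k=UNBOUNDED
) -> KOrderedSuffixArray:
    """Derive the order of all suffixes from the ordered LMS suffixes."""
    text = seq.text
    n = len(text)
    is_s = np.asarray(is_s, dtype=bool)
    sorted_lms = np.asarray(sorted_lms, dtype=np.int64)
    if len(is_s) != n:
        raise ValueError("type array length does not match the text")
    lms_set = find_lms_positions(is_s)
    if sorted_lms.size != lms_set.size or not np.array_equal(
        np.sort(sorted_lms), lms_set
    ):
        raise ValueError("sorted_lms is not a permutation of the LMS set")

    starts, ends = _bucket_bounds(text)
    sa = np.full(n, -1, dtype=np.int64)

    # 1) LMS tails, in reverse given order
    tails = ends.copy()
    for p in sorted_lms[::-1]:
        c = text[p]
        tails[c] -= 1
        sa[tails[c]] = p

    # 2) induce L-type predecessors left-to-right into bucket heads
    heads = starts.copy()
    for i in range(n):
        j = sa[i]
        if j > 0 and not is_s[j - 1]:
            c = text[j - 1]
            sa[heads[c]] = j - 1
            heads[c] += 1

    # 3) induce S-type predecessors right-to-left into bucket tails
    tails = ends.copy()
    for i in range(n - 1, -1, -1):
        j = sa[i]
        if j > 0 and is_s[j - 1]:
            c = text[j - 1]
            tails[c] -= 1
            sa[tails[c]] = j - 1
    return KOrderedSuffixArray(order=sa, k=None if k is UNBOUNDED else int(k))


def build_korder_sa(
    seq: Sequence,
    k=UNBOUNDED,
    strategy: int = 1,
    *,
    l: int = 3,
    l_bucket: int = 0,
    stabilized: bool = False,
) -> KOrderedSuffixArray:
    """Full pipeline: classify types, find LMS, k-order them, induce.

    ``strategy`` 1 sorts LMS k-prefixes directly (``l_bucket > 0`` enables
    the bucket-split variant); strategy 2 encodes the reduced reference with
    segment length ``l`` and ranks it by prefix doubling.  ``stabilized``
    applies the optional position-sort within equal-k-prefix groups of the
    final array (for reproducible serialization comparisons).
    """
    is_s = classify_ls_types(seq)
    lms = find_lms_positions(is_s)
    meta: dict = {"strategy": strategy, "k": None if k is UNBOUNDED else int(k)}
    if strategy == 1:
        if l_bucket > 0:
            ordered = sort_lms_bucket_split(seq, lms, k, l_bucket=l_bucket)
            meta["l_bucket"] = l_bucket
        else:
            ordered = sort_lms_direct(seq, lms, k)
    elif strategy == 2:
        reduced = encode_reduced_reference(seq, lms, l=l)
        stats: dict = {}
        ordered = prefix_double_ranks(reduced, k, stats=stats)
        meta["l"] = l
        meta["doubling_rounds"] = stats["rounds"]
    else:
        raise ValueError(f"strategy must be 1 or 2, got {strategy}")
    sa = induce_from_lms(seq, is_s, ordered, k)
    sa.meta = meta
    if stabilized:
        sa = stabilize(seq, sa)
        sa.meta = dict(meta, stabilized=True)
    return sa


def stabilize(seq: Sequence, sa: KOrderedSuffixArray) -> KOrderedSuffixArray:
    """Position-sort within equal-k-prefix groups.

    The induction pipeline leaves intra-group tie order unspecified; this
    optional pass imposes ascending text position inside every group of rows
    sharing the same first-k characters, making arrays from different
    build routes comparable element-wise.
    """
    tb = seq.text.tobytes()
    k = sa.k
    order = sa.order
    out = np.empty_like(order)
    n = len(order)
    i = 0
    while i < n:
        p = int(order[i])
        key = tb[p:] if k is None else tb[p : p + k]
        j = i + 1
        while j < n:
            q = int(order[j])
            if (tb[q:] if k is None else tb[q : q + k]) != key:
                break
            j += 1
        out[i:j] = np.sort(order[i:j])
        i = j
    return KOrderedSuffixArray(order=out, k=k, meta=dict(sa.meta, stabilized=True))
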