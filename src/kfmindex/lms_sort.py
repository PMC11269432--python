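"""k-ordered sorting of LMS suffixes.

Two interchangeable strategies order the LMS suffixes by their first k
characters:

* **Strategy 1** — direct comparison sort of the k-prefixes (optionally
  split into buckets keyed by a short leading l-mer first).
* **Strategy 2** — the text is compacted into a *reduced reference*: each
  LMS substring (the span between consecutive LMS positions, inclusive) is
  cut into consecutive l-mers, each l-mer encoded as one base-5 integer
  (sentinel included in the digit set, so the encoding is order-preserving
  over the coded alphabet).  Prefix doubling with singleton exclusion then
  ranks the reduced suffixes; the LMS order is read off at the recorded
  offsets.

The normative tie rule everywhere is *stable by text position*: suffixes
whose first k characters are equal appear in ascending position order.  Both
strategies produce bit-identical output under this rule, which the brute
force oracle in :mod:`kfmindex.oracles` also follows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .reference_io import SENTINEL, Sequence

__all__ = [
    "UNBOUNDED",
    "ReducedReference",
    "sort_lms_direct",
    "sort_lms_bucket_split",
    "segment_substring",
    "encode_reduced_reference",
    "prefix_double_ranks",
]

#: Marker for a full (unbounded-k) lexicographic order.
UNBOUNDED = None


def _norm_k(k) -> int | None:
    if k is UNBOUNDED:
        return None
    k = int(k)
    if k < 1:
        raise ValueError(f"k must be >= 1 or UNBOUNDED, got {k}")
    return k


def _prefix_key(text_bytes: bytes, pos: int, k: int | None) -> bytes:
    """First min(k, remaining) characters as a bytes sort key.

    Symbol codes are single bytes with the sentinel smallest, so bytewise
    comparison equals lexicographic comparison; a shorter suffix that is a
    prefix of a longer one sorts first, matching sentinel-terminated order.
    """
    return text_bytes[pos:] if k is None else text_bytes[pos : pos + k]


def sort_lms_direct(seq: Sequence, lms: np.ndarray, k=UNBOUNDED) -> np.ndarray:
    """Strategy 1: sort LMS positions by (first-k characters, position)."""
    k = _norm_k(k)
    tb = seq.text.tobytes()
    order = sorted(np.asarray(lms).tolist(), key=lambda p: _prefix_key(tb, p, k))
    return np.asarray(order, dtype=np.int64)


def sort_lms_bucket_split(
    seq: Sequence, lms: np.ndarray, k=UNBOUNDED, l_bucket: int = 10
) -> np.ndarray:
    """Strategy 1 bucket-split variant: partition by the leading l-mer, then
    sort within each bucket.  Output is identical to :func:`sort_lms_direct`.
    """
    k = _norm_k(k)
    if l_bucket < 1:
        raise ValueError("l_bucket must be >= 1")
    l_eff = l_bucket if k is None else min(l_bucket, k)
    tb = seq.text.tobytes()
    buckets: dict[bytes, list[int]] = {}
    for p in np.asarray(lms).tolist():
        buckets.setdefault(tb[p : p + l_eff], []).append(p)
    out: list[int] = []
    for bkey in sorted(buckets):
        out.extend(sorted(buckets[bkey], key=lambda p: _prefix_key(tb, p, k)))
    return np.asarray(out, dtype=np.int64)


@dataclass
class ReducedReference:
    """Base-encoded compaction of the LMS substrings.

    ``symbols[lms_offsets[j]:]`` is the integer rendering of the j-th LMS
    suffix: consecutive l-mers of its substring, with a short final l-mer
    completed from the characters that follow in the original text
    (equivalently, prefixes of subsequent LMS substrings) and sentinel-padded
    past the text end.
    """

    symbols: np.ndarray
    lms_offsets: np.ndarray
    lms_positions: np.ndarray
    l: int
    base: int = 5
    text: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.lms_offsets) != len(self.lms_positions):
            raise ValueError("lms_offsets and lms_positions length mismatch")
        if len(self.symbols) < len(self.lms_offsets):
            raise ValueError("reduced reference shorter than the LMS count")
        if np.any(np.diff(self.lms_offsets) <= 0):
            raise ValueError("lms_offsets must be strictly increasing")


def segment_substring(
    text: np.ndarray, start: int, stop_inclusive: int, l: int
) -> list[np.ndarray]:
    """Cut one LMS substring into its l-mer chunks.

    The substring spans ``start .. stop_inclusive`` (the next LMS position,
    or the sentinel).  Chunks are consecutive l-mers read from the *original
    text* starting at ``start``; the final short chunk is completed with the
    characters following the substring and sentinel-padded past the text
    end.  E.g. substring ``ACCTA`` with l=3 followed by ``A...`` yields
    ``ACC`` and ``TAA``.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    length = stop_inclusive - start + 1
    if length < 1:
        raise ValueError("empty LMS substring span")
    n_chunks = -(-length // l)
    chunks = []
    for t in range(n_chunks):
        lo = start + t * l
        piece = text[lo : lo + l]
        if len(piece) < l:
            piece = np.concatenate(
                [piece, np.full(l - len(piece), SENTINEL, dtype=text.dtype)]
            )
        chunks.append(piece)
    return chunks


def encode_reduced_reference(
    seq: Sequence, lms: np.ndarray, l: int = 3
) -> ReducedReference:
    """Strategy 2 encoding step: build the reduced reference.

    Each l-mer chunk maps to ``sum(digit(c) * base**(l-1-j))`` with base 5
    (the sentinel participates as digit 0), a positional encoding that
    preserves character order between aligned chunks.
    """
    lms = np.asarray(lms, dtype=np.int64)
    if lms.size == 0:
        raise ValueError("LMS set is empty")
    base = 5
    if l < 1 or base**l > np.iinfo(np.int64).max // base:
        raise ValueError(f"segment length l={l} out of the supported range")
    text = seq.text
    n = len(text)
    weights = base ** np.arange(l - 1, -1, -1, dtype=np.int64)

    # pad so every chunk window is full-width, then encode all chunk starts
    padded = np.concatenate([text, np.full(l, SENTINEL, dtype=text.dtype)])
    stops = np.concatenate([lms[1:], [np.int64(n - 1)]])
    lengths = stops - lms + 1
    counts = -(-lengths // l)
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(np.int64)
    total = int(counts.sum())
    starts = np.empty(total, dtype=np.int64)
    # chunk t of substring j starts at lms[j] + t*l
    pos = 0
    for j in range(len(lms)):
        c = int(counts[j])
        starts[pos : pos + c] = lms[j] + l * np.arange(c)
        pos += c
    windows = padded[starts[:, None] + np.arange(l)]
    symbols = windows.astype(np.int64) @ weights
    return ReducedReference(
        symbols=symbols,
        lms_offsets=offsets,
        lms_positions=lms,
        l=l,
        base=base,
        text=text,
    )


def _dense_rank_start(values: np.ndarray) -> np.ndarray:
    """Rank each value by the index of its group's first slot in sorted order."""
    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    new_group = np.empty(len(values), dtype=bool)
    new_group[0] = True
    new_group[1:] = sorted_vals[1:] != sorted_vals[:-1]
    group_start = np.maximum.accumulate(
        np.where(new_group, np.arange(len(values)), 0)
    )
    rank = np.empty(len(values), dtype=np.int64)
    rank[order] = group_start
    return rank


def _finalize_bounded(
    text: np.ndarray, positions: np.ndarray, ranks: np.ndarray, k: int
) -> np.ndarray:
    """Resolve residual rank structure against the exact k-prefix tie rule.

    Doubling over l-mer symbols can leave an order that is finer (decided by
    characters past k) or, for unfavourable l, coarser (rank ties spanning
    distinct k-prefixes) than the k-prefix partition.  Cross-rank order is
    always consistent with true lexicographic order, so both defects are
    local: rank-tie groups are resolved by direct k-prefix comparison, then
    maximal runs of equal k-prefixes are re-sorted by ascending position.
    """
    tb = text.tobytes()
    order = np.lexsort((positions, ranks))
    pos_sorted = positions[order]
    rank_sorted = ranks[order]
    out: list[int] = []
    i = 0
    m = len(pos_sorted)
    while i < m:
        j = i
        while j < m and rank_sorted[j] == rank_sorted[i]:
            j += 1
        group = pos_sorted[i:j].tolist()
        if len(group) > 1:
            group.sort(key=lambda p: (tb[p : p + k], p))
        out.extend(group)
        i = j
    # merge adjacent equal-k-prefix runs across former rank boundaries
    final: list[int] = []
    i = 0
    while i < len(out):
        j = i + 1
        key = tb[out[i] : out[i] + k]
        while j < len(out) and tb[out[j] : out[j] + k] == key:
            j += 1
        run = sorted(out[i:j])
        final.extend(run)
        i = j
    return np.asarray(final, dtype=np.int64)


def prefix_double_ranks(
    reduced: ReducedReference, k=UNBOUNDED, stats: dict | None = None
) -> np.ndarray:
    """Strategy 2 ranking step: prefix doubling over the reduced reference.

    Initial ranks come from single symbols (span ``h = 1``).  Each round
    orders the still-ambiguous (non-singleton) positions by the pair
    ``(rank[i], rank[i+h])`` — an out-of-range second component ranks below
    everything — refines the ranks in place, retires new singletons, and
    doubles ``h``.  Rounds stop when the active set is empty, when
    ``h * l >= k`` (bounded k: ``h`` symbols cover at least the first k
    characters needed), or when ``h`` reaches the reduced length (unbounded).

    Returns the LMS positions ordered by final rank with the stable position
    tie rule; ``stats`` (if given) receives ``{"rounds": int}``.
    """
    k = _norm_k(k)
    sym = reduced.symbols
    m = len(sym)
    rank = _dense_rank_start(sym)
    active = np.flatnonzero(np.bincount(rank, minlength=m)[rank] > 1)
    h = 1
    rounds = 0
    while active.size:
        if k is not None and h * reduced.l >= k:
            break
        if h >= m:
            break
        second = np.zeros(active.size, dtype=np.int64)
        in_range = active + h < m
        second[in_range] = rank[active[in_range] + h] + 1
        order_in = np.lexsort((second, rank[active]))
        sa_pos = active[order_in]
        sr = rank[active][order_in]
        ss = second[order_in]
        new_block = np.empty(sa_pos.size, dtype=bool)
        new_block[0] = True
        new_block[1:] = sr[1:] != sr[:-1]
        new_run = new_block.copy()
        new_run[1:] |= ss[1:] != ss[:-1]
        idx = np.arange(sa_pos.size)
        block_start = np.maximum.accumulate(np.where(new_block, idx, 0))
        run_start = np.maximum.accumulate(np.where(new_run, idx, 0))
        rank[sa_pos] = sr + (run_start - block_start)
        run_id = np.cumsum(new_run) - 1
        run_len = np.bincount(run_id)
        active = sa_pos[run_len[run_id] > 1]
        h *= 2
        rounds += 1
    if stats is not None:
        stats["rounds"] = rounds
        stats["h_final"] = h
    positions = reduced.lms_positions
    lms_ranks = rank[reduced.lms_offsets]
    if k is None:
        order = np.lexsort((positions, lms_ranks))
        return positions[order]
    return _finalize_bounded(reduced.text, positions, lms_ranks, k)
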