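"""The k-ordered FM-index: Schindler transform, count, and locate.

The index stores, instead of the BWT, the Schindler transform — the last
column of the rotations sorted only by their first k characters — plus the
classical bucket-start (C) array, strided occurrence checkpoints, and a
value-sampled suffix array: rows whose suffix value is a multiple of the
sampling distance ``vd`` are marked and their values kept in row order.

Backward search (LF mapping) is valid on such an index as long as the total
extended pattern length stays within k, so ``count`` accepts patterns up to
length k.  ``locate`` must additionally explore left extensions of up to
``vd - 1`` characters to reach a sampled row, hence its pattern bound
``k - vd + 1``.  Two locate schemes are provided: depth-first enumeration of
left extensions (the sBWT scheme) and a breadth-first |Σ|-ary tree walk that
merges contiguous sibling ranges before extending them (the FMtree scheme),
which returns identical results with never more LF operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .induced_sort import KOrderedSuffixArray, build_korder_sa
from .lms_sort import UNBOUNDED
from .reference_io import ALPHABET, CODE, Sequence

__all__ = [
    "MatchRange",
    "KOrderedFMIndex",
    "PatternError",
    "schindler_transform",
    "build_fm_index",
    "indexes_equal",
]

_EXT_CODES = (1, 2, 3, 4)  # A C G T; the sentinel never precedes a match


class PatternError(ValueError):
    """Pattern violates the index's length or alphabet constraints."""


@dataclass(frozen=True)
class MatchRange:
    """Half-open row interval [begin, end) in the k-ordered suffix array."""

    begin: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.begin <= self.end:
            raise ValueError(f"invalid range [{self.begin}, {self.end})")

    @property
    def size(self) -> int:
        return self.end - self.begin

    def __bool__(self) -> bool:
        return self.end > self.begin


def schindler_transform(seq: Sequence, sa: KOrderedSuffixArray) -> np.ndarray:
    """Last column of the k-ordered rotation sort.

    ``transform[i] = text[(order[i] + n - 1) mod n]``; with unbounded k this
    is the classical BWT.
    """
    text = seq.text
    n = len(text)
    if len(sa.order) != n:
        raise ValueError("suffix array length does not match the text")
    return text[(sa.order + n - 1) % n]


@dataclass
class KOrderedFMIndex:
    """Queryable k-ordered FM-index (no full suffix array retained)."""

    transform: np.ndarray
    bucket_starts: np.ndarray  # length |Σ|+1 cumulative counts
    occ_checkpoints: np.ndarray  # (n_ckpt, |Σ|) counts at row strides
    sample_mark: np.ndarray  # bool per row: suffix value % vd == 0
    sample_values: np.ndarray  # marked values, in row order
    k: int | None
    vd: int
    n: int
    checkpoint_stride: int = 64
    sd: int | None = None  # subscript-sampling distance, metadata only
    alphabet: str = ALPHABET
    name: str = ""
    records: tuple = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # prefix counts of marks, for O(1) row -> sample slot mapping
        self._mark_cum = np.concatenate(
            [[0], np.cumsum(self.sample_mark.astype(np.int64))]
        )

    # -- low-level ---------------------------------------------------------

    def occ(self, c: int | str, r: int) -> int:
        """Occurrences of symbol ``c`` in ``transform[0:r]``."""
        c = self._code(c)
        if not 0 <= r <= self.n:
            raise ValueError(f"row {r} outside [0, {self.n}]")
        ck = r // self.checkpoint_stride
        base = int(self.occ_checkpoints[ck, c])
        lo = ck * self.checkpoint_stride
        return base + int(np.count_nonzero(self.transform[lo:r] == c))

    def _code(self, c: int | str) -> int:
        if isinstance(c, str):
            if c not in CODE:
                raise PatternError(f"symbol {c!r} not in alphabet {self.alphabet!r}")
            return CODE[c]
        c = int(c)
        if not 0 <= c < len(self.alphabet):
            raise PatternError(f"symbol code {c} not in alphabet")
        return c

    def backward_extend(self, rng: MatchRange, c: int | str) -> MatchRange:
        """LF-map a row range to the range of the pattern extended left by c."""
        c = self._code(c)
        b = int(self.bucket_starts[c]) + self.occ(c, rng.begin)
        e = int(self.bucket_starts[c]) + self.occ(c, rng.end)
        return MatchRange(b, e)

    def encode_pattern(self, pattern: str) -> np.ndarray:
        codes = []
        for ch in pattern.upper():
            if ch not in CODE or ch == "$":
                raise PatternError(f"pattern symbol {ch!r} outside ACGT")
            codes.append(CODE[ch])
        return np.asarray(codes, dtype=np.int64)

    # -- queries -----------------------------------------------------------

    def full_range(self) -> MatchRange:
        return MatchRange(0, self.n)

    def count(self, pattern: str) -> MatchRange:
        """Backward-search range of ``pattern``; its size is the hit count.

        Valid for patterns up to length k (the rotation order is only
        decided to depth k).  The empty pattern maps to the full range.
        """
        codes = self.encode_pattern(pattern)
        if self.k is not None and len(codes) > self.k:
            raise PatternError(
                f"pattern length {len(codes)} exceeds the index order k={self.k}"
            )
        rng = self.full_range()
        for c in codes[::-1]:
            rng = self.backward_extend(rng, int(c))
            if not rng:
                return rng
        return rng

    def _check_locate_length(self, m: int) -> None:
        if m < 1:
            raise PatternError("locate requires a non-empty pattern")
        if self.k is not None and m > self.k - self.vd + 1:
            raise PatternError(
                f"pattern length {m} exceeds k - vd + 1 = "
                f"{self.k - self.vd + 1} (k={self.k}, vd={self.vd}); "
                "left extensions of up to vd-1 characters must stay within "
                "the k-ordered depth"
            )

    def _harvest(self, rng: MatchRange, depth: int, out: list[int]) -> None:
        lo = int(self._mark_cum[rng.begin])
        hi = int(self._mark_cum[rng.end])
        if hi > lo:
            out.extend((self.sample_values[lo:hi] + depth).tolist())

    def locate_enumerate(self, pattern: str, stats: dict | None = None) -> np.ndarray:
        """Occurrence positions via depth-first left-extension enumeration.

        For every extension string s with 0 <= |s| < vd, sampled rows in the
        range of sP contribute ``value + |s|``; empty ranges prune the
        branch.  Each occurrence is reported exactly once (the extension
        depth is forced to ``position mod vd``).
        """
        self._check_locate_length(len(pattern))
        counter = {"backward_extends": 0}
        rng = self.count(pattern)
        out: list[int] = []

        def rec(r: MatchRange, depth: int) -> None:
            self._harvest(r, depth, out)
            if depth + 1 >= self.vd:
                return
            for c in _EXT_CODES:
                counter["backward_extends"] += 1
                child = self.backward_extend(r, c)
                if child:
                    rec(child, depth + 1)

        if rng:
            rec(rng, 0)
        if stats is not None:
            stats.update(counter)
        return np.asarray(sorted(out), dtype=np.int64)

    def locate_fmtree(self, pattern: str, stats: dict | None = None) -> np.ndarray:
        """Occurrence positions via the multiway-tree (FMtree) scheme.

        Breadth-first over extension depths: at each depth every node's
        sampled rows are harvested as one contiguous block, sibling ranges
        that abut in row space are merged, and only the merged ranges are
        LF-extended — identical output to :meth:`locate_enumerate` with
        never more backward extensions.
        """
        self._check_locate_length(len(pattern))
        counter = {"backward_extends": 0}
        rng = self.count(pattern)
        out: list[int] = []
        level: list[MatchRange] = [rng] if rng else []
        depth = 0
        while level:
            for r in level:
                self._harvest(r, depth, out)
            if depth + 1 >= self.vd:
                break
            merged = _merge_contiguous(level)
            nxt: list[MatchRange] = []
            for r in merged:
                for c in _EXT_CODES:
                    counter["backward_extends"] += 1
                    child = self.backward_extend(r, c)
                    if child:
                        nxt.append(child)
            level = nxt
            depth += 1
        if stats is not None:
            stats.update(counter)
        return np.asarray(sorted(out), dtype=np.int64)


def _merge_contiguous(ranges: list[MatchRange]) -> list[MatchRange]:
    """Fuse row ranges that are exactly adjacent (end == next begin)."""
    if len(ranges) <= 1:
        return list(ranges)
    srt = sorted(ranges, key=lambda r: r.begin)
    merged = [srt[0]]
    for r in srt[1:]:
        last = merged[-1]
        if r.begin == last.end:
            merged[-1] = MatchRange(last.begin, r.end)
        else:
            merged.append(r)
    return merged


def build_fm_index(
    seq: Sequence,
    k=UNBOUNDED,
    vd: int = 4,
    checkpoint_stride: int = 64,
    *,
    strategy: int = 1,
    l: int = 3,
    l_bucket: int = 0,
    sd: int | None = None,
    sa: KOrderedSuffixArray | None = None,
) -> KOrderedFMIndex:
    """Build the full index from a sequence (or a pre-built suffix array).

    The suffix array is consumed to produce the transform and the
    value-sampled rows, then dropped; only ceil(n/vd) values are retained.
    """
    if vd < 1:
        raise ValueError("vd must be >= 1")
    if checkpoint_stride < 1:
        raise ValueError("checkpoint_stride must be >= 1")
    k_val = None if k is UNBOUNDED else int(k)
    if k_val is not None and k_val - vd + 1 < 1:
        raise ValueError(
            f"k - vd + 1 = {k_val - vd + 1} < 1: no pattern could be located; "
            "increase k or decrease vd"
        )
    if sa is None:
        sa = build_korder_sa(seq, k, strategy, l=l, l_bucket=l_bucket)
    elif len(sa.order) != seq.n:
        raise ValueError("provided suffix array does not match the sequence")
    transform = schindler_transform(seq, sa)
    n = seq.n
    sigma = len(ALPHABET)
    counts = np.bincount(seq.text, minlength=sigma)
    bucket_starts = np.zeros(sigma + 1, dtype=np.int64)
    np.cumsum(counts, out=bucket_starts[1:])
    n_ckpt = n // checkpoint_stride + 1
    ckpt = np.zeros((n_ckpt, sigma), dtype=np.int64)
    for i in range(1, n_ckpt):
        block = transform[(i - 1) * checkpoint_stride : i * checkpoint_stride]
        ckpt[i] = ckpt[i - 1] + np.bincount(block, minlength=sigma)
    sample_mark = (sa.order % vd) == 0
    sample_values = sa.order[sample_mark].astype(np.int64)
    return KOrderedFMIndex(
        transform=transform,
        bucket_starts=bucket_starts,
        occ_checkpoints=ckpt,
        sample_mark=sample_mark,
        sample_values=sample_values,
        k=k_val,
        vd=int(vd),
        n=n,
        checkpoint_stride=int(checkpoint_stride),
        sd=sd,
        name=seq.name,
        records=seq.records,
        meta=dict(sa.meta),
    )


def indexes_equal(a: KOrderedFMIndex, b: KOrderedFMIndex) -> bool:
    """Field-by-field equality (used by serialization round-trip checks)."""
    return (
        a.k == b.k
        and a.vd == b.vd
        and a.sd == b.sd
        and a.n == b.n
        and a.checkpoint_stride == b.checkpoint_stride
        and a.alphabet == b.alphabet
        and a.name == b.name
        and tuple(a.records) == tuple(b.records)
        and np.array_equal(a.transform, b.transform)
        and np.array_equal(a.bucket_starts, b.bucket_starts)
        and np.array_equal(a.occ_checkpoints, b.occ_checkpoints)
        and np.array_equal(a.sample_mark, b.sample_mark)
        and np.array_equal(a.sample_values, b.sample_values)
    )
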