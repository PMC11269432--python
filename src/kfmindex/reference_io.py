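"""Reference sequence I/O and index serialization.

The in-memory text is a numpy ``uint8`` array of integer symbol codes over
the DNA alphabet plus a terminal sentinel.  Codes are ``$=0, A=1, C=2, G=3,
T=4``: the sentinel is strictly smaller than every real symbol (the standard
induced-sorting convention) and the codes double as base-5 digits for the
order-preserving l-mer encoding used by the prefix-doubling LMS sort.

Ambiguity codes are not kept: ``N``/``n`` is mapped to ``A`` on input, any
other non-ACGT character is rejected with the record name and offset.
Multi-record FASTA files are concatenated with no separator symbol; record
boundaries are retained as metadata so query hits can be reported per
record (BED output).
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "ALPHABET",
    "SENTINEL",
    "Sequence",
    "ReferenceIOError",
    "IndexFormatError",
    "read_fasta",
    "sequence_to_fasta",
    "save_index",
    "load_index",
]

ALPHABET = "$ACGT"
SENTINEL = 0
CODE = {c: i for i, c in enumerate(ALPHABET)}

# translation table: ASCII -> code, 0xFF marks invalid, N/n -> A
_LUT = np.full(256, 0xFF, dtype=np.uint8)
for _c, _i in CODE.items():
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i
_LUT[ord("N")] = CODE["A"]
_LUT[ord("n")] = CODE["A"]

_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


class ReferenceIOError(ValueError):
    """Malformed or unsupported reference input."""


class IndexFormatError(ValueError):
    """Corrupt, truncated, or incompatible index file."""


@dataclass
class Sequence:
    """Sentinel-terminated coded text.

    ``text`` holds integer codes; exactly one sentinel (code 0) sits at the
    final position.  ``records`` lists ``(name, start, length)`` for each
    concatenated FASTA record, used only for reporting.
    """

    text: np.ndarray
    name: str = ""
    records: tuple = ()

    def __post_init__(self) -> None:
        self.text = np.ascontiguousarray(self.text, dtype=np.uint8)
        n = len(self.text)
        if n < 1 or self.text[-1] != SENTINEL:
            raise ReferenceIOError("sequence must end with a single sentinel")
        body = self.text[:-1]
        if np.any(body == SENTINEL) or np.any(body > 4):
            raise ReferenceIOError("non-ACGT code inside sequence body")
        if not self.records:
            self.records = ((self.name or "seq", 0, n - 1),)

    @property
    def n(self) -> int:
        """Length including the sentinel."""
        return len(self.text)

    @classmethod
    def from_string(cls, s: str, name: str = "") -> "Sequence":
        """Build from a character string; a trailing ``$`` is optional."""
        if s.endswith("$"):
            s = s[:-1]
        raw = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
        codes = _LUT[raw]
        bad = np.flatnonzero(codes == 0xFF)
        if bad.size or "$" in s:
            off = int(bad[0]) if bad.size else s.index("$")
            raise ReferenceIOError(
                f"invalid character {s[off]!r} at offset {off} in {name or 'input'}"
            )
        text = np.concatenate([codes, np.array([SENTINEL], dtype=np.uint8)])
        return cls(text=text, name=name)

    def to_string(self) -> str:
        """Decoded text including the trailing ``$``."""
        return _DECODE[self.text].tobytes().decode("ascii")

    def body_string(self) -> str:
        return _DECODE[self.text[:-1]].tobytes().decode("ascii")

    def record_at(self, pos: int) -> tuple:
        """Record ``(name, start, length)`` containing text position ``pos``."""
        for name, start, length in self.records:
            if start <= pos < start + length:
                return name, start, length
        return self.records[-1]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Sequence)
            and self.name == other.name
            and self.records == other.records
            and np.array_equal(self.text, other.text)
        )


def _encode_record(rec_name: str, seq_str: str) -> np.ndarray:
    raw = np.frombuffer(seq_str.encode("ascii"), dtype=np.uint8)
    codes = _LUT[raw]
    bad = np.flatnonzero(codes == 0xFF)
    if bad.size:
        off = int(bad[0])
        raise ReferenceIOError(
            f"record {rec_name!r}: invalid character {seq_str[off]!r} at offset {off}"
        )
    return codes


def read_fasta(path, record_policy: str = "concatenate") -> Sequence:
    """Read a FASTA file into a coded, sentinel-terminated :class:`Sequence`.

    ``record_policy`` is ``"concatenate"`` (records joined in file order with
    no separator) or ``"first_only"``.  Symbols are uppercased, ``N`` becomes
    ``A``, anything outside ACGTN is rejected naming the record and offset.
    """
    if record_policy not in ("concatenate", "first_only"):
        raise ValueError(f"unknown record_policy {record_policy!r}")
    parts: list[np.ndarray] = []
    records: list[tuple] = []
    name = ""
    offset = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        codes = _encode_record(rec.id, str(rec.seq))
        if not parts:
            name = rec.id
        parts.append(codes)
        records.append((rec.id, offset, len(codes)))
        offset += len(codes)
        if record_policy == "first_only":
            break
    if not parts:
        raise ReferenceIOError(f"no FASTA records found in {path}")
    body = np.concatenate(parts) if len(parts) > 1 else parts[0]
    text = np.concatenate([body, np.array([SENTINEL], dtype=np.uint8)])
    return Sequence(text=text, name=name, records=tuple(records))


def sequence_to_fasta(seq: Sequence, path, width: int = 70) -> None:
    """Write the sequence body back out as FASTA (sentinel dropped)."""
    with open(path, "w") as fh:
        for name, start, length in seq.records:
            fh.write(f">{name}\n")
            s = _DECODE[seq.text[start : start + length]].tobytes().decode()
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Index container.
#
# Little-endian layout, version 1:
#   magic   8s   b"KORDFMI1"
#   version u16  1
#   k       u64  0 means unbounded
#   vd      u32
#   sd      u32  0 means absent (metadata only)
#   stride  u32  occ checkpoint stride
#   n       u64
#   name    u32 length + bytes (utf-8)
#   alpha   u32 length + bytes
#   records u32 count, then per record: name (u32+bytes), start u64, len u64
#   transform      u8[n]            (one byte per symbol)
#   bucket_starts  u64[|alpha|+1]
#   checkpoints    u64[nckpt*|alpha|]
#   sample_mark    packed bits, u8[ceil(n/8)]
#   sample_values  u64[nmarks]
#   end     4s   b"KEND"
# ---------------------------------------------------------------------------

_MAGIC = b"KORDFMI1"
_END = b"KEND"
_VERSION = 1


def _w_bytes(fh, b: bytes) -> None:
    fh.write(struct.pack("<I", len(b)))
    fh.write(b)


def _r_exact(fh, size: int) -> bytes:
    b = fh.read(size)
    if len(b) != size:
        raise IndexFormatError("index file truncated")
    return b


def _r_bytes(fh) -> bytes:
    (ln,) = struct.unpack("<I", _r_exact(fh, 4))
    return _r_exact(fh, ln)


def save_index(index, path) -> None:
    """Serialize a k-ordered FM-index to ``path`` (documented binary v1)."""
    k_code = 0 if index.k is None else int(index.k)
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<H", _VERSION))
        fh.write(
            struct.pack(
                "<QIIIQ",
                k_code,
                int(index.vd),
                0 if index.sd is None else int(index.sd),
                int(index.checkpoint_stride),
                int(index.n),
            )
        )
        _w_bytes(fh, index.name.encode("utf-8"))
        _w_bytes(fh, index.alphabet.encode("ascii"))
        fh.write(struct.pack("<I", len(index.records)))
        for rname, start, length in index.records:
            _w_bytes(fh, rname.encode("utf-8"))
            fh.write(struct.pack("<QQ", int(start), int(length)))
        fh.write(np.ascontiguousarray(index.transform, dtype=np.uint8).tobytes())
        fh.write(
            np.ascontiguousarray(index.bucket_starts, dtype="<u8").tobytes()
        )
        fh.write(
            np.ascontiguousarray(index.occ_checkpoints, dtype="<u8").tobytes()
        )
        fh.write(np.packbits(index.sample_mark.astype(np.uint8)).tobytes())
        fh.write(
            np.ascontiguousarray(index.sample_values, dtype="<u8").tobytes()
        )
        fh.write(_END)


def load_index(path):
    """Load an index written by :func:`save_index`; validates magic/version."""
    from .fm_index import KOrderedFMIndex

    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise IndexFormatError(f"bad magic {magic!r}; not an index file")
        (version,) = struct.unpack("<H", _r_exact(fh, 2))
        if version != _VERSION:
            raise IndexFormatError(f"unsupported index version {version}")
        k_code, vd, sd, stride, n = struct.unpack("<QIIIQ", _r_exact(fh, 28))
        name = _r_bytes(fh).decode("utf-8")
        alphabet = _r_bytes(fh).decode("ascii")
        (nrec,) = struct.unpack("<I", _r_exact(fh, 4))
        records = []
        for _ in range(nrec):
            rname = _r_bytes(fh).decode("utf-8")
            start, length = struct.unpack("<QQ", _r_exact(fh, 16))
            records.append((rname, start, length))
        sigma = len(alphabet)
        transform = np.frombuffer(_r_exact(fh, n), dtype=np.uint8).copy()
        bucket_starts = np.frombuffer(
            _r_exact(fh, 8 * (sigma + 1)), dtype="<u8"
        ).astype(np.int64)
        nckpt = n // stride + 1
        occ_checkpoints = (
            np.frombuffer(_r_exact(fh, 8 * nckpt * sigma), dtype="<u8")
            .astype(np.int64)
            .reshape(nckpt, sigma)
        )
        nbytes = (n + 7) // 8
        sample_mark = np.unpackbits(
            np.frombuffer(_r_exact(fh, nbytes), dtype=np.uint8), count=n
        ).astype(bool)
        nmarks = int(sample_mark.sum())
        sample_values = np.frombuffer(
            _r_exact(fh, 8 * nmarks), dtype="<u8"
        ).astype(np.int64)
        if fh.read(4) != _END:
            raise IndexFormatError("index file truncated (missing end marker)")
    return KOrderedFMIndex(
        transform=transform,
        bucket_starts=bucket_starts,
        occ_checkpoints=occ_checkpoints,
        sample_mark=sample_mark,
        sample_values=sample_values,
        k=None if k_code == 0 else int(k_code),
        vd=int(vd),
        sd=None if sd == 0 else int(sd),
        checkpoint_stride=int(stride),
        n=int(n),
        alphabet=alphabet,
        name=name,
        records=tuple(records),
    )
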