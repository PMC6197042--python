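"""Stream container: low-level field codecs and the archive file format.

Provides 2-bit nucleotide packing (A=00, C=01, G=10, T=11, big-endian within a
byte), delta coding of sorted integer lists, unsigned varints, bit-level
readers/writers, and the framed archive holding every named stream compressed
independently by a general-purpose backend (LZMA by default).

The on-disk layout is documented in docs/FORMAT.md.
"""

from __future__ import annotations

import bz2
import lzma
import struct
import zlib
from dataclasses import dataclass, field

import numpy as np

from .sequence import NUCLEOTIDES, check_acgt

MAGIC = b"PPK1"
FORMAT_VERSION = 1

#: archive stream order; every archive contains all of these, possibly empty
STREAM_NAMES = (
    "f_index",
    "f_cov",
    "f_indexPos",
    "f_rc",
    "f_len",
    "f_N",
    "f_order",
    "f_firSeq",
    "f_bifurL",
    "f_bifurR",
    "f_numFlag",
    "f_newPos",
    "fallback_reads",
)

LAYOUT_SINGLE = 0
LAYOUT_PAIRED = 1
LAYOUT_INTERLEAVED = 2
LAYOUT_NAMES = {LAYOUT_SINGLE: "single", LAYOUT_PAIRED: "paired",
                LAYOUT_INTERLEAVED: "interleaved"}


class ArchiveError(Exception):
    """Base class for container-level failures."""


class BadMagicError(ArchiveError):
    pass


class TruncatedArchiveError(ArchiveError):
    pass


class CorruptStreamError(ArchiveError):
    pass


class FormatLimitError(ArchiveError):
    """A value exceeds a fixed field width (e.g. read length > 255)."""


# ---------------------------------------------------------------------------
# backends

_BACKENDS = {
    "lzma": (lambda b: lzma.compress(b, preset=6), lzma.decompress),
    "bz2": (lambda b: bz2.compress(b, 9), bz2.decompress),
    "zlib": (lambda b: zlib.compress(b, 9), zlib.decompress),
    "raw": (lambda b: b, lambda b: b),
}
BACKEND_IDS = {name: i for i, name in enumerate(("lzma", "bz2", "zlib", "raw"))}
_BACKEND_BY_ID = {i: name for name, i in BACKEND_IDS.items()}


def backend_compress(name: str, data: bytes) -> bytes:
    try:
        return _BACKENDS[name][0](data)
    except KeyError:
        raise ArchiveError(f"unknown backend {name!r}") from None


def backend_decompress(name: str, data: bytes) -> bytes:
    try:
        return _BACKENDS[name][1](data)
    except KeyError:
        raise ArchiveError(f"unknown backend {name!r}") from None
    except Exception as exc:  # backend-specific corruption errors
        raise CorruptStreamError(f"backend {name} failed: {exc}") from exc


# ---------------------------------------------------------------------------
# 2-bit packing

_PACK_TABLE = bytes.maketrans(b"ACGT", bytes([0, 1, 2, 3]))
_UNPACK_TABLE = bytes.maketrans(bytes([0, 1, 2, 3]), b"ACGT")
_WEIGHTS = np.array([64, 16, 4, 1], dtype=np.uint8)


def pack_2bit(s: str) -> bytes:
    """Pack an ACGT string at 2 bits/base, big-endian within each byte, the
    final byte zero-padded."""
    check_acgt(s)
    if not s:
        return b""
    codes = np.frombuffer(s.encode("ascii").translate(_PACK_TABLE), dtype=np.uint8)
    pad = (-len(codes)) % 4
    if pad:
        codes = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)])
    return (codes.reshape(-1, 4) * _WEIGHTS).sum(axis=1, dtype=np.uint8).tobytes()


def unpack_2bit(data: bytes, n: int) -> str:
    """Inverse of :func:`pack_2bit` for a string of known length ``n``."""
    if n == 0:
        return ""
    if len(data) * 4 < n:
        raise CorruptStreamError("2-bit payload shorter than declared length")
    arr = np.frombuffer(data, dtype=np.uint8)
    codes = np.empty((len(arr), 4), dtype=np.uint8)
    codes[:, 0] = arr >> 6
    codes[:, 1] = (arr >> 4) & 3
    codes[:, 2] = (arr >> 2) & 3
    codes[:, 3] = arr & 3
    return codes.reshape(-1)[:n].tobytes().translate(_UNPACK_TABLE).decode("ascii")


# ---------------------------------------------------------------------------
# delta coding and varints

def delta_encode(xs: list[int]) -> list[int]:
    """First element kept, then successive differences; input must be
    non-decreasing."""
    out = []
    prev = 0
    for i, x in enumerate(xs):
        if i and x < prev:
            raise ValueError(f"delta_encode input decreases at index {i}")
        out.append(x if i == 0 else x - prev)
        prev = x
    return out


def delta_decode(ds: list[int]) -> list[int]:
    out = []
    acc = 0
    for i, d in enumerate(ds):
        acc = d if i == 0 else acc + d
        out.append(acc)
    return out


def write_uvarint(buf: bytearray, value: int) -> None:
    if value < 0:
        raise ValueError("uvarint is unsigned")
    while True:
        b = value & 0x7F
        value >>= 7
        if value:
            buf.append(b | 0x80)
        else:
            buf.append(b)
            return


def read_uvarint(data: bytes, pos: int) -> tuple[int, int]:
    result = 0
    shift = 0
    while True:
        if pos >= len(data):
            raise TruncatedArchiveError("varint runs past end of buffer")
        b = data[pos]
        pos += 1
        result |= (b & 0x7F) << shift
        if not b & 0x80:
            return result, pos
        shift += 7


# ---------------------------------------------------------------------------
# bit-level I/O

class BitWriter:
    """Append-only MSB-first bit buffer."""

    __slots__ = ("_bytes", "_acc", "_nacc", "bit_length")

    def __init__(self) -> None:
        self._bytes = bytearray()
        self._acc = 0
        self._nacc = 0
        self.bit_length = 0

    def write_bit(self, bit: int) -> None:
        self._acc = (self._acc << 1) | (bit & 1)
        self._nacc += 1
        self.bit_length += 1
        if self._nacc == 8:
            self._bytes.append(self._acc)
            self._acc = 0
            self._nacc = 0

    def write_bits(self, value: int, n: int) -> None:
        for shift in range(n - 1, -1, -1):
            self.write_bit((value >> shift) & 1)

    def write_2bit_seq(self, s: str) -> None:
        codes = s.encode("ascii").translate(_PACK_TABLE)
        for c in codes:
            if c > 3:
                raise ValueError("non-ACGT character in 2-bit sequence")
            self.write_bits(c, 2)

    def getvalue(self) -> bytes:
        """Serialize as uvarint(bit length) + zero-padded payload."""
        out = bytearray()
        write_uvarint(out, self.bit_length)
        out += self._bytes
        if self._nacc:
            out.append(self._acc << (8 - self._nacc))
        return bytes(out)


class BitReader:
    """MSB-first reader over a :class:`BitWriter` serialization."""

    __slots__ = ("_data", "_pos", "bit_length", "_bit")

    def __init__(self, payload: bytes) -> None:
        self.bit_length, self._pos = read_uvarint(payload, 0)
        self._data = payload
        self._bit = 0
        if len(payload) - self._pos < (self.bit_length + 7) // 8:
            raise CorruptStreamError("bitstream shorter than declared bit length")

    def read_bit(self) -> int:
        if self._bit >= self.bit_length:
            raise CorruptStreamError("bitstream exhausted")
        byte = self._data[self._pos + (self._bit >> 3)]
        bit = (byte >> (7 - (self._bit & 7))) & 1
        self._bit += 1
        return bit

    def read_bits(self, n: int) -> int:
        v = 0
        for _ in range(n):
            v = (v << 1) | self.read_bit()
        return v

    def read_2bit_seq(self, n: int) -> str:
        return "".join(NUCLEOTIDES[self.read_bits(2)] for _ in range(n))

    @property
    def bits_remaining(self) -> int:
        return self.bit_length - self._bit


# ---------------------------------------------------------------------------
# archive header and framing

@dataclass(slots=True)
class ArchiveHeader:
    k: int
    threshold_num: int
    threshold_den: int
    n_reads: int
    n_fallback: int
    n_buckets: int
    layout: int = LAYOUT_SINGLE
    order_preserved: bool = True
    backend: str = "lzma"
    version: int = FORMAT_VERSION

    def to_bytes(self) -> bytes:
        buf = bytearray(MAGIC)
        buf.append(self.version)
        buf.append(BACKEND_IDS[self.backend])
        buf.append(self.k)
        buf.append(self.layout)
        buf.append(1 if self.order_preserved else 0)
        for v in (self.threshold_num, self.threshold_den, self.n_reads,
                  self.n_fallback, self.n_buckets):
            write_uvarint(buf, v)
        return bytes(buf)

    @classmethod
    def from_bytes(cls, data: bytes, pos: int = 0) -> tuple["ArchiveHeader", int]:
        if data[pos : pos + 4] != MAGIC:
            raise BadMagicError("not a pathpack archive (bad magic)")
        pos += 4
        if pos + 5 > len(data):
            raise TruncatedArchiveError("truncated header")
        version = data[pos]
        if version != FORMAT_VERSION:
            raise BadMagicError(f"unsupported format version {version}")
        backend_id = data[pos + 1]
        if backend_id not in _BACKEND_BY_ID:
            raise BadMagicError(f"unknown backend id {backend_id}")
        k = data[pos + 2]
        layout = data[pos + 3]
        order_preserved = bool(data[pos + 4])
        pos += 5
        num, pos = read_uvarint(data, pos)
        den, pos = read_uvarint(data, pos)
        n_reads, pos = read_uvarint(data, pos)
        n_fallback, pos = read_uvarint(data, pos)
        n_buckets, pos = read_uvarint(data, pos)
        return cls(k=k, threshold_num=num, threshold_den=den, n_reads=n_reads,
                   n_fallback=n_fallback, n_buckets=n_buckets, layout=layout,
                   order_preserved=order_preserved,
                   backend=_BACKEND_BY_ID[backend_id], version=version), pos


@dataclass(slots=True)
class StreamSet:
    """The named byte buffers of one archive.  Missing names are empty."""

    streams: dict[str, bytes] = field(default_factory=dict)

    def __getitem__(self, name: str) -> bytes:
        return self.streams.get(name, b"")

    def __setitem__(self, name: str, data: bytes) -> None:
        if name not in STREAM_NAMES:
            raise KeyError(f"unknown stream {name!r}")
        self.streams[name] = bytes(data)

    def update(self, other: dict[str, bytes]) -> None:
        for name, data in other.items():
            self[name] = data


def write_archive(header: ArchiveHeader, streams: StreamSet) -> bytes:
    """Frame header + per-stream (compressed length, raw length, payload)."""
    out = bytearray(header.to_bytes())
    for name in STREAM_NAMES:
        raw = streams[name]
        comp = backend_compress(header.backend, raw)
        write_uvarint(out, len(comp))
        write_uvarint(out, len(raw))
        out += comp
    return bytes(out)


def read_archive(data: bytes) -> tuple[ArchiveHeader, StreamSet]:
    header, pos = ArchiveHeader.from_bytes(data)
    streams = StreamSet()
    for name in STREAM_NAMES:
        clen, pos = read_uvarint(data, pos)
        rlen, pos = read_uvarint(data, pos)
        if pos + clen > len(data):
            raise TruncatedArchiveError(f"stream {name} truncated")
        raw = backend_decompress(header.backend, data[pos : pos + clen])
        if len(raw) != rlen:
            raise CorruptStreamError(
                f"stream {name}: declared {rlen} bytes, got {len(raw)}"
            )
        streams[name] = raw
        pos += clen
    if pos != len(data):
        raise CorruptStreamError(f"{len(data) - pos} trailing bytes after streams")
    return header, streams


def encode_u32_list(xs: list[int]) -> bytes:
    return struct.pack(f"<{len(xs)}I", *xs)


def decode_u32_list(data: bytes) -> list[int]:
    if len(data) % 4:
        raise CorruptStreamError("u32 stream length not a multiple of 4")
    return list(struct.unpack(f"<{len(data) // 4}I", data))
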