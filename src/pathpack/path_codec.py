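"""Read encoding as bifurcation paths over the dynamic de Bruijn graph.

Each read of a bucket (after the first, which is stored verbatim 2-bit packed
in f_firSeq) is represented by its anchor position plus a left and a right
bifurcation path.  The right path walks the graph from the anchor k-mer to the
read end; the left path walks the reverse complement symmetrically.  At each
node the classification against the read's next nucleotide decides what, if
anything, is emitted:

* Simple - nothing (a 0 flag bit marks "not New" at one-successor nodes);
* New    - flag bit 1, the position (one byte, read coordinates) and the
  nucleotide coded uniformly over the three nucleotides differing from the
  graph's sole successor (~log2 3 bits); the walk then follows the *graph*
  successor, so a lone substitution costs a single record;
* Tip    - the nucleotide at ~2 bits (uniform over ACGT);
* Branch - the nucleotide coded with frequencies from the surviving successor
  counts.

After a read is coded, the k-mers of the stored sequence and of its reverse
complement are inserted into the graph, on the encoder and the decoder alike;
the graph is reset at each bucket boundary and never serialized.

The arithmetic coder is a 32-bit carry-free (pending-bit) coder; any coder
meeting the round-trip and near-entropy contracts would do, bit compatibility
with other tools is a non-goal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from .dbg import DeBruijnGraph, NodeType, as_ratio
from .sequence import NT_TO_INDEX, NUCLEOTIDES, rc_unchecked
from .streams import (
    BitReader,
    BitWriter,
    CorruptStreamError,
    StreamSet,
)

__all__ = [
    "ArithmeticEncoder",
    "ArithmeticDecoder",
    "BifurcationRecord",
    "PathCode",
    "EncoderContext",
    "DecoderContext",
    "encode_read",
    "decode_read",
    "encode_buckets",
    "decode_buckets",
]

_MASK32 = 0xFFFFFFFF
_HALF = 0x80000000
_QTR = 0x40000000
_3QTR = 0xC0000000

_UNIFORM4 = (1, 1, 1, 1)
_UNIFORM3 = (1, 1, 1)


class ArithmeticEncoder:
    """32-bit arithmetic encoder over caller-supplied integer frequencies.

    ``encode(symbol_index, freqs)`` narrows the interval; bits (plus carries)
    are emitted MSB-first.  Total frequency must stay below 2**30; callers
    rescale larger models.
    """

    __slots__ = ("_low", "_high", "_pending", "_bits")

    def __init__(self) -> None:
        self._low = 0
        self._high = _MASK32
        self._pending = 0
        self._bits = bytearray()

    def _emit(self, bit: int) -> None:
        bits = self._bits
        bits.append(bit)
        if self._pending:
            inv = bit ^ 1
            bits.extend(inv for _ in range(self._pending))
            self._pending = 0

    def encode(self, sym: int, freqs) -> None:
        total = 0
        cum = 0
        for i, f in enumerate(freqs):
            if f <= 0:
                raise ValueError("frequencies must be positive")
            if i < sym:
                cum += f
            total += f
        span = self._high - self._low + 1
        self._high = self._low + span * (cum + freqs[sym]) // total - 1
        self._low = self._low + span * cum // total
        while True:
            if self._high < _HALF:
                self._emit(0)
            elif self._low >= _HALF:
                self._emit(1)
                self._low -= _HALF
                self._high -= _HALF
            elif self._low >= _QTR and self._high < _3QTR:
                self._pending += 1
                self._low -= _QTR
                self._high -= _QTR
            else:
                break
            self._low = (self._low << 1) & _MASK32
            self._high = ((self._high << 1) | 1) & _MASK32

    @property
    def bit_length(self) -> int:
        # two termination bits are still outstanding at most
        return len(self._bits)

    def finish(self) -> bytes:
        """Flush and serialize (uvarint bit length + zero-padded payload)."""
        self._pending += 1
        self._emit(1 if self._low >= _QTR else 0)
        writer = BitWriter()
        for b in self._bits:
            writer.write_bit(b)
        return writer.getvalue()


class ArithmeticDecoder:
    """Mirror of :class:`ArithmeticEncoder`; reads zero bits past the end of
    the stream, as the encoder's termination requires."""

    __slots__ = ("_low", "_high", "_code", "_reader")

    def __init__(self, payload: bytes) -> None:
        self._reader = BitReader(payload)
        self._low = 0
        self._high = _MASK32
        code = 0
        for _ in range(32):
            code = (code << 1) | self._next_bit()
        self._code = code

    def _next_bit(self) -> int:
        reader = self._reader
        if reader.bits_remaining > 0:
            return reader.read_bit()
        return 0

    def decode(self, freqs) -> int:
        total = 0
        for f in freqs:
            if f <= 0:
                raise ValueError("frequencies must be positive")
            total += f
        span = self._high - self._low + 1
        target = ((self._code - self._low + 1) * total - 1) // span
        cum = 0
        for sym, f in enumerate(freqs):
            if cum + f > target:
                break
            cum += f
        else:
            raise CorruptStreamError("arithmetic decoder target out of range")
        self._high = self._low + span * (cum + f) // total - 1
        self._low = self._low + span * cum // total
        while True:
            if self._high < _HALF:
                pass
            elif self._low >= _HALF:
                self._low -= _HALF
                self._high -= _HALF
                self._code -= _HALF
            elif self._low >= _QTR and self._high < _3QTR:
                self._low -= _QTR
                self._high -= _QTR
                self._code -= _QTR
            else:
                break
            self._low = (self._low << 1) & _MASK32
            self._high = ((self._high << 1) | 1) & _MASK32
            self._code = ((self._code << 1) | self._next_bit()) & _MASK32
        return sym


class BifurcationRecord(NamedTuple):
    kind: NodeType           # TIP, NEW or BRANCH (Simple emits no record)
    nt: str                  # nucleotide in walk-strand orientation
    pos: int | None          # read coordinate, present only for NEW


@dataclass(slots=True)
class PathCode:
    left: list[BifurcationRecord] = field(default_factory=list)
    right: list[BifurcationRecord] = field(default_factory=list)

    @property
    def records(self) -> list[BifurcationRecord]:
        return self.left + self.right


@dataclass(slots=True)
class EncoderContext:
    """Shared per-archive codec state (one arithmetic stream per direction,
    one flag bitstream, one New-position byte stream, one f_firSeq bitstream)."""

    threshold_num: int
    threshold_den: int
    enc_left: ArithmeticEncoder = field(default_factory=ArithmeticEncoder)
    enc_right: ArithmeticEncoder = field(default_factory=ArithmeticEncoder)
    flags: BitWriter = field(default_factory=BitWriter)
    newpos: bytearray = field(default_factory=bytearray)
    firseq: BitWriter = field(default_factory=BitWriter)

    def finalize(self) -> dict[str, bytes]:
        return {
            "f_bifurL": self.enc_left.finish(),
            "f_bifurR": self.enc_right.finish(),
            "f_numFlag": self.flags.getvalue(),
            "f_newPos": bytes(self.newpos),
            "f_firSeq": self.firseq.getvalue(),
        }


@dataclass(slots=True)
class DecoderContext:
    threshold_num: int
    threshold_den: int
    dec_left: ArithmeticDecoder
    dec_right: ArithmeticDecoder
    flags: BitReader
    newpos: bytes
    newpos_pos: int
    firseq: BitReader

    @classmethod
    def from_streams(cls, streams: StreamSet, threshold_num: int,
                     threshold_den: int) -> "DecoderContext":
        return cls(
            threshold_num=threshold_num,
            threshold_den=threshold_den,
            dec_left=ArithmeticDecoder(streams["f_bifurL"]),
            dec_right=ArithmeticDecoder(streams["f_bifurR"]),
            flags=BitReader(streams["f_numFlag"]),
            newpos=streams["f_newPos"],
            newpos_pos=0,
            firseq=BitReader(streams["f_firSeq"]),
        )

    def next_newpos(self) -> int:
        if self.newpos_pos >= len(self.newpos):
            raise CorruptStreamError("f_newPos exhausted mid-read")
        v = self.newpos[self.newpos_pos]
        self.newpos_pos += 1
        return v


def _branch_freqs(counts, num, den, total):
    """Coding frequencies at a node with >= 2 surviving successors: surviving
    counts (rescaled to keep the total small) weighted 4x, plus one for every
    nucleotide so any read nucleotide - even a filtered or novel one - stays
    codable.  Deterministic from the counts, hence identical on both sides."""
    shift = 0
    while (total >> shift) >= 1 << 13:
        shift += 1
    return [
        (max(1, c >> shift) << 2) + 1 if c and c * den >= num * total else 1
        for c in counts
    ]


def _walk_encode(graph: DeBruijnGraph, walk_seq: str, start: int,
                 coder: ArithmeticEncoder, ctx: EncoderContext,
                 pos_base: int, pos_step: int) -> list[BifurcationRecord]:
    """Encode one direction.  ``walk_seq`` is the strand actually walked
    (stored sequence for the right path, its reverse complement for the left);
    the original-read coordinate of step i is pos_base + pos_step*(i+k)."""
    k = graph.k
    nodes = graph.nodes
    n = len(walk_seq)
    num = ctx.threshold_num
    den = ctx.threshold_den
    flags = ctx.flags
    records: list[BifurcationRecord] = []
    node = walk_seq[start : start + k]
    for i in range(start, n - k):
        nt = walk_seq[i + k]
        counts = nodes.get(node)
        total = counts[0] + counts[1] + counts[2] + counts[3] if counts else 0
        if total == 0:
            # Tip: 2 bits, uniform over ACGT
            coder.encode(NT_TO_INDEX[nt], _UNIFORM4)
            records.append(BifurcationRecord(NodeType.TIP, nt, None))
            node = node[1:] + nt
            continue
        surv = [j for j in range(4) if counts[j] and counts[j] * den >= num * total]
        if len(surv) == 1:
            s_idx = surv[0]
            s_nt = NUCLEOTIDES[s_idx]
            if s_nt == nt:
                flags.write_bit(0)
            else:
                flags.write_bit(1)
                pos = pos_base + pos_step * (i + k)
                ctx.newpos.append(pos)
                others = [j for j in range(4) if j != s_idx]
                coder.encode(others.index(NT_TO_INDEX[nt]), _UNIFORM3)
                records.append(BifurcationRecord(NodeType.NEW, nt, pos))
            # the walk follows the graph successor, not the read nucleotide:
            # a lone substitution rejoins the graph path immediately
            node = node[1:] + s_nt
        else:
            freqs = _branch_freqs(counts, num, den, total)
            coder.encode(NT_TO_INDEX[nt], freqs)
            records.append(BifurcationRecord(NodeType.BRANCH, nt, None))
            node = node[1:] + nt
    return records


def _walk_decode(graph: DeBruijnGraph, node: str, n_steps: int,
                 coder: ArithmeticDecoder, ctx: DecoderContext,
                 pos_base: int, pos_step: int, start: int) -> list[str]:
    """Mirror of :func:`_walk_encode`; returns the decoded walk-strand
    nucleotides in step order."""
    k = graph.k
    nodes = graph.nodes
    num = ctx.threshold_num
    den = ctx.threshold_den
    flags = ctx.flags
    out: list[str] = []
    for step in range(n_steps):
        counts = nodes.get(node)
        total = counts[0] + counts[1] + counts[2] + counts[3] if counts else 0
        if total == 0:
            nt = NUCLEOTIDES[coder.decode(_UNIFORM4)]
            node = node[1:] + nt
            out.append(nt)
            continue
        surv = [j for j in range(4) if counts[j] and counts[j] * den >= num * total]
        if len(surv) == 1:
            s_idx = surv[0]
            s_nt = NUCLEOTIDES[s_idx]
            if flags.read_bit():
                pos = ctx.next_newpos()
                expected = pos_base + pos_step * (start + step + k)
                if pos != expected:
                    raise CorruptStreamError(
                        f"New-node position {pos} != expected {expected}; "
                        "encoder/decoder graphs out of sync"
                    )
                others = [j for j in range(4) if j != s_idx]
                nt = NUCLEOTIDES[others[coder.decode(_UNIFORM3)]]
            else:
                nt = s_nt
            node = node[1:] + s_nt
            out.append(nt)
        else:
            freqs = _branch_freqs(counts, num, den, total)
            nt = NUCLEOTIDES[coder.decode(freqs)]
            node = node[1:] + nt
            out.append(nt)
    return out


def encode_read(graph: DeBruijnGraph, seq: str, anchor: int,
                ctx: EncoderContext) -> PathCode:
    """Encode one stored-orientation read against the current graph state.

    The caller inserts the read into the graph afterwards (both strands).
    ``seq[anchor:anchor+k]`` must equal the bucket label's occurrence used at
    bucketing time.
    """
    k = graph.k
    n = len(seq)
    if anchor < 0 or anchor + k > n:
        raise ValueError(f"anchor {anchor} does not fit a {k}-mer in a read of length {n}")
    right = _walk_encode(graph, seq, anchor, ctx.enc_right, ctx, 0, 1)
    rseq = rc_unchecked(seq)
    left = _walk_encode(graph, rseq, n - anchor - k, ctx.enc_left, ctx, n - 1, -1)
    return PathCode(left=left, right=right)


def decode_read(graph: DeBruijnGraph, label: str, anchor: int, length: int,
                ctx: DecoderContext) -> str:
    """Reconstruct one stored-orientation read; mirror of :func:`encode_read`."""
    k = graph.k
    n_right = length - anchor - k
    n_left = anchor
    if n_right < 0:
        raise CorruptStreamError(
            f"anchor {anchor} inconsistent with read length {length} and k={k}"
        )
    right_nts = _walk_decode(graph, label, n_right, ctx.dec_right, ctx, 0, 1, anchor)
    left_nts = _walk_decode(graph, rc_unchecked(label), n_left, ctx.dec_left,
                            ctx, length - 1, -1, length - anchor - k)
    # left walk nucleotides are rc-strand bases for read positions
    # anchor-1 .. 0; complement and reverse to get the prefix
    prefix = "".join(left_nts).translate(_COMP_TABLE)[::-1]
    return prefix + label + "".join(right_nts)


_COMP_TABLE = str.maketrans("ACGT", "TGCA")


def _insert_both_strands(graph: DeBruijnGraph, seq: str) -> None:
    graph.insert_read(seq)
    graph.insert_read(rc_unchecked(seq))


def encode_buckets(buckets, k: int, threshold, ctx: EncoderContext | None = None,
                   digest_cb=None) -> tuple[EncoderContext, list[list[PathCode]]]:
    """Encode every bucket (sorted members assumed): first member 2-bit packed
    into f_firSeq, the rest path-coded.  ``digest_cb(graph)``, when given, is
    called after every read insertion (synchronization instrumentation)."""
    num, den = as_ratio(threshold)
    if ctx is None:
        ctx = EncoderContext(threshold_num=num, threshold_den=den)
    all_paths: list[list[PathCode]] = []
    for bucket in buckets:
        graph = DeBruijnGraph(k)
        paths: list[PathCode] = []
        for j, member in enumerate(bucket.members):
            seq = member.stored_seq
            if j == 0:
                ctx.firseq.write_2bit_seq(seq)
            else:
                if seq[member.anchor : member.anchor + k] != bucket.label:
                    raise AssertionError(
                        "bucket label does not occur at the recorded anchor"
                    )
                paths.append(encode_read(graph, seq, member.anchor, ctx))
            _insert_both_strands(graph, seq)
            if digest_cb is not None:
                digest_cb(graph)
        all_paths.append(paths)
    return ctx, all_paths


def decode_buckets(labels, covs, anchors_per_bucket, lengths_per_bucket,
                   streams: StreamSet, k: int, threshold,
                   digest_cb=None) -> list[list[str]]:
    """Decode every bucket's stored-orientation sequences.

    ``anchors_per_bucket`` / ``lengths_per_bucket`` are per-bucket lists
    aligned with ``labels`` and ``covs``.
    """
    num, den = as_ratio(threshold)
    ctx = DecoderContext.from_streams(streams, num, den)
    out: list[list[str]] = []
    for label, cov, anchors, lengths in zip(labels, covs, anchors_per_bucket,
                                            lengths_per_bucket):
        if not (cov == len(anchors) == len(lengths)):
            raise CorruptStreamError("f_cov inconsistent with per-read metadata")
        graph = DeBruijnGraph(k)
        seqs: list[str] = []
        for j in range(cov):
            if j == 0:
                seq = ctx.firseq.read_2bit_seq(lengths[0])
            else:
                seq = decode_read(graph, label, anchors[j], lengths[j], ctx)
            seqs.append(seq)
            _insert_both_strands(graph, seq)
            if digest_cb is not None:
                digest_cb(graph)
        out.append(seqs)
    return out
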