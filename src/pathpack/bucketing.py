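"""Read bucketing by shared-k-mer score.

Every read (or its reverse complement) joins the candidate bucket with the
highest number of shared k-mers, where candidates are the buckets whose label
equals some k-mer of the read on either strand.  On a miss a new bucket is
created, labeled with the read's two-strand minimizer.  After all reads are
placed, singleton buckets are dissolved and their reads rescued into surviving
buckets; reads that still fit nowhere go to the fallback bucket (empty-string
label) and are stored 2-bit packed.

Ties in score prefer forward-strand candidates, then the lexicographically
smallest label.  The k-mer pool of a bucket grows with every assigned read, so
assignment depends on arrival order; arrival order is input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .sequence import Read, kmer_list, minimizer, rc_unchecked
from .streams import (
    BitReader,
    BitWriter,
    CorruptStreamError,
    FormatLimitError,
    StreamSet,
    decode_u32_list,
    delta_decode,
    delta_encode,
    encode_u32_list,
    read_uvarint,
    write_uvarint,
)

FALLBACK_LABEL = ""


@dataclass(slots=True)
class BucketMember:
    read: Read
    stored_seq: str  # read.seq or its reverse complement
    anchor: int      # leftmost occurrence of the bucket label in stored_seq
    rc_flag: int     # 1 if stored reverse-complemented


@dataclass(slots=True)
class Bucket:
    label: str
    members: list[BucketMember] = field(default_factory=list)
    kmer_pool: set[str] = field(default_factory=set)

    def add(self, read: Read, stored_seq: str, rc_flag: int, k: int) -> BucketMember:
        anchor = stored_seq.find(self.label) if self.label else 0
        if self.label and anchor < 0:
            raise AssertionError("bucket label missing from stored sequence")
        member = BucketMember(read, stored_seq, anchor, rc_flag)
        self.members.append(member)
        self.kmer_pool.update(kmer_list(stored_seq, k))
        return member

    def sort(self) -> None:
        """Order members by (anchor ascending, stored sequence); stable, so
        equal reads keep their arrival order."""
        self.members.sort(key=lambda m: (m.anchor, m.stored_seq))


class BucketTable:
    """Label -> bucket map plus the fallback bucket."""

    def __init__(self, k: int):
        self.k = k
        self.buckets: dict[str, Bucket] = {}
        self.creation_order: list[str] = []
        self.fallback = Bucket(FALLBACK_LABEL)

    def __len__(self) -> int:
        return len(self.buckets)

    def total_members(self) -> int:
        return sum(len(b.members) for b in self.buckets.values()) + len(
            self.fallback.members
        )


def score(read_kmers: set[str], bucket: Bucket) -> int:
    """Number of distinct k-mers shared between the read and the bucket pool."""
    return len(read_kmers & bucket.kmer_pool)


@dataclass(slots=True)
class AssignResult:
    kind: str            # "joined" | "new" | "fallback"
    label: str
    anchor: int
    rc_flag: int


def assign_read(read: Read, table: BucketTable, k: int | None = None,
                allow_new: bool = True) -> AssignResult:
    """Dispatch one read into ``table``.

    Candidate buckets are those labeled by a k-mer of the read on either
    strand; the winner maximizes the shared-k-mer score, computed with the
    read in the candidate's orientation.  When no candidate exists a new
    bucket labeled with the minimizer is created (or, with ``allow_new``
    False, the read goes to the fallback bucket).
    """
    if k is None:
        k = table.k
    seq = read.seq
    if len(seq) < k:
        table.fallback.add(read, seq, 0, k)
        return AssignResult("fallback", FALLBACK_LABEL, 0, 0)

    fwd_kmers = set(kmer_list(seq, k))
    rseq = rc_unchecked(seq)
    rc_kmers = set(kmer_list(rseq, k))

    buckets = table.buckets
    candidates: dict[str, int] = {}
    for km in rc_kmers:
        if km in buckets:
            candidates[km] = 1
    for km in fwd_kmers:
        if km in buckets:
            candidates[km] = 0  # forward wins when a label sits on both strands

    if candidates:
        best = None
        for label, orient in candidates.items():
            sc = score(fwd_kmers if orient == 0 else rc_kmers, buckets[label])
            key = (-sc, orient, label)
            if best is None or key < best[0]:
                best = (key, label, orient)
        _, label, orient = best
        stored = seq if orient == 0 else rseq
        member = buckets[label].add(read, stored, orient, k)
        return AssignResult("joined", label, member.anchor, orient)

    if not allow_new:
        table.fallback.add(read, seq, 0, k)
        return AssignResult("fallback", FALLBACK_LABEL, 0, 0)

    label = minimizer(seq, k)
    orient = 0 if label in fwd_kmers else 1
    stored = seq if orient == 0 else rseq
    bucket = Bucket(label)
    buckets[label] = bucket
    table.creation_order.append(label)
    member = bucket.add(read, stored, orient, k)
    return AssignResult("new", label, member.anchor, orient)


def rescue_singletons(table: BucketTable) -> int:
    """Dissolve all one-read buckets and re-run their reads through
    :func:`assign_read` restricted to the surviving buckets; unplaceable reads
    go to the fallback bucket.  Returns the number of reads reassigned out of
    singleton buckets."""
    singleton_labels = [
        label
        for label in table.creation_order
        if label in table.buckets and len(table.buckets[label].members) == 1
    ]
    orphans = []
    for label in singleton_labels:
        bucket = table.buckets.pop(label)
        orphans.append(bucket.members[0].read)
    for read in orphans:
        assign_read(read, table, allow_new=False)
    return len(orphans)


def build_table(reads: list[Read], k: int) -> tuple[BucketTable, int]:
    """Full bucketing pass: assign, rescue, sort.  Returns the table and the
    number of singleton reads that went through rescue."""
    table = BucketTable(k)
    for read in reads:
        assign_read(read, table)
    n_rescued = rescue_singletons(table)
    for bucket in table.buckets.values():
        bucket.sort()
    table.fallback.sort()
    return table, n_rescued


# ---------------------------------------------------------------------------
# stream emission

def label_to_int(label: str) -> int:
    """2-bit big-endian integer value of a label k-mer."""
    v = 0
    for c in label:
        v = (v << 2) | "ACGT".index(c)
    return v


def int_to_label(v: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[v & 3])
        v >>= 2
    return "".join(reversed(out))


def sorted_labels(table: BucketTable) -> list[str]:
    return sorted(table.buckets)


def emission_members(table: BucketTable) -> tuple[list[BucketMember], list[Bucket]]:
    """Per-read emission order: fallback reads first, then buckets in
    ascending label order with members in sorted order."""
    buckets = [table.buckets[label] for label in sorted_labels(table)]
    members = list(table.fallback.members)
    for bucket in buckets:
        members.extend(bucket.members)
    return members, buckets


def emit_bucket_streams(table: BucketTable, preserve_order: bool = True) -> StreamSet:
    """Fill the bucket-description streams.

    f_index: ascending label integers, delta-coded as uvarints.
    f_cov: members per bucket, u32 little-endian.
    f_indexPos: anchors, one byte each, delta-coded within each bucket.
    f_rc: orientation bits (bucket members only).
    f_len: read lengths, one byte each (all reads, fallback first).
    f_N: per read, run count then (start, length) byte pairs.
    f_order: original order of every read, u32 little-endian.
    fallback_reads: fallback sequences 2-bit packed back to back.
    """
    members, buckets = emission_members(table)
    streams = StreamSet()

    index_buf = bytearray()
    for d in delta_encode([label_to_int(b.label) for b in buckets]):
        write_uvarint(index_buf, d)
    streams["f_index"] = bytes(index_buf)
    streams["f_cov"] = encode_u32_list([len(b.members) for b in buckets])

    pos_buf = bytearray()
    rc_bits = BitWriter()
    for bucket in buckets:
        prev = 0
        for i, m in enumerate(bucket.members):
            if m.anchor > 255:
                raise FormatLimitError(f"anchor {m.anchor} exceeds 8-bit field")
            pos_buf.append(m.anchor if i == 0 else m.anchor - prev)
            prev = m.anchor
            rc_bits.write_bit(m.rc_flag)
    streams["f_indexPos"] = bytes(pos_buf)
    streams["f_rc"] = rc_bits.getvalue()

    len_buf = bytearray()
    n_buf = bytearray()
    orders = []
    for m in members:
        length = len(m.stored_seq)
        if not 1 <= length <= 255:
            raise FormatLimitError(f"read length {length} exceeds 8-bit field")
        len_buf.append(length)
        runs = m.read.n_runs
        if len(runs) > 255:
            raise FormatLimitError("more than 255 N runs in one read")
        n_buf.append(len(runs))
        for start, run_len in runs:
            if start > 255 or run_len > 255:
                raise FormatLimitError("N-run field exceeds 8 bits")
            n_buf.append(start)
            n_buf.append(run_len)
        orders.append(m.read.order)
    streams["f_len"] = bytes(len_buf)
    streams["f_N"] = bytes(n_buf)
    if preserve_order:
        streams["f_order"] = encode_u32_list(orders)

    fb = BitWriter()
    for m in table.fallback.members:
        fb.write_2bit_seq(m.stored_seq)
    streams["fallback_reads"] = fb.getvalue()
    return streams


# ---------------------------------------------------------------------------
# stream parsing (decompression side)

@dataclass(slots=True)
class DecodedBucketMeta:
    """Bucket-description streams parsed back into per-bucket structure."""

    labels: list[str]
    covs: list[int]
    anchors: list[list[int]]          # per bucket, member order
    lengths: list[list[int]]          # per bucket, member order
    rc_flags: list[list[int]]         # per bucket, member order
    fallback_seqs: list[str]
    n_runs: list[list[tuple[int, int]]]  # all reads, emission order
    orders: list[int] | None             # all reads, emission order


def parse_bucket_streams(streams: StreamSet, header) -> DecodedBucketMeta:
    k = header.k
    n_reads = header.n_reads
    n_fallback = header.n_fallback
    n_buckets = header.n_buckets

    index_raw = streams["f_index"]
    deltas = []
    pos = 0
    while pos < len(index_raw):
        v, pos = read_uvarint(index_raw, pos)
        deltas.append(v)
    if len(deltas) != n_buckets:
        raise CorruptStreamError(
            f"f_index holds {len(deltas)} labels, header says {n_buckets}"
        )
    labels = [int_to_label(v, k) for v in delta_decode(deltas)]

    covs = decode_u32_list(streams["f_cov"])
    if len(covs) != n_buckets:
        raise CorruptStreamError("f_cov length does not match bucket count")
    n_members = sum(covs)
    if n_fallback + n_members != n_reads:
        raise CorruptStreamError("f_cov totals do not match header read count")

    len_raw = streams["f_len"]
    if len(len_raw) != n_reads:
        raise CorruptStreamError("f_len length does not match read count")
    fallback_lengths = list(len_raw[:n_fallback])
    member_lengths_flat = list(len_raw[n_fallback:])

    pos_raw = streams["f_indexPos"]
    if len(pos_raw) != n_members:
        raise CorruptStreamError("f_indexPos length does not match member count")
    rc_reader = BitReader(streams["f_rc"])
    if rc_reader.bit_length != n_members:
        raise CorruptStreamError("f_rc bit length does not match member count")

    anchors: list[list[int]] = []
    lengths: list[list[int]] = []
    rc_flags: list[list[int]] = []
    at = 0
    for cov in covs:
        deltas = pos_raw[at : at + cov]
        anchors.append(delta_decode(list(deltas)))
        lengths.append(member_lengths_flat[at : at + cov])
        rc_flags.append([rc_reader.read_bit() for _ in range(cov)])
        at += cov

    n_raw = streams["f_N"]
    n_runs: list[list[tuple[int, int]]] = []
    pos = 0
    for _ in range(n_reads):
        if pos >= len(n_raw):
            raise CorruptStreamError("f_N exhausted")
        count = n_raw[pos]
        pos += 1
        if pos + 2 * count > len(n_raw):
            raise CorruptStreamError("f_N exhausted mid-record")
        n_runs.append(
            [(n_raw[pos + 2 * i], n_raw[pos + 2 * i + 1]) for i in range(count)]
        )
        pos += 2 * count
    if pos != len(n_raw):
        raise CorruptStreamError("trailing bytes in f_N")

    orders = None
    if header.order_preserved:
        orders = decode_u32_list(streams["f_order"])
        if len(orders) != n_reads:
            raise CorruptStreamError("f_order length does not match read count")

    fb_reader = BitReader(streams["fallback_reads"])
    fallback_seqs = [fb_reader.read_2bit_seq(n) for n in fallback_lengths]

    return DecodedBucketMeta(
        labels=labels, covs=covs, anchors=anchors, lengths=lengths,
        rc_flags=rc_flags, fallback_seqs=fallback_seqs, n_runs=n_runs,
        orders=orders,
    )
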