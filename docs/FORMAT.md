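# Archive format (version 1)

A pathpack archive is a single binary file: a fixed header followed by every
named stream, each compressed independently by the backend named in the
header. Multi-byte integers are unsigned LEB128 varints unless stated
otherwise; bitstreams are MSB-first and serialized as
`uvarint(bit_length) + ceil(bit_length/8) bytes` (zero-padded tail).

## Header

| field | encoding |
|-------|----------|
| magic | 4 bytes `PPK1` |
| version | 1 byte (= 1) |
| backend | 1 byte: 0 lzma, 1 bz2, 2 zlib, 3 raw |
| k | 1 byte |
| layout | 1 byte: 0 single, 1 paired two-file, 2 interleaved |
| order_preserved | 1 byte boolean |
| threshold numerator, denominator | 2 varints (exact ratio) |
| n_reads, n_fallback, n_buckets | 3 varints |

## Streams

Streams appear in this fixed order, each framed as
`uvarint(compressed length) + uvarint(raw length) + compressed payload`.
Unknown magic/version/backend, truncation, raw-length mismatch and trailing
bytes raise distinct archive errors.

Per-read metadata is ordered: fallback reads first (sorted by sequence),
then buckets in ascending label order, members in (anchor, sequence) order.

| stream | content |
|--------|---------|
| `f_index` | bucket labels as 2-bit big-endian integers, ascending, delta-coded, one varint per delta |
| `f_cov` | members per bucket, u32 LE |
| `f_indexPos` | member anchors, 1 byte each, delta-coded within each bucket (first absolute) |
| `f_rc` | bitstream: one orientation bit per bucket member (1 = stored reverse-complemented) |
| `f_len` | one byte per read (all reads, emission order) |
| `f_N` | per read: run-count byte, then (start, length) byte pairs |
| `f_order` | original order per read, u32 LE; empty when order is dropped |
| `f_firSeq` | bitstream: each bucket's first member, 2 bits/base, back to back |
| `f_bifurL` / `f_bifurR` | arithmetic-coded left/right path payloads (Tip, New, Branch nucleotides), one continuous coder stream each |
| `f_numFlag` | bitstream: one bit per single-successor node, both directions interleaved in walk order (1 = New) |
| `f_newPos` | one byte per New record: absolute read offset |
| `fallback_reads` | bitstream: fallback sequences, 2 bits/base, back to back |

Bitstreams and coder streams are continuous across buckets and padded once,
at end of stream. An empty input produces a valid archive in which every
stream is empty.

2-bit code: A=00, C=01, G=10, T=11, big-endian within each byte.
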