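"""FASTQ reading and sequence-line writing.

Only the sequence lines matter to the codec: identifiers and quality strings
are discarded on input and replaced with placeholders on output.  Paired-end
data may arrive as two files (mates on the same line number) or interleaved in
one file; mates of pair p are assigned original orders 2p and 2p+1, so
restoring the original order alone restores pairing.
"""

from __future__ import annotations

import gzip
from pathlib import Path

from Bio import SeqIO

from .sequence import Read, substitute_n
from .streams import (
    LAYOUT_INTERLEAVED,
    LAYOUT_PAIRED,
    LAYOUT_SINGLE,
    FormatLimitError,
)

MAX_READ_LENGTH = 255  # 8-bit f_len field


class FastqError(ValueError):
    pass


class PairingError(FastqError):
    pass


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def iter_sequences(path) -> list[str]:
    """Uppercased sequence strings of a (optionally gzipped) FASTQ file."""
    seqs = []
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                seqs.append(str(rec.seq).upper())
        except ValueError as exc:
            raise FastqError(f"{path}: malformed FASTQ ({exc})") from exc
    return seqs


def _make_read(raw: str, order: int, mate: int | None, path, index: int) -> Read:
    if len(raw) > MAX_READ_LENGTH:
        raise FormatLimitError(
            f"{path}: read {index} has length {len(raw)} > {MAX_READ_LENGTH}"
        )
    if not raw:
        raise FastqError(f"{path}: read {index} has an empty sequence")
    seq, runs = substitute_n(raw)
    return Read(order=order, seq=seq, n_runs=runs, mate=mate)


def read_fastq(paths, layout: int = LAYOUT_SINGLE) -> list[Read]:
    """Parse one or two FASTQ files into :class:`Read` records with original
    order indices assigned."""
    if layout == LAYOUT_PAIRED:
        if len(paths) != 2:
            raise FastqError("paired layout needs exactly two input files")
        seqs1 = iter_sequences(paths[0])
        seqs2 = iter_sequences(paths[1])
        if len(seqs1) != len(seqs2):
            raise PairingError(
                f"mate files differ in read count: {len(seqs1)} vs {len(seqs2)}"
            )
        reads = []
        for p, (s1, s2) in enumerate(zip(seqs1, seqs2)):
            reads.append(_make_read(s1, 2 * p, 0, paths[0], p))
            reads.append(_make_read(s2, 2 * p + 1, 1, paths[1], p))
        return reads
    if len(paths) != 1:
        raise FastqError("single/interleaved layouts take exactly one input file")
    seqs = iter_sequences(paths[0])
    if layout == LAYOUT_INTERLEAVED:
        if len(seqs) % 2:
            raise PairingError("interleaved file holds an odd number of reads")
        return [
            _make_read(s, i, i % 2, paths[0], i) for i, s in enumerate(seqs)
        ]
    return [_make_read(s, i, None, paths[0], i) for i, s in enumerate(seqs)]


def _write_records(path, seqs, fasta: bool) -> None:
    with open(path, "wt") as fh:
        for i, seq in enumerate(seqs):
            if fasta:
                fh.write(f">{i}\n{seq}\n")
            else:
                fh.write(f"@{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_reads(reads_in_order: list[Read], layout: int, paths,
                fasta: bool = False) -> None:
    """Write restored sequences (N runs re-applied) as placeholder FASTQ or
    FASTA, splitting mates into two files for the paired layout."""
    raws = [r.raw for r in reads_in_order]
    if layout == LAYOUT_PAIRED:
        if len(paths) != 2:
            raise FastqError("paired layout needs exactly two output files")
        _write_records(paths[0], raws[0::2], fasta)
        _write_records(paths[1], raws[1::2], fasta)
    else:
        if len(paths) != 1:
            raise FastqError("this layout takes exactly one output file")
        _write_records(paths[0], raws, fasta)


def sequence_lines(path) -> list[str]:
    """The raw sequence lines of a FASTQ file, for byte-exact comparisons."""
    return iter_sequences(path)
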