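"""Nucleotide-string primitives.

Reverse complement, k-mer enumeration, canonical (two-strand) minimizers and
N-run extraction.  All coordinates are 0-based; intervals are half-open.  The
working alphabet after N substitution is {A, C, G, T}; lexicographic order is
the ASCII order A < C < G < T.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

NUCLEOTIDES = "ACGT"
NT_TO_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}
DEFAULT_K = 15

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_NON_ACGT = re.compile(r"[^ACGT]")
_NON_ACGTN = re.compile(r"[^ACGTN]")
_N_RUN = re.compile(r"N+")


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside the expected alphabet."""


class NoMinimizerError(ValueError):
    """Raised when a minimizer is requested for a read shorter than k."""


def check_acgt(s: str) -> None:
    m = _NON_ACGT.search(s)
    if m:
        raise AlphabetError(
            f"non-ACGT character {m.group()!r} at position {m.start()}"
        )


def check_acgtn(s: str) -> None:
    m = _NON_ACGTN.search(s)
    if m:
        raise AlphabetError(
            f"non-ACGTN character {m.group()!r} at position {m.start()}"
        )


def reverse_complement(s: str) -> str:
    """Return the reverse complement of an ACGT string (A<->T, C<->G, reversed)."""
    check_acgt(s)
    return s.translate(_COMPLEMENT)[::-1]


def rc_unchecked(s: str) -> str:
    # hot-path variant: caller guarantees the alphabet
    return s.translate(_COMPLEMENT)[::-1]


def kmer_list(s: str, k: int) -> list[str]:
    """All |s|-k+1 k-mers of ``s`` in left-to-right order; [] if the read is
    shorter than k (such reads end up in the fallback bucket)."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    n = len(s)
    if k > n:
        return []
    return [s[i : i + k] for i in range(n - k + 1)]


def minimizer(s: str, k: int) -> str:
    """Lexicographically smallest k-mer over ``s`` and its reverse complement.

    Forward-strand occurrences win ties (relevant only to the orientation a
    new bucket stores its seed read in, not to the returned k-mer).
    """
    if k > len(s):
        raise NoMinimizerError(f"read of length {len(s)} has no {k}-mer")
    fwd = min(kmer_list(s, k))
    rev = min(kmer_list(rc_unchecked(s), k))
    return fwd if fwd <= rev else rev


def substitute_n(raw: str) -> tuple[str, list[tuple[int, int]]]:
    """Replace every N by C, returning the cleaned sequence plus the (start,
    length) of each maximal N run so the substitution can be inverted exactly."""
    check_acgtn(raw)
    runs = [(m.start(), m.end() - m.start()) for m in _N_RUN.finditer(raw)]
    return (raw.replace("N", "C") if runs else raw), runs


def restore_n(seq: str, n_runs: list[tuple[int, int]]) -> str:
    """Inverse of :func:`substitute_n`."""
    if not n_runs:
        return seq
    out = list(seq)
    for start, length in n_runs:
        out[start : start + length] = "N" * length
    return "".join(out)


@dataclass(slots=True)
class Read:
    """One sequence record.

    ``order`` is the position in the original input (unique across the input);
    ``seq`` is the post-N-substitution sequence over ACGT; ``n_runs`` are the
    non-overlapping (start, length) N runs of the raw sequence in ascending
    start order; ``mate`` is 0/1 for paired-end data, None for single-end.
    """

    order: int
    seq: str
    n_runs: list[tuple[int, int]] = field(default_factory=list)
    mate: int | None = None

    @property
    def raw(self) -> str:
        """The original sequence with N runs restored."""
        return restore_n(self.seq, self.n_runs)
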