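"""The dynamic de Bruijn graph.

Nodes are k-mers; each node stores a count per successor nucleotide.  The
graph is built read-by-read, identically on the encoder and decoder sides, so
it is never serialized.  Successors whose abundance ratio falls below a
proportion threshold (default 1/5) are filtered before a node is classified,
which keeps sequencing errors from spawning spurious Branch nodes.

Node classification (given the read's next nucleotide):

* ``TIP``    - no surviving successor;
* ``SIMPLE`` - one surviving successor, equal to the read nucleotide;
* ``NEW``    - one surviving successor, different from the read nucleotide;
* ``BRANCH`` - two or more surviving successors.
"""

from __future__ import annotations

import hashlib
from enum import Enum
from fractions import Fraction

from .sequence import NT_TO_INDEX, NUCLEOTIDES

DEFAULT_THRESHOLD = Fraction(1, 5)


class NodeType(Enum):
    TIP = "Tip"
    SIMPLE = "Simple"
    NEW = "New"
    BRANCH = "Branch"


def as_ratio(threshold) -> tuple[int, int]:
    """Normalize a threshold given as float/str/Fraction/(num, den) to an
    exact integer ratio in [0, 1).

    Floats are interpreted through their decimal repr (0.2 -> 1/5), so the
    default threshold compares exactly: a successor survives iff
    count * den >= num * total.
    """
    if isinstance(threshold, tuple):
        num, den = threshold
    else:
        frac = Fraction(str(threshold)) if isinstance(threshold, float) else Fraction(threshold)
        num, den = frac.numerator, frac.denominator
    if den <= 0 or num < 0 or num >= den:
        raise ValueError(f"threshold must satisfy 0 <= t < 1, got {num}/{den}")
    return num, den


class DeBruijnGraph:
    """Map from k-mer to per-nucleotide successor counts (A, C, G, T)."""

    __slots__ = ("k", "nodes")

    def __init__(self, k: int):
        if k < 2:
            raise ValueError(f"k must be >= 2, got {k}")
        self.k = k
        self.nodes: dict[str, list[int]] = {}

    def __len__(self) -> int:
        return len(self.nodes)

    def insert_read(self, s: str) -> None:
        """Add every k-mer transition of ``s``; the terminal k-mer is
        registered with zero successors.  Reads shorter than k are a no-op."""
        k = self.k
        n = len(s)
        if n < k:
            return
        nodes = self.nodes
        idx = NT_TO_INDEX
        for i in range(n - k):
            node = s[i : i + k]
            counts = nodes.get(node)
            if counts is None:
                counts = nodes[node] = [0, 0, 0, 0]
            counts[idx[s[i + k]]] += 1
        last = s[n - k :]
        if last not in nodes:
            nodes[last] = [0, 0, 0, 0]

    def successor_counts(self, v: str) -> list[int] | None:
        return self.nodes.get(v)

    def filtered_successors(self, v: str, threshold=DEFAULT_THRESHOLD) -> list[tuple[str, int]]:
        """Successors of ``v`` whose count/total >= threshold, as
        (nucleotide, count) pairs; [] for absent or successor-free nodes."""
        counts = self.nodes.get(v)
        if counts is None:
            return []
        total = counts[0] + counts[1] + counts[2] + counts[3]
        if total == 0:
            return []
        num, den = as_ratio(threshold)
        return [
            (NUCLEOTIDES[j], counts[j])
            for j in range(4)
            if counts[j] and counts[j] * den >= num * total
        ]

    def classify(self, v: str, next_nt: str, threshold=DEFAULT_THRESHOLD) -> NodeType:
        """Classify the (node, read-next-nucleotide) query; total over all
        inputs by construction."""
        if next_nt not in NT_TO_INDEX:
            raise ValueError(f"next_nt must be one of ACGT, got {next_nt!r}")
        surv = self.filtered_successors(v, threshold)
        if not surv:
            return NodeType.TIP
        if len(surv) == 1:
            return NodeType.SIMPLE if surv[0][0] == next_nt else NodeType.NEW
        return NodeType.BRANCH

    def state_digest(self) -> str:
        """Order-independent digest of the full node/count map; used to assert
        encoder/decoder synchronization."""
        h = hashlib.blake2b(digest_size=16)
        for node in sorted(self.nodes):
            counts = self.nodes[node]
            h.update(node.encode("ascii"))
            h.update(bytes((counts[0] & 0xFF, counts[1] & 0xFF,
                            counts[2] & 0xFF, counts[3] & 0xFF)))
            h.update(repr(counts).encode("ascii"))
        return h.hexdigest()
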