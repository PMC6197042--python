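"""Synthetic read-set generator.

Emulates the statistical structure the codec exploits: reads sampled with
coverage redundancy from a single random reference, on both strands, with
independent per-base substitution errors and occasional N runs, optionally as
paired-end fragments (forward/reverse mates).  It deliberately omits indels,
quality-correlated error profiles and PCR duplicates; passing tests therefore
demonstrate the substitution-dominated regime of short-read data, not every
real-data pathology (see docs/methods.md).

Also provides the hand-built three-read bucket fixture whose encoding
exercises the canonical record pattern: first read stored verbatim, second
read a single New record, third read one New plus one Tip record.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .sequence import Read, rc_unchecked, substitute_n

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(slots=True)
class SimulationSpec:
    """Study conditions for one synthetic read set.

    ``genome_length`` (G) and ``coverage`` (C) set the redundancy the codec
    feeds on; ``sub_rate`` (e) is the per-base substitution probability
    (Illumina-like data sits around 0.1-1%); ``n_run_rate`` is the per-read
    probability of one masked N run of 1-3 bases.  Paired mode draws
    fragments of Normal(insert_mean, insert_sd) length and emits
    forward/reverse-complement mate pairs.
    """

    genome_length: int = 10_000
    read_length: int = 100
    coverage: float = 10.0
    sub_rate: float = 0.01
    n_run_rate: float = 0.01
    paired: bool = False
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if self.read_length > self.genome_length:
            raise ValueError("read length exceeds genome length")
        if not 1 <= self.read_length <= 255:
            raise ValueError("read length must be in [1, 255]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0 <= self.sub_rate < 1:
            raise ValueError("substitution rate must be in [0, 1)")

    @property
    def n_reads(self) -> int:
        n = max(1, round(self.genome_length * self.coverage / self.read_length))
        if self.paired:
            n += n % 2  # whole pairs
        return n


def random_genome(rng: np.random.Generator, length: int) -> str:
    return _ALPHABET[rng.integers(0, 4, length)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, sub_rate: float,
            n_run_rate: float) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    codes = np.searchsorted(_ALPHABET, arr)  # ACGT are sorted ASCII
    if sub_rate > 0:
        hits = np.nonzero(rng.random(len(codes)) < sub_rate)[0]
        if hits.size:
            codes[hits] = (codes[hits] + rng.integers(1, 4, hits.size)) % 4
    out = _ALPHABET[codes]
    if n_run_rate > 0 and rng.random() < n_run_rate:
        start = int(rng.integers(0, len(out)))
        length = int(rng.integers(1, 4))
        out[start : start + length] = ord("N")
    return out.tobytes().decode("ascii")


def generate_sequences(spec: SimulationSpec) -> tuple[str, list[str]]:
    """Reference genome plus raw read strings (over ACGTN) in input order."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ref = random_genome(rng, spec.genome_length)
    L = spec.read_length
    G = spec.genome_length
    reads: list[str] = []
    if spec.paired:
        n_pairs = spec.n_reads // 2
        for _ in range(n_pairs):
            insert = int(np.clip(round(rng.normal(spec.insert_mean, spec.insert_sd)),
                                 L, G))
            start = int(rng.integers(0, G - insert + 1))
            frag = ref[start : start + insert]
            m0, m1 = frag[:L], rc_unchecked(frag[-L:])
            if rng.random() < 0.5:  # fragment sampled from the other strand
                m0, m1 = rc_unchecked(frag[-L:]), frag[:L]
            reads.append(_mutate(rng, m0, spec.sub_rate, spec.n_run_rate))
            reads.append(_mutate(rng, m1, spec.sub_rate, spec.n_run_rate))
    else:
        for _ in range(spec.n_reads):
            start = int(rng.integers(0, G - L + 1))
            sub = ref[start : start + L]
            if rng.random() < 0.5:
                sub = rc_unchecked(sub)
            reads.append(_mutate(rng, sub, spec.sub_rate, spec.n_run_rate))
    return ref, reads


def generate_reads(spec: SimulationSpec) -> tuple[str, list[Read]]:
    """In-memory variant: reference plus :class:`Read` records with orders and
    N runs extracted (paired specs interleave mates: orders 2p, 2p+1)."""
    ref, raws = generate_sequences(spec)
    reads = []
    for i, raw in enumerate(raws):
        seq, runs = substitute_n(raw)
        mate = i % 2 if spec.paired else None
        reads.append(Read(order=i, seq=seq, n_runs=runs, mate=mate))
    return ref, reads


def generate(spec: SimulationSpec, out_prefix, two_files: bool = False):
    """Write FASTQ file(s) plus a JSON metadata sidecar.

    Returns (reference, list of FASTQ paths).  Paired specs write either one
    interleaved file or two mate files (``two_files=True``).
    """
    ref, raws = generate_sequences(spec)
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)

    def _write(path, seqs, name_offset, step):
        with open(path, "wt") as fh:
            for j, s in enumerate(seqs):
                fh.write(f"@sim{name_offset + step * j}\n{s}\n+\n{'I' * len(s)}\n")

    if spec.paired and two_files:
        paths = [Path(f"{out_prefix}_1.fastq"), Path(f"{out_prefix}_2.fastq")]
        _write(paths[0], raws[0::2], 0, 2)
        _write(paths[1], raws[1::2], 1, 2)
    else:
        paths = [Path(f"{out_prefix}.fastq")]
        _write(paths[0], raws, 0, 1)
    meta = asdict(spec)
    meta["n_reads"] = len(raws)
    meta["layout"] = ("paired" if two_files else
                      "interleaved" if spec.paired else "single")
    Path(f"{out_prefix}.json").write_text(json.dumps(meta, indent=2))
    return ref, paths


def random_spec(rng: np.random.Generator) -> SimulationSpec:
    """Draw one study condition from the randomized-validation ranges:
    genome length log-uniform in [1e3, 1e5], read length uniform in [35, 150],
    coverage log-uniform in [1, 30], substitution rate uniform in [0, 0.02],
    N runs present in half the conditions, single- or paired-end.  Log-uniform
    draws spread the sweep across scales while keeping the total simulated
    volume desk-sized."""
    return SimulationSpec(
        genome_length=int(np.exp(rng.uniform(np.log(1e3), np.log(1e5)))),
        read_length=int(rng.integers(35, 151)),
        coverage=float(np.exp(rng.uniform(0, np.log(30)))),
        sub_rate=float(rng.uniform(0, 0.02)),
        n_run_rate=float(rng.choice([0.0, 0.05])),
        paired=bool(rng.integers(0, 2)),
        seed=int(rng.integers(0, 2**31)),
    )


def fig3_fixture() -> dict:
    """Synthetic three-read bucket (k=3, label AGG) hand-built so that
    encoding produces the canonical structural pattern:

    * read 1 ("TTAGGCA", anchor 2): stored verbatim in f_firSeq, no records;
    * read 2 ("TTAGGCG", anchor 2): differs from read 1 by one substitution at
      its last base -> exactly one New record;
    * read 3 ("GTCAGGC", anchor 3): one substitution left of the anchor plus a
      one-base extension past the covered region -> one New and one Tip record.

    The member order is already (anchor, sequence)-sorted.  These reads are a
    constructed stand-in exercising the pattern, not data from any experiment.
    """
    return {
        "k": 3,
        "label": "AGG",
        "members": [("TTAGGCA", 2), ("TTAGGCG", 2), ("GTCAGGC", 3)],
        "expected_kinds": [[], ["New"], ["New", "Tip"]],
    }
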