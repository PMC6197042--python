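# Methods

## The model

`pathpack` is a de-novo (reference-free) codec for short-read sequence data.
Its premise is that shotgun sequencing oversamples the genome: at coverage C,
each locus appears in ~C reads, so most of a read's information is already
present in reads seen earlier. The codec makes that redundancy explicit in
two stages.

**Bucketing.** Reads are streamed once and dispatched into buckets. The
candidate buckets for read *r* are those whose label equals one of the
2(|r|−k+1) k-mers of *r* or rc(*r*); among candidates the winner maximizes
the number of distinct k-mers shared between the read (in the candidate's
orientation) and the union of k-mers of the bucket's stored reads. A read
found via its reverse complement is stored reverse-complemented, so every
bucket accumulates co-oriented, overlapping reads. On a miss the read seeds a
new bucket labeled with its two-strand minimizer: similar reads have a high
chance of sharing their minimizer, so later overlapping reads find the
bucket. After the pass, singleton buckets are dissolved and their reads
redispatched into the surviving buckets (scored the same way, no new buckets);
still-unplaceable reads and reads shorter than k go to the fallback bucket
and are stored at 2 bits/base. Bucket members are sorted by (anchor position,
sequence), which clusters near-identical reads adjacently.

**Path coding.** Per bucket, a de Bruijn graph over k-mers with
per-nucleotide successor counts is grown read by read. The first (sorted)
member is emitted verbatim at 2 bits/base and seeds the graph. Every later
read is encoded as its anchor plus two bifurcation paths: rightward from the
anchor k-mer over the read, and leftward as the identical procedure on the
reverse complement. At each node, successors whose abundance ratio is below
the threshold t (default 0.2, compared exactly as count·den ≥ num·total) are
filtered, and the node is classified against the read's next nucleotide:

| type   | surviving successors | emitted |
|--------|----------------------|---------|
| Simple | 1, equal to read nt  | flag bit 0 |
| New    | 1, different         | flag bit 1, position byte, nt coded uniformly over the 3 alternatives |
| Tip    | 0                    | nt at 2 bits (uniform over 4) |
| Branch | ≥ 2                  | nt arithmetic-coded from successor counts |

After a New node the walk follows the **graph** successor rather than the
read nucleotide. This is the detail that makes a lone substitution cost a
single record: the walk stays on the already-known context, and the rest of
the read decodes as Simple nodes. After Tip/Branch nodes the walk follows the
read nucleotide. Once a read is coded, the k-mers of its stored sequence
*and of its reverse complement* are inserted into the graph. Forward-only
insertion would leave the left path (which queries rc-space nodes) without
context, turning even an exact duplicate's left path into Tips; two-strand
insertion makes duplicate reads record-free in both directions. A corollary:
with an even k, a reverse-palindromic k-mer (rc(x) = x) can collect
successors from both strands and classify as Branch on a duplicate's path;
the default k = 15 is odd, which excludes palindromes.

The decoder performs the same walk: lengths and anchors come from metadata
streams, node classification from its own graph, and it inserts each decoded
read identically — so the graphs on the two sides are equal after every read
(asserted via order-independent digests in the tests) and the graph itself is
never serialized.

## Parameters

* **k = 15** (2..31): bucket label and graph node size. Larger k sharpens
  context at the cost of fewer shared k-mers between overlapping reads.
* **threshold t = 0.2**: successor filter. With t ≤ 0.25 at least one
  successor always survives; raising t above 0.25 can empty a node's
  successor set, which the classifier treats as Tip — still lossless, just
  costlier. Stored in the archive as an exact num/den pair.
* **backend = lzma** (bz2, zlib, raw): per-stream general-purpose
  compression applied to every named stream independently.
* **order preservation**: on by default; off (`--no-order`) restores the
  multiset of reads only, and is refused for paired layouts because pairing
  is recovered purely from the order stream (mates of pair p sit at orders
  2p, 2p+1).

## Numerical and coding choices

* The arithmetic coder is a 32-bit low/high coder with pending-bit carry
  handling; models are per-symbol positive integer frequency vectors. A
  power-of-two total (Tip's 1,1,1,1) costs exactly 2 bits/symbol; the
  uniform 3-way New model approaches log₂3 ≈ 1.585 bits/symbol.
* Branch models use the surviving counts (scaled down only when the total
  reaches 2¹³, deterministically on both sides) weighted ×4, plus 1 for
  every nucleotide. The +1 floor exists because the read's nucleotide at a
  branch can be a filtered or entirely novel successor — a zero frequency
  would be uncodable and break losslessness; the ×4 weighting keeps the
  survivors' ratios dominant so the floor costs little.
* New-node positions are stored as absolute 8-bit read offsets (consistent
  with the 8-bit anchor/length fields; reads are capped at 255 bases). The
  decoder re-derives the expected position from its own walk and treats a
  mismatch as archive corruption — a cheap synchrony check.
* One flag bit is emitted per single-successor node only. Tip and Branch
  nodes are recognizable from the successor counts alone on both sides, so
  flagging them would be redundant.
* All bitstreams (flags, both bifurcation payloads, first-read and fallback
  2-bit sequences) are continuous per archive and padded once at the end,
  not per bucket; the coder state crossing bucket boundaries is harmless
  because decoding is strictly sequential.
* Bucket labels are written as ascending 2-bit integers, delta-coded, as
  varints; anchors are delta-coded within each bucket (member sort makes
  them non-decreasing); coverages and orders are 32-bit little-endian.
* Degenerate inputs: an empty input yields a valid archive of empty streams;
  reads shorter than k can never anchor a label and go straight to the
  fallback bucket; reads longer than 255 bases are rejected up front.
* Ties: candidate scores break forward-strand-first, then smallest label;
  a label reachable on both strands counts as forward; the anchor is the
  leftmost label occurrence; rescue processes singletons in bucket-creation
  order. Compression is a deterministic function of (input bytes, config).

## What the generator emulates — and what it does not

The synthetic generator samples reads uniformly from a uniform-random
reference, on both strands, with independent per-base substitutions, optional
short N runs, and optional paired-end fragments (Normal insert length,
forward/reverse mates, either fragment strand). That reproduces the features
the method exploits (coverage redundancy, strandedness, substitution errors,
order scrambling across loci) and the features its metadata streams must
carry (Ns, pairing, unequal lengths are supported though the generator emits
fixed-length reads). It does **not** model indels (still lossless, but a
frame-shifted read decays into Tip records), quality-correlated or
position-dependent error profiles, PCR duplicates, repeat structure of real
genomes, or coverage bias. Passing tests therefore certify correctness and
the substitution-regime compression behavior, not the exact bits-per-base a
particular sequencing run would achieve.

Validation problem sizes were chosen to keep the whole suite desk-sized: the
randomized round-trip sweep draws 200 configurations with genome length
log-uniform in [10³, 10⁵], read length uniform in [35, 150], coverage
log-uniform in [1, 30] and substitution rate uniform in [0, 0.02]; the
redundancy benchmark uses a 10⁵-base genome at 20× error-free coverage
(2·10⁶ bases); graph-digest instrumentation runs on smaller instances because
digesting after every read is quadratic in bucket size; the scaling check
times coverages 4–32× over a 3·10⁴-base genome (1,200–9,600 reads).

## Known limitations

* Bucketing keeps all reads and all bucket k-mer pools in memory; there is no
  disk-binning mode, so memory grows linearly with input size.
* The 8-bit length/position fields cap reads at 255 bases — short-read data
  by design; long reads need a different format profile.
* Identifiers and quality scores are not compressed; decompressed FASTQ
  carries placeholder ids and qualities (FASTA output available).
* The archive format is this package's own (documented in FORMAT.md); it is
  not byte-compatible with any other tool's container.
* Assignment is order-dependent (pools grow as reads arrive), which is
  inherent to the streaming formulation; determinism is preserved because
  arrival order is input order.
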