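# Methods

## The rotational code

The codec works over an ordered alphabet of K letters (default
A, T, C, G, M with M = 5-methylcytosine) and has radix N = K − 1 = 4.
The transcoding table is the cyclic rotation

    next(prev, d) = letters[(index(prev) + 1 + d) mod K],  d ∈ {0..N−1}

which for every previous letter maps the N digits bijectively onto the
other N letters, so raw output can never repeat a letter and any
adjacent repeat observed at decode time is proof of corruption
(`InvalidTransitionError`). The first position rotates from a *virtual*
previous letter A, reset at the start of every oligo so oligos decode
independently. The table order is configurable; the default order is
the unique simple cyclic rule consistent with the canonical worked
example (byte 150 → quaternary 2112 → GACA), verified by brute force
over all 120 candidate orders.

Bytes are converted digit-wise, 4 base-4 digits per byte (MSB first),
rather than by big-integer conversion of the whole stream: byte
boundaries survive, any segment is randomly accessible, and the same
rule generalises to other radices (radix 7 packs each byte into 3
digits). Encoding and decoding are vectorised: with
idx<sub>i</sub> = idx<sub>i−1</sub> + 1 + d<sub>i</sub> (mod K), the whole letter-index
sequence is a cumulative sum, and decoding inverts it column-wise; a
digit value of K − 1 marks an invalid transition.

## Packetisation and erasure redundancy

Segments are 22 bytes (the last zero-padded), addressed 0..n−1. Pairs
(2k, 2k+1) produce parity segments by bytewise XOR, appended after the
data block with consecutive addresses; an odd trailing segment pairs
with an implicit all-zero phantom so the algebra stays uniform. A
5,929-byte file therefore yields 270 data + 135 parity = 405 oligos.

Each oligo is 100 letters: a 12-digit (24-bit) address field, chosen so
12 + 88 = 100 exactly fits a 22-byte payload, then the payload digits,
transcoded as one stream from the virtual letter. The original file
length and checksum live in a JSON manifest sidecar rather than a
header oligo, preserving the oligo count arithmetic.

Decoding marks an oligo invalid — an erasure, never an exception — on
wrong length, an invalid transition, a foreign symbol, or an address at
or beyond the segment count (a useful corruption detector: a randomly
corrupted 24-bit address almost surely overshoots a store of a few
hundred segments). For each triple with exactly one missing member the
XOR of the other two restores it. Unrecoverable data segments decode as
zero bytes so the recovery-rate denominator is always the full file:
recovery rate = correctly decoded bits / total bits of the original.

## Channel model

Errors are independent per-letter Bernoulli events at total rate p;
the event type is drawn from a (substitution, insertion, deletion) mix,
default uniform thirds since all three classes occur in long-read
sequencing and no finer in-silico mix is prescribed. Substitutions
always change the letter; insertions add a uniform letter after the
position. Corruption is applied per oligo — the stored unit — and
replicate generators derive from (seed, rate index, replicate index),
so experiments are reproducible and replicates independent. The
replicate coefficient of variation uses the sample standard deviation
(ddof = 1). At p = 10⁻⁴ a ~6 kB store decodes essentially completely
(the residual comes from the rare substitution that neither creates an
adjacent repeat nor corrupts the address field and therefore evades
detection); recovery then falls smoothly through p = 10⁻³ and 10⁻².

## Sequence statistics

GC content counts G, C and M (methylated cytosine is chemically a
cytosine); a flag excludes M for sensitivity analyses. Homopolymers are
computed after collapsing M onto C for the same reason — raw rotational
output never repeats a letter, so uncollapsed runs are always 1.
Uniform random input makes the letter process a uniform walk over the
5 letters, giving stationary frequency 1/5 each and expected GC 3/5;
per-oligo GC means of random fixtures sit near 60% and within the
50–70% band. Statistics are per oligo by default with an optional
whole-stream mode for file-level summaries.

## Adaptor design

All 4⁸ = 65,536 8-mers are enumerated; the composition filter keeps GC
in [40%, 60%] inclusive (for 8-mers this forces exactly four G/C) and
maximum run ≤ 2, leaving 14,696 survivors. Distance selection reads
"greater than 4" as Hamming ≥ 5. The literal all-pairs rule keeps a
survivor only if it is ≥ 5 from *every* other survivor; because
survivors come in dense clusters this annihilates the set (size 0), so
it is retained only for fidelity. The default is greedy code
construction in lexicographic order (A < C < G < T), which yields a
deterministic, maximal set of 48 adaptors at minimum pairwise distance
5 — enough for the 27 junctions of one ligation group. An optional
flag additionally rejects reverse-complement clashes.

## Assembly layout

Oligos get their adaptor appended 3′ (108-nt units) and are grouped 27
at a time by consecutive address, groups labelled A, B, C, … Units
1–15 form subfragment 1 and units 16–27 subfragment 2, mirroring the
5+5+5 / 4+4+4 staged ligation. 12 × 108 = 1,296, so the observed
1,288 bp second subfragment is reproduced by omitting the trailing
adaptor on each group's final unit (the unique simple arithmetic that
reconciles the printed value); the convention is configurable and the
group total is then 27 × 108 − 8 = 1,620 + 1,288 = 2,908 bp.

## Read simulation and the decoding pipeline

Synthetic reads emulate the *shape* of nanopore output: basecalled
ACGT (M rendered as C), a methylation score 0–255 for every basecalled
C, per-base substitution/insertion/deletion errors, and flanking
barcodes. True-M sites score ≥ 128 unless the caller "misses"
(rate 5% by default), true-C sites score < 128 unless it "false-calls"
(5%); base errors default to 0.5% substitutions and 0.25% each indel,
a modest long-read-like profile, and depth defaults to 10 reads per
fragment. The score scale is the 0–255 byte scale standard for BAM ML
methylation tags, with the calling threshold ≥ 128 inclusive. The
generator does not model sequence-context error biases, quality drift
along the read, chimeras or coverage skew, so passing tests demonstrate
the pipeline's logic, not performance on real flow-cell data.

The pipeline: methylation calling rewrites qualifying C to M; identity
against a reference is matches / aligned columns of a semi-global
alignment (edlib; read overhangs such as barcodes are free), screened
at ≥ 0.85 inclusive; barcodes are trimmed by fuzzy search (≤ 1
mismatch) near the read ends; adaptor cutting uses exact 8-mer search
with a one-mismatch fallback that only engages when no exact occurrence
remains (unconditional fuzzy matching would cut spuriously inside
payloads); pieces must measure 80–120 nt inclusive.

Consensus is a deterministic star MSA: the piece of median length
(first on ties) is the centre, all others are globally aligned to it
with edlib, and columns — centre positions plus ranked insertion
columns — vote by majority. A strict gap majority emits nothing; letter
ties break by the fixed precedence A < T < C < G < M. A hand-rolled
star alignment is used rather than an external MSA tool because
general-purpose aligners interpret M as an IUPAC ambiguity code (A/C),
which corrupts alignment over the expanded alphabet; for ~10 near-
identical ~100-nt pieces a star alignment is accurate and fast.

Two decode modes. *With reference*: reads are assigned to their best-
matching designed fragment, a consensus is built per fragment, cut at
adaptors and decoded. *Without reference*: each read is cut first, each
piece's address field is decoded, pieces group by address, and a
consensus per address is decoded — fully blind, but any piece whose
length or transitions were corrupted cannot be grouped, so this mode is
never more accurate than reference-guided decoding (the blind grouping
rule is this package's own design; address-keyed grouping is the
natural choice given independently decodable oligos). Error statistics
classify consensus-vs-reference differences by global alignment into
substitutions, insertions and deletions, report the C↔M share of
substitutions, and attribute each event to a reference position.

## Problem sizes and numerical choices

The test suite and acceptance script run entirely on generated
fixtures: the canonical 5,929-byte file for counting/assembly checks,
a 1 MB random fixture for GC statistics (≈ 68k oligos, a second or two
with the vectorised codec), ten replicates for channel experiments, and
small multi-oligo stores (≈ 3–9 oligos, depth 10) for pipeline
round-trips — sizes chosen so every property is exercised end-to-end
while the whole suite stays interactive. Randomness flows exclusively
through numpy `default_rng` seeds; all boundary conventions
(threshold 128, identity 0.85, window 80–120, GC 40–60%) are inclusive.

## Known limitations

- The rotational code constrains neither GC content nor collapsed
  homopolymer runs; constrained transcoding is out of scope.
- No Reed–Solomon or fountain coding: a triple with two lost members is
  unrecoverable and decodes as zeros.
- The blind decode mode depends on exact-length (100-letter) pieces;
  heavy indel noise starves it of groupable pieces.
- Real basecalling, FAST5/POD5/BAM ingestion and wet-lab protocol
  modelling (ligation efficiency, gel yields) are not modelled; the
  published real-data recovery rates depend on deposited sequencing
  data and are deliberately not reproduction targets here.
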