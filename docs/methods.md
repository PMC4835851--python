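# Methods

## Problem setting

A genomic lookup hash table maps every possible k-mer to the list of its
start positions in a genome. It is stored as a *positions array* (all
positions, grouped by k-mer code) and an *offset array* of length 4^k + 1
whose entry *m* points at the start of k-mer *m*'s list; retrieving a list
means reading the adjacent pair (offsets[m], offsets[m+1]). The offset
array grows as 4^k — 4 GB of 4-byte entries at k = 15 — while the positions
array grows only with the genome, so the offset array is the structure
worth compressing. Because offsets point at successive locations in the
positions array they are monotone nondecreasing, and the differences
between successive entries are mostly 0 or small, with occasional large
values at repetitive k-mers. `bpoffsets` compresses those differences in
fixed-size blocks and supports random access to any single offset, or to an
adjacent pair, without decoding the rest of the stream.

## Block model

The difference stream is cut into blocks of B = 64 (or 32) values. Each
block stores its differences at one uniform bit width — the smallest
allowed width that fits the block's largest difference — and a separate
metainformation array holds, per block, a pointer into the bitstream and
the prefix sum at the block's first element, plus one sentinel entry past
the last block so every block also knows its *ending* prefix sum. Widths
are restricted so a block always fills whole 128-bit vectors (even widths
for B = 64, multiples of 4 for B = 32): an odd width would occupy the same
number of vectors as the next allowed width while needing more complex
decode arithmetic. The width is therefore implicit in the difference
between successive pointers (stored in 128-bit vector units) and is not
stored separately. Width 0 marks the all-zero block; lookups there return
the stored prefix sum without touching the bitstream. A final partial
block is padded by repeating the last offset; padded slots are never
exposed.

## Difference schemes

Decoding works on four 32-bit lanes of a 128-bit vector at once,
maintaining four running sums. The stored differences are therefore
lane-cyclic, `d[i] = x[i+1] - x[i-3]`, with the first four taken relative
to the block prefix sum x0 (*unidirectional* scheme). Reconstructing x_r
needs only the chain `d[(r-1) mod 4], d[(r-1) mod 4 + 4], ...` — one
*column* of the block.

The *bidirectional* scheme cuts the worst case in half: the first
half-block is encoded forward from x0 as above, and the second half-block
encodes the mirrored chain toward x_B (with y_s = x_B − x_{B−s}, the
second-half differences are the unidirectional differences of y). A
second-half value is recovered by subtracting a short cumulative sum from
x_B, which the sentinel meta entry always provides. x_{B/2} reconstructs
identically from either end (both chains telescope to the same integer
sums), which `undiff` verifies. For any position r the distance to the
nearest prefix sum is δ = (B/2 − 1) − |r − B/2| (for B = 64: 31 − |r−32|);
the required column is δ mod 4 and rows 0..⌊δ/4⌋. At r = B the formula
gives δ = −1: the value *is* the ending prefix sum, returned directly with
zero decode steps (inside a container this case is always answered from
the meta array anyway). Step-pattern assertions therefore range over
r = 1..B−1.

## Layouts

Within a lane, bits are least-significant-first; a value straddling a
32-bit word boundary puts its low bits in the earlier vector.

* **Vertical** (unidirectional): differences striped in index order, four
  per row. Serial decode masks, shifts, and accumulates one group of four
  per cycle: ⌈r/4⌉ cycles to reach x_r (11 cycles for x_43).
* **Columnar**: each column's entries are packed contiguously, striped in
  groups of four rows across the lanes, so reaching x_r loads only its own
  column: quarter-blocks Q1–Q4 (16 positions each for B = 64) need
  1/2/3/4 group loads unidirectionally and 1/2/2/1 bidirectionally. In the
  bidirectional layout the first half's columns are packed in order
  0,1,2,3 and the second half's in reverse order 3,2,1,0. The reversal
  keeps *neighboring* columns (the column of r and of r+1, with 3 and 0
  neighboring) in adjacent stripes for both halves, which one-pass pair
  retrieval exploits. At width 6 this reproduces the canonical shift
  constants: first-half column 2, group 0 sits at lane bits 24–29 (a
  24-bit right shift exposes it) and group 1 straddles the word boundary
  (30-bit right shift of one vector, 2-bit left shift of the next).

After loading its G groups a columnar decode chains G−1 parallel
additions, producing a 4G-word array whose word 4g+l holds the cumulative
lane sum through group g. Any within-column cumulative sum is then a
scalar sum of at most four of those words (x_23: exactly words 2–5), the
property that makes per-quarter procedures constant-work. Step counts are
per-quarter, not per-row: an entry early in Q3 still runs the two-load Q3
procedure. Q1 results fall out en route to Q2 and Q4 en route to Q3, so
only Q2/Q3 procedures are primitive: with 16 nonzero even widths, 4
columns and 4 quarters the dispatch table has 256 entries, 128 of them
primitive. The table is realized as partial applications of one
parameterized decoder keyed by (width, column, quarter) — an indexed
dispatch whose variant count is enumerable, which the tests assert.

`DecodeStats` counts `group_steps` (shift/mask/add cycles over four-entry
groups — the unit all step claims use), `vector_loads` (distinct four-word
vectors read; can exceed steps when a group straddles words, and is shared
between the two halves of a one-pass pair lookup), and `terms_summed`.
One asymmetry: the vertical decoder reports ⌈r/4⌉ steps even at width 0
(its serial loop is the defined cost model), while the columnar decoder
short-circuits width 0 to the prefix sum with zero steps.

## Universal-code baselines

Elias gamma (2c−1 bits for a c-bit value), Elias delta (gamma-coded bit
count, then the c−1 trailing bits) and Fibonacci (Zeckendorf form, lowest
Fibonacci first, '11'-terminated) serve as compression/speed baselines,
with 64 *adjacent* differences per block — decoding is serial within a
block, so lane-cyclic differences would buy nothing. Since these codes
cannot represent 0 but zero differences dominate, every difference d is
stored as code(d+1) and decoders subtract 1 (the shifted convention).
Block pointers for these schemes are bit offsets. Random access decodes r
codes serially from the block start; pair retrieval continues one more
code, the natural one-pass form. Array-scale compression uses vectorized
encoders (uint64 code lanes, scatter-OR assembly) cross-checked against
the scalar encoders; values ≥ 2^31 fall back to scalar big-integer
encoding because gamma(2^32) needs 65 bits.

## Container and file format

`CompressedOffsetVector` = scheme id + logical length n + uint32 bitstream
+ pointer array + prefix-sum array. `lookup(i)` maps i to block ⌊i/B⌋ and
position r = i mod B; r = 0 is answered from the meta array alone.
`lookup_pair_twopass` makes two independent calls;
`lookup_pair_onepass` shares loaded vectors between the two columns (or
continues the serial scan for universal codes) and is verified to return
identical pairs with never more vector loads. Serialization is
little-endian: a "BPOF" magic, format version, scheme id, block size, k
(−1 if unknown), n and meta count, then pointers (int64 — universal-code
bit offsets can exceed 32 bits at the 4^15 scale), prefix sums (uint32)
and the bitstream. `storage_size_bytes` reports the conventional
in-memory accounting — 4 bytes per entry uncompressed (4 GB at k = 15),
4 bytes per bitstream word plus 8 bytes per meta entry compressed.
Prefix sums are stored as 32 bits; offsets[n−1] < 2^32 is a container
precondition (positions arrays beyond 4G entries are out of scope).

## Hash-table construction

`build_hash_table` stores position p for every p with p mod sampling = 0,
p + k ≤ L, and the k-mer at p entirely in {A,C,G,T}; k-mers touching any
ambiguity code are skipped, not masked, because the table indexes the
exhaustive set of unambiguous k-mers. The 2-bit code is the conventional
A=0, C=1, G=2, T=3 with the leftmost base most significant. Construction
counts codes, prefix-sums the counts into the offset array, and places
positions with a stable sort so each list ascends; it is fully
deterministic. Multi-record FASTA input is concatenated with an `N`
separator into one global coordinate space so no k-mer spans records.
Only the forward strand is indexed. The default cap k ≤ 15 bounds the
4^k + 1 allocation.

## Synthetic data

`random_offsets` emulates k-mer-table offset statistics: a zero_fraction
share of zero differences (default 0.85 — at 15-mers sampled every 3 bp,
most table slots are empty even for mammalian genomes) and Zipf-tailed
nonzero differences (default exponent 1.4, clipped at 2^16) modelling
occasional highly repetitive k-mers; the cumulative sum must stay within
32 bits or generation fails. `random_genome` draws i.i.d. bases at a
chosen GC content (default 0.42, a typical vertebrate value), optionally
injects tandem-repeat tracts to skew k-mer counts, and optionally sprinkles
N's. What the generator does **not** emulate: long-range genomic repeat
structure (segmental duplications, satellite arrays), compositional
heterogeneity along chromosomes, and real k-mer spectra; passing tests
demonstrate codec correctness on the right *difference statistics*, not
biological fidelity of any particular genome.

## Benchmark protocol

`run_benchmark` draws uniform random pair queries over indices 0..n−2
(the last index has no successor), visits schemes in a freshly shuffled
order each trial, subtracts a measured empty-loop overhead, and summarizes
per-query nanoseconds by the median over trials (protocol defaults: 10^7
queries, 9 trials; tests and the CLI default to reduced sizes). A 64-bit
additive checksum over all returned pairs must agree across schemes in
every trial — a cross-codec consistency assertion. Timing numbers are
hardware- and interpreter-dependent and are reported, never asserted;
space numbers are deterministic and are asserted exactly.

## Numerical and edge-case choices

* All difference arithmetic is int64 internally; packing uses uint64
  shifts (max value 2^32−1 shifted by ≤ 31 stays in range).
* Width selection uses exact integer bit lengths (via `frexp`, exact below
  2^53) rounded up to the allowed granularity.
* n = 1 arrays compress to zero blocks (meta only); n − 1 ≤ B uses one
  block.
* Non-monotone input, width overflow, out-of-range indices, unencodable
  k-mers, 32-bit overflow, malformed bitstreams and malformed container
  files each raise a dedicated exception rather than returning garbage.

## Problem sizes used in the test suite

Exhaustive oracle-equivalence runs use arrays up to 12 289 entries (all
indices, all pair variants, all six schemes) plus a 10^6-entry
heavy-tailed array checked by full decompression and sampled lookups; the
end-to-end check builds a 1 Mb synthetic genome with k = 8, sampling 3,
and verifies all 4^8 + 1 lookups under every scheme. The full suite runs
in well under a minute on one core.

## Known limitations

* Pure Python/NumPy: the step counters model the SIMD cost structure, but
  wall-clock ns/query are nowhere near compiled-code figures; relative
  ordering of schemes is nonetheless observed to match the design's
  intent.
* The horizontal packing layout and 128-value vertical blocks are not
  implemented (background material, not part of this design).
* Containers are immutable after construction; no appending or concurrent
  mutation, no memory-mapped access.
* Positions arrays are deliberately left uncompressed — adjacent genomic
  positions lack the closeness structure offsets have, and alignment-side
  consumers want plain arrays.
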