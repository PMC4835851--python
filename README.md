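# bpoffsets

Random-access compressed offset arrays for genomic k-mer hash tables.

A lookup hash table gives, for every possible k-mer, the list of its start
positions in a genome: a *positions array* holds all positions grouped by
k-mer code, and an *offset array* of length 4^k + 1 delimits each list —
k-mer *m*'s positions are `positions[offsets[m] : offsets[m+1]]`. The
offset array grows as 4^k (4 GB of plain 4-byte entries at k = 15), which
is what keeps aligner hash tables stuck at small k. Because offsets are
monotone nondecreasing, their differences are mostly tiny and compress
extremely well — but an aligner needs *random access* to two adjacent
offsets per seed lookup, not serial decompression.

`bpoffsets` implements block-based differential bitpacking designed for
exactly that access pattern, for anyone building or studying genome index
structures:

* **bp64v** — vertical layout, unidirectional lane-cyclic differences
  (`d_i = x_{i+4} − x_i`), block size 64: the classic serial-decode
  arrangement, here instrumented for random access.
* **bp64c** — columnar layout with a *bidirectional* difference scheme:
  the first half-block is encoded forward from the block's prefix sum x_0,
  the second half backward from x_64 (already stored as the next block's
  prefix sum). Any value x_r is then at distance δ = 31 − |r − 32| from a
  stored prefix sum, in column δ mod 4, and is reconstructed from at most
  two group loads plus a scalar sum of at most four terms.
* **bp32c** — the same columnar design at block size 32 (widths in
  multiples of 4): fewer decode steps, twice the metainformation.
* **gamma / delta / fibonacci** — block-wise Elias and Fibonacci universal
  codes (64 adjacent differences per block, each difference d stored as
  code(d+1) so zeros cost one bit), as baselines.

Every scheme supports `lookup(i)`, plus `lookup_pair_onepass` /
`lookup_pair_twopass` for the adjacent pair an aligner needs; one-pass
retrieval reuses vectors already loaded for the neighboring column.
Instrumented decoders report group-decode steps and vector loads, so the
cost structure of each scheme is measurable, not just its output.

## Worked example

```python
import bpoffsets as bp
from bpoffsets import compressed_offsets as co, synthetic as syn

genome = syn.random_genome(100_000, seed=1, repeat_spec=syn.RepeatSpec())
table = bp.build_hash_table(genome, k=7, sampling=3)
print("offsets entries:", len(table.offsets), " positions stored:", len(table.positions))

vec = co.compress(table.offsets, "bp64c", k=7)
print("uncompressed bytes:", co.storage_size_bytes("uncompressed", n=vec.n))
print("bp64c bytes:       ", co.storage_size_bytes(vec))

code = bp.encode_kmer("ACGTACG")
a, b = co.lookup_pair_onepass(vec, code)
print(f"ACGTACG -> code {code}, offsets ({a}, {b}), {b - a} genomic positions")

stats = bp.DecodeStats()
co.lookup(vec, 10003, stats)
print("group steps for one random lookup:", stats.group_steps)
```

prints

```
offsets entries: 16385  positions stored: 33332
uncompressed bytes: 65540
bp64c bytes:        12328
ACGTACG -> code 1734, offsets (4285, 4286), 1 genomic positions
group steps for one random lookup: 2
```

The 16 385-entry offset array (4^7 + 1; 65 540 bytes uncompressed) shrinks
to 12 328 bytes of bitstream + metainformation. The k-mer `ACGTACG` has
code 1734; the adjacent offset pair (4285, 4286) says its positions list
holds one entry. The random lookup needed only 2 group-decode steps — the
bidirectional columnar worst case.

The same pipeline is available from a shell:

```sh
bpoffsets build genome.fa genome.bpof --k 15 --sampling 3 --scheme bp64c
bpoffsets query genome.bpof --kmer ACGTACGTACGTACG --one-pass
bpoffsets bench --container genome.bpof --queries 100000 --trials 3 --out report.csv
bpoffsets inspect genome.bpof --limit 20
```

`bench` compresses the same offsets under all six schemes plus the
uncompressed baseline, runs a shared random pair-query stream per trial
with per-scheme order shuffling and overhead subtraction, verifies that
all schemes produce identical checksums, and reports bytes and median
ns/query per scheme as CSV and a text table. (Absolute timings are
interpreter-bound; the step/load counters are the portable cost measure.)

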