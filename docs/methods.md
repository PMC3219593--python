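# Methods

## Model

`recoil` compresses a collection of short DNA reads by exploiting read
overlap rather than a reference: if two reads are similar it is cheaper to
store one of them plus their differences than both. Similarity between reads
`s1` and `s2` is expressed through their maximal exact matches (MEMs) —
exact matches that cannot be extended in either direction without a mismatch
or running off an end. Encoding `s2` against `s1` stores the coordinates of
a chain of MEMs plus the letters of `s2` the chain leaves uncovered.

The partner for each read is chosen globally. A weighted similarity graph is
built over all reads, with edge weight equal to the number of shared-seed
anchors between the two reads (a proxy for the encoding gain), and a maximum
spanning tree of this graph provides the parent of every read. The tree is
rooted and traversed breadth-first; reads are stored in BFS order, so each
read's parent is decoded before the read itself and parent positions are
non-decreasing, turning both encoding and decoding into forward-only scans.

Every stage is a reduction to scanning or sorting: seed generation (scan),
seed sort, anchor generation (scan), anchor sort, edge aggregation (scan),
Kruskal over the sorted edge stream, BFS reordering of reads (sort), MEM
encoding (two parallel forward scans), decoding (forward scans plus one sort
to restore the input order). Sorting is a chunked external merge sort; only
the union-find array, the spanning tree and the BFS permutation are assumed
to fit in memory (a few machine words per read).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k_graph` | 15 nt | seed length for the similarity graph |
| `k_encode` | 10 nt | seed length for MEM finding between a read pair |
| `top_seeds` (t) | 8 | distinct largest k-mer values kept per read |
| `anchor_cap` | 80 | anchors emitted per seed value before cutting off |
| `letter_cost` | 2 bits | cost of one plaintext nucleotide |
| `mem_record_cost` | 2·`k_encode` bits | cost charged per stored MEM record |
| `codec` | lzma | final general-purpose stage (lzma / bz2 / zlib / none) |
| `chunk_limit` | 2·10⁶ records | resident records per external-sort chunk |
| `buffer_records` | 1024 | parent-scan buffer in the encoder/decoder |

The top-t filter is interpreted as the t largest *distinct* values per read,
keeping all of their occurrences: occurrences are what anchor two reads, and
a repeated top value inside one read must not crowd out the others. A
switch (`top_mode="records"`) provides the stricter per-record reading.

The gain model makes the chaining objective exactly the encoded-size
minimisation: a chain's gain is Σ(2·length − mem_record_cost), gap opening
costs one MEM record, gap extension costs 2 bits per uncovered letter. The
default `mem_record_cost = 2·k_encode` places the shortest profitable MEM
exactly at the seed length k — the sparse-alignment restriction that every
matching segment be at least k long then coincides with the profitability
threshold, so the seed length and the gap-open penalty are a single
consistent knob. A MEM of length exactly k has gain 0 and is still used
(profitable-at-zero), which also means a read whose best chain only breaks
even is stored via MEMs rather than explicitly; explicit storage is chosen
only when it is strictly smaller. The cost constants are recorded in the
archive header and configurable (`--mem-record-cost`).

## Numerical and tie-break choices

- Nucleotide digits fixed as A=0, C=1, G=2, T=3, recorded in the header.
  All coordinates are 0-based, end-exclusive.
- k-mer windows containing N produce no seed; N letters always travel in the
  plaintext stream.
- External sort breaks key ties by the full record tuple, so output is a
  total order and byte-identical for every chunk size.
- Anchors within a seed-value run are emitted ring by ring (adjacent pairs
  first) in left-to-right order; pairs are normalised small-id-first;
  self-pairs (a read meeting its own reverse complement) are skipped and do
  not consume the cap.
- Connectivity chain edges carry weight 0, so the maximum spanning tree uses
  them only where no anchor path exists; reads joined only by a chain edge
  fall back to explicit storage through the gain test.
- Kruskal ties break by (weight desc, u asc, v asc); BFS visits children in
  ascending read id; the root is read 0. Together these make archives
  deterministic for a given input and configuration.
- MEM chains are selected by an O(n²) dynamic program over MEMs sorted by
  destination start (n = MEMs per read pair, typically a handful); a chain
  member overlapping its predecessor in either string is trimmed from the
  left, and a member trimmed below profitability simply is not selected.
  The O(n log n) sparse-DP scheme would compute the same optimum; at these n
  the quadratic form is simpler and fast.
- Orientation ties (forward vs reverse-complement parent) go to forward.
- Degenerate inputs: an empty dataset produces a valid empty archive; reads
  shorter than k produce no seeds and are stored explicitly; a single read
  is its own root.

## Archive format

Streams are kept separate (read lengths, modes, parent positions, MEM source
starts, destination gaps, MEM lengths, plaintext letters, original-order
permutation) because each is individually low-entropy: lengths are nearly
constant, parent positions are non-decreasing, MEM coordinates are small
after difference coding. Integer streams are difference-coded (first value
verbatim, then zig-zag deltas) as LEB128 varints, then each stream is
independently compressed by the chosen codec, so the decoder can stream all
of them concurrently. The header records magic, version, codec, both k
values, the letter map, t, the anchor cap and the gain-model constants,
making archives fully self-contained.

The original-order permutation is stored by default so decompression is
order-faithful; `--no-order` drops it for extra ratio when read order is
considered insignificant, in which case decoding returns the reads in tree
(BFS) order.

## Synthetic data

The generator emulates the evaluation protocol the compressor is designed
for: reads of fixed length sampled uniformly from a source genome (a seeded
i.i.d. random sequence by default, or a user-supplied FASTA for realistic
repeat structure), with an error applied independently at each emitted base
with probability 0.02 — insertion, deletion or substitution chosen uniformly,
substitutions uniform over the three alternative bases — and each read
reverse-complemented with probability 0.5. Coverage c over a genome of
length G yields ⌈c·G/L⌉ reads of length L. The genome is treated as
circular so sampling is exactly uniform and every read has full length.

What this does not model: platform-specific error profiles (quality-
dependent error rates, homopolymer indel bias), non-uniform coverage,
paired-end structure, and real genomic repeat families (unless a real genome
is supplied). Passing tests on this generator therefore demonstrate the
mechanics — losslessness, bounded memory, redundancy exploitation and its
trends in coverage and read length — not absolute compression ratios on any
particular instrument's output.

Test and evaluation problem sizes are desk-scale by design: round-trip and
trend checks use 10⁵–10⁶ base genomes and 1–2 Mb of reads, which already
give the coverage regimes of interest while keeping the whole suite fast.

## Known limitations

- The anchor cap and top-t filter are heuristics; they can under-weight the
  true pairwise gain for highly repetitive seeds, occasionally picking a
  suboptimal spanning-tree parent.
- Edge weights count shared seeds, not actual encoded savings; the spanning
  tree is a maximum-weight proxy, not a provably optimal encoding forest.
- No random access: retrieving one read requires decoding its whole ancestor
  path, i.e. in practice a full decompression.
- Quality scores and read names are not stored; decompressed FASTA headers
  are `>read_<original ordinal>`.
- The pure-Python implementation favours clarity and auditability; the
  bounded-memory architecture is real, but constants are far from those of
  an optimised native implementation.
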