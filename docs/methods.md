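# Methods

## Model and procedure

basecov compiles read alignments into per-position tracks and serves them
back at any zoom. The quantities it computes are:

- **Coverage.** For each genomic position *p* and strand, the number of
  reads whose alignment consumes the reference base at *p*. A read is a
  list of reference intervals ("blocks") derived from its CIGAR string:
  match/mismatch (`M`, `=`, `X`) and deletion (`D`) operations consume the
  reference and count as covered; skipped regions (`N`, spliced-aligner
  introns) consume the reference but split the read into separate blocks;
  insertions and clips (`I`, `S`, `H`) consume none. A plain unspliced,
  indel-free read is the single-block special case.
- **Mismatch counts and %mis.** The MD tag interleaves match-run lengths
  with substituted reference bases (`"59A15"`: 59 matches, a substitution
  whose reference base is A, 15 matches — the 60th 1-based read position).
  MD offsets count covered reference bases, including deleted bases in
  `^`-groups but excluding N-gaps, which is exactly the block coordinate
  system above; each substitution is mapped through the blocks to a genomic
  position. `%mis[p] = 100 · mis[p] / total[p]` (0 where depth is 0). When
  a record has no MD tag, mismatches are recovered by comparing the read
  sequence against the FASTA over the aligned pairs; when neither is
  possible the read contributes coverage but no mismatches.
- **Composition.** Per-position counts of read bases A/C/G/T, attached to
  narrow views (< 500 bp by default) where individual substitutions are
  interpretable.

### Difference-array construction

Coverage is built in O(r + g) rather than O(r·l): each block [s, e) does
`diff[s] += 1; diff[e] -= 1`, and one prefix sum per chromosome converts
changes to depths. The classical statement of this trick decrements at the
*last covered position* and starts the accumulation one position late; with
a standard inclusive prefix sum that variant covers l−1 positions per
l-base read. This implementation uses the half-open form (decrement one
past the block end, plain prefix sum), under which a length-l read covers
exactly l positions. The per-base naive pileup is kept in the test suite as
the independent oracle and is the arbiter of this fencepost choice.

The strand-separated tracks come from two difference arrays; `total` is
their sum rather than a third array (halves the work; an invariant check
enforces `total = pos + neg`). Composition reuses the trick: a third
difference array counts read-base-bearing depth (M/=/X only — deletions
have no read base), composition for base B equals that depth wherever the
reference base is B, and each mismatch site gets a sparse correction
(−1 reference base, +1 read base), so the whole construction stays
O(r + g + #mismatches). If an MD tag contradicts the FASTA the correction
could undershoot; such cells are clipped at zero and tallied.

Counts are stored as unsigned 32-bit (max depth ≈ 4.29 × 10⁹); deeper
coverage is a fatal overflow error, not a silent wraparound. Accumulation
validates that the difference array sums to zero and that no prefix goes
negative.

### Multi-resolution pyramid

Level 0 is the base-level profile. Level k+1 takes non-overlapping windows
of `factor` (default 20) bins of level k and keeps the **maximum**; the
last window may be partial (max over the available children — zero-padding
cannot distort a max of non-negative tracks). Levels are added while the
previous level exceeds `threshold` (default 20 000) bins, so the level
count is set by chromosome size: a 10 Mb chromosome gets levels of
10 000 000 / 500 000 / 25 000 / 1 250 bins. Total stored points follow the
geometric series 1 + 1/20 + 1/400 + … < 20/19, i.e. ≈ 1.05× the base
level.

Maxima compose, so a bin at any level equals the max base-level value over
its genomic span — the property every query relies on. Count tracks
aggregate as integer maxima. %mis aggregates as the max of the *per-base
rates* (stored float32 at levels ≥ 1), because a max of counts divided by
a max of totals is not the max rate. Composition exists at level 0 only:
it backs the narrow-view display, and a max-composition has no meaning
(this also keeps the 1.05× storage bound honest for the integer tracks).

**Level selection.** A viewing range of width w is served by the smallest
level k with w ≤ threshold · factor^k, clamped to the deepest level:
widths ≤ 20 000 bp use the base profile, 20 001–400 000 bp the second,
and so on. The boundary at exactly 20 000 belongs to level 0.

### Store format

A compiled sample is a directory: `manifest.json` plus one binary file per
chromosome (8-byte magic, uint32 format version, then every level's tracks
as contiguous little-endian arrays — uint32 counts, float32 rates — in a
fixed catalog order). The manifest records every array's byte offset, so a
slice of any track is `seek(offset + bin_start·itemsize)` plus one read of
`(bin_end − bin_start)·itemsize` bytes: O(slice), never O(file). Writes go
through a temp file and atomic rename; empty slice requests are errors
rather than empty arrays (they surface caller bugs). The on-disk widths
equal the in-memory widths, so round-trips are bit-exact and a store is
usable across process restarts with no recomputation.

### Query engine

Queries resolve first: reversed start/end are swapped, coordinates clamped
to [1, chromosome length], and gene names resolved case-insensitively
against every name/alias in the compiled GTF index (one record per
gene_id; span = min/max over all its feature lines; prefix completion for
type-ahead). The selected level's bins covering the region are read in one
slice per track; if the bin count exceeds the caller's `max_points`
(their display width), adjacent bins are max-pooled to fit the budget —
chosen over jumping to a deeper level because it returns the finest
resolution consistent with the budget. Returned spans are bin-aligned and
clipped to the chromosome, so edge spans can extend slightly past the
requested coordinates while every value remains the exact base-level max
over its reported span. %mis is computed from counts at level 0 and read
from the stored rate track at deeper levels; at level 0 both routes are
computed in float32 with the same expression, so they agree bitwise.

Exports: TSV (1-based inclusive spans, all tracks, composition columns
when attached, rates printed with 9 significant digits so float32 values
round-trip exactly) and bedGraph (one track per call, native 0-based
half-open coordinates, track definition line included).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `factor` | 20 | bin ratio between adjacent pyramid levels |
| `threshold` | 20 000 bins | stop adding levels once a level fits this; also the per-level serving limit |
| `max_points` | 20 000 | per-query point budget (callers pass their screen width) |
| `composition_threshold` | 500 bp | widest view that attaches A/C/G/T composition |
| `include_secondary` | True | secondary/supplementary alignments count like primaries (no filtering of duplicates or multi-mappers by default); a flag excludes them |

## Synthetic data generator

The fixtures module emits FASTA + SAM + GTF with exact ground truth, so the
whole pipeline is testable hermetically. It emulates: piecewise-constant
per-strand target depths realized by tiling fixed-length (default 75 bp)
reads; uniform-random ACGT references; per-base substitution errors
(default rate 0.01, substituted never to the original base, encoded in MD
tags and the read sequence); a fraction of spliced reads (default 0.1)
carrying an N-gap, mirroring RNA-seq alignments; and genes with names and
aliases laid out as exon features. Truth tracks are computed during
generation by the naive per-base loop — the independent oracle — and the
same seed reproduces byte-identical files. The bundled demo sample is
three chromosomes (25/15/10 kb), ~900 reads and 20 genes.

What it does **not** emulate: realistic error profiles (quality-dependent,
indel errors — generated reads contain no deletions; the CIGAR `D` path is
exercised by hand-written records in the unit tests), paired-end structure,
duplicate reads, non-uniform fragment sampling, or reference ambiguity
(N bases). Passing tests therefore demonstrate algorithmic correctness on
well-formed inputs, not robustness to every pathology of real sequencing
data; malformed-input handling is tested separately with crafted records.

## Numerical and degenerate-input choices

- Ties in window maxima need no tie-break (the value, not the position, is
  stored).
- Depth-0 positions: %mis defined as 0.
- Reads whose blocks fall outside the chromosome are skipped and tallied;
  a SAM chromosome absent from the FASTA is fatal (reference mismatch).
- An MD tag whose implied span disagrees with the CIGAR keeps the read's
  coverage but drops its mismatch list (tallied), since the tag is
  untrustworthy while the CIGAR is mandatory.
- Empty SAM: every FASTA chromosome still gets (all-zero) tracks and a
  store, so queries behave uniformly.
- Gene spans cover *all* of a gene's feature lines; GTF has no standard
  alias attribute, so any `*alias*`/`gene_synonym` attribute is indexed
  when present and aliases are otherwise simply absent.

## Problem sizes used in the automated checks

The test suite works on synthetic chromosomes of 2–100 kb (20+ random
seeds for the oracle-equivalence property; an exhaustive width sweep of
1–100 000 bp for the point-budget contract) and builds full pyramids up to
10 Mb for the geometry and storage-ratio checks; these sizes exercise
every code path, including multi-level pyramids and pooling, while keeping
the suite quick on one CPU.

## Known limitations

- Per-record SAM parsing is delegated to pysam, which reports malformed
  mandatory fields without line numbers and cannot resume iteration after
  a truly unparseable record; such files fail fatally.
- A SAM without @SQ header lines cannot be processed (pysam needs them to
  resolve reference names).
- No normalization (RPKM/CPM), duplicate marking, quality weighting, or
  variant calling — the tracks are raw counts by design.
- Stores are single-writer; there is no compression (the memory-dump
  layout trades size for one-read random access).
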