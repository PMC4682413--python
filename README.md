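# basecov

**basecov** is a headless compile-and-query kernel for base-level read
coverage from next-generation sequencing alignments. It is aimed at people
building genome-browser backends or doing interactive coverage inspection:
it turns a SAM file of aligned reads (plus the FASTA reference and an
optional GTF annotation) into a compact binary *track store*, and then
answers arbitrary genomic-range or gene-name queries — whole chromosomes
included — returning a bounded number of data points, each of which is an
exact summary of the underlying per-base data.

## The method

**Difference-array coverage construction.** The naive pileup walks every
covered base of every read: for *r* reads of length *l* that is O(*r*·*l*).
basecov instead records, for each reference-consuming block [*s*, *e*) of a
read, `diff[s] += 1` and `diff[e] -= 1` — O(1) per block — and recovers the
coverage curve with a single prefix sum over the *g*-base chromosome:

```
cov[p] = Σ_{q ≤ p} diff[q]        →  O(r + g) total
```

Forward- and reverse-strand reads accumulate into separate difference
arrays; `total = pos_strand + neg_strand`. While streaming, per-base
mismatch counts are extracted from each record's MD tag (`"59A15"` means:
of 75 aligned bases, the 60th is a substitution whose reference base is A),
giving the per-position mismatch rate `%mis = 100 · mis[p] / total[p]`.
A/C/G/T read-base composition tracks are built with the same trick: a
difference array of read-base-bearing depth, classified by the reference
base, with sparse corrections at mismatch sites.

**Multi-resolution max pyramid.** Level 0 stores one point per base. Each
higher level bins the previous one by a factor of 20 and keeps the
per-window **maximum**, so a bin at any zoom equals the max base-level
value over its span (peaks are never averaged away). Levels are added until
one has ≤ 20 000 bins, and level *k* serves viewing ranges up to
20 000 · 20^*k* bp. Total storage is 1 + 1/20 + 1/400 + … ≈ **1.05×** the
base level.

**Two-stage architecture.** Compilation (once per sample) writes the
pyramid as a "memory dump": contiguous little-endian arrays whose byte
offsets are recorded in a JSON manifest, so any slice of any track at any
level is one `seek` + one `read`, independent of file size. Queries (many
per sample) never reopen the raw SAM/FASTA/GTF. If the requested range
still maps to more bins than the caller's point budget (their screen
width), adjacent bins are max-pooled on the fly — the max-over-span
guarantee survives every aggregation step.

## Worked example

```sh
$ basecov fixture demo_data               # synthetic sample w/ known truth
$ basecov compile demo --sam demo_data/alignments.sam \
    --fasta demo_data/reference.fa --gtf demo_data/genes.gtf --out store
compiled sample 'demo': 901 reads used, 0 skipped
  chrI: length 25000, 2 levels
  chrII: length 15000, 1 levels
  chrIII: length 10000, 1 levels
$ basecov query demo chrI:10038-10043 --store store
chrom	start	end	total	pos_strand	neg_strand	mis_rate_percent	comp_A	comp_C	comp_G	comp_T
chrI	10038	10038	40	40	0	2.5	0	0	1	39
chrI	10039	10039	40	40	0	0	0	0	40	0
chrI	10040	10040	40	40	0	0	40	0	0	0
chrI	10041	10041	40	40	0	0	0	0	40	0
chrI	10042	10042	40	40	0	0	0	0	0	40
chrI	10043	10043	40	40	0	0	40	0	0	0
```

Each row is one genomic base (the range is < 500 bp, so base composition is
attached): 40 reads cover position 10038, all on the forward strand, and
2.5 % of them (1 of 40) mismatch the reference there — the kind of signal
one inspects for SNP candidates. Queries also accept `--gene Snord11`
(names and aliases, case-insensitive; `basecov genes demo Sno` gives
type-ahead completions), reversed coordinates are auto-swapped, and
`--format bedgraph` exports any single track in standard 0-based half-open
bedGraph. The same operations are available from Python — see
`examples/` for short narrative scripts.

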