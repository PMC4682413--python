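"""Deterministic synthetic data: FASTA + SAM + GTF with exact ground truth.

The generator lays reads according to a piecewise-constant per-strand depth
plan, injects base substitutions at a configurable rate (encoded in each
record's MD tag), optionally splices a fraction of reads with an N-gap, and
writes standard files.  Ground-truth tracks are computed *during generation*
by the naive O(r x l) per-base loop — the independent oracle the fast
difference-array construction is checked against — never by the code under
test.

Same seed, same spec -> byte-identical output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment_io import GeneRecord
from .coverage import COMPOSITION_BASES, COUNT_DTYPE, BaseTrackSet
from .errors import FixturePlanError

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CoverageSegment:
    """Target depth over a 1-based inclusive interval on one strand."""

    start: int
    end: int
    depth: int
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class GenePlan:
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 1-based inclusive
    name: str | None = None
    aliases: tuple[str, ...] = ()


@dataclass
class FixtureSpec:
    """Everything needed to generate a reproducible synthetic sample."""

    seed: int
    chromosomes: tuple[tuple[str, int], ...]
    coverage: dict[str, tuple[CoverageSegment, ...]]
    read_length: int = 75
    mismatch_rate: float = 0.01
    splice_fraction: float = 0.1
    genes: tuple[GenePlan, ...] = ()


@dataclass
class FixtureTruth:
    tracks: dict[str, BaseTrackSet]
    genes: tuple[GeneRecord, ...]
    n_reads: int = 0
    n_mismatches: int = 0
    aligned_bases: int = 0


@dataclass
class Fixture:
    fasta_path: Path
    sam_path: Path
    gtf_path: Path | None
    truth: FixtureTruth


@dataclass
class _Read:
    chrom: str
    pos0: int                       # 0-based leftmost
    strand: str
    blocks: tuple[tuple[int, int], ...]
    seq: str
    subs: tuple[tuple[int, str, str], ...]  # (block_offset, ref_base, read_base)
    cigar: str
    md: str


def _validate(spec: FixtureSpec) -> None:
    lengths = dict(spec.chromosomes)
    if spec.read_length < 1:
        raise FixturePlanError("read_length must be >= 1")
    if not (0.0 <= spec.mismatch_rate < 1.0):
        raise FixturePlanError("mismatch_rate must be in [0, 1)")
    for chrom, segs in spec.coverage.items():
        if chrom not in lengths:
            raise FixturePlanError(f"coverage plan names unknown chromosome {chrom!r}")
        g = lengths[chrom]
        for seg in segs:
            if seg.depth < 0:
                raise FixturePlanError(f"negative depth in segment {seg} on {chrom}")
            if seg.strand not in "+-":
                raise FixturePlanError(f"bad strand in segment {seg} on {chrom}")
            if not (1 <= seg.start <= seg.end <= g):
                raise FixturePlanError(
                    f"segment {seg} does not fit chromosome {chrom} of length {g}"
                )
    for gp in spec.genes:
        if gp.chrom not in lengths:
            raise FixturePlanError(f"gene {gp.gene_id} on unknown chromosome")
        g = lengths[gp.chrom]
        for s, e in gp.exons:
            if not (1 <= s <= e <= g):
                raise FixturePlanError(
                    f"gene {gp.gene_id} exon ({s}, {e}) outside chromosome"
                )


def _make_reads(
    spec: FixtureSpec,
    sequences: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> list[_Read]:
    reads: list[_Read] = []
    lengths = dict(spec.chromosomes)
    for chrom, _ in spec.chromosomes:
        g = lengths[chrom]
        ref = sequences[chrom]
        for seg in spec.coverage.get(chrom, ()):
            for _pass in range(seg.depth):
                pos = seg.start - 1          # 0-based
                seg_end = seg.end            # 0-based exclusive
                while pos < seg_end:
                    l = min(spec.read_length, seg_end - pos)
                    blocks = [(pos, pos + l)]
                    # optionally splice: split into two blocks with an N gap
                    if (
                        l >= 20
                        and rng.random() < spec.splice_fraction
                        and pos + l + 50 <= g
                    ):
                        l1 = int(rng.integers(5, l - 4))
                        gap = int(rng.integers(10, 51))
                        blocks = [(pos, pos + l1), (pos + l1 + gap, pos + l + gap)]
                    # substitutions over the covered (read-base) positions
                    covered = np.concatenate(
                        [np.arange(s, e) for s, e in blocks]
                    )
                    hit = rng.random(len(covered)) < spec.mismatch_rate
                    seq_arr = ref[covered].copy()
                    subs: list[tuple[int, str, str]] = []
                    for off in np.flatnonzero(hit):
                        rb = str(seq_arr[off])
                        alt = [b for b in "ACGT" if b != rb]
                        nb = alt[int(rng.integers(0, 3))]
                        seq_arr[off] = nb
                        subs.append((int(off), rb, nb))
                    cigar = (
                        f"{l}M"
                        if len(blocks) == 1
                        else (
                            f"{blocks[0][1] - blocks[0][0]}M"
                            f"{blocks[1][0] - blocks[0][1]}N"
                            f"{blocks[1][1] - blocks[1][0]}M"
                        )
                    )
                    reads.append(
                        _Read(
                            chrom=chrom,
                            pos0=pos,
                            strand=seg.strand,
                            blocks=tuple(blocks),
                            seq="".join(seq_arr),
                            subs=tuple(subs),
                            cigar=cigar,
                            md=_md_string(subs, l),
                        )
                    )
                    pos += l
    return reads


def _md_string(subs: list[tuple[int, str, str]], aligned_len: int) -> str:
    parts: list[str] = []
    prev = 0
    for off, rb, _nb in sorted(subs):
        parts.append(str(off - prev))
        parts.append(rb)
        prev = off + 1
    parts.append(str(aligned_len - prev))
    return "".join(parts)


def _naive_truth(
    spec: FixtureSpec,
    reads: list[_Read],
) -> dict[str, BaseTrackSet]:
    """Ground-truth tracks by the brute-force per-base loop."""
    tracks = {
        name: BaseTrackSet.zeros(name, g, composition=True)
        for name, g in spec.chromosomes
    }
    for r in reads:
        ts = tracks[r.chrom]
        strand_arr = ts.pos_strand if r.strand == "+" else ts.neg_strand
        off = 0
        for s, e in r.blocks:
            for p in range(s, e):
                strand_arr[p] += 1
                ts.total[p] += 1
                ts.composition[r.seq[off]][p] += 1
                off += 1
        for boff, _rb, _nb in r.subs:
            p = _map_offset(r.blocks, boff)
            ts.mismatch_count[p] += 1
    return tracks


def _map_offset(blocks: tuple[tuple[int, int], ...], off: int) -> int:
    for s, e in blocks:
        if off < e - s:
            return s + off
        off -= e - s
    raise AssertionError("offset beyond read")


def _write_fasta(path: Path, sequences: dict[str, np.ndarray], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, arr in sequences.items():
            fh.write(f">{name}\n")
            s = "".join(arr)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def _write_sam(
    path: Path, spec: FixtureSpec, reads: list[_Read]
) -> None:
    order = {name: i for i, (name, _g) in enumerate(spec.chromosomes)}
    reads = sorted(reads, key=lambda r: (order[r.chrom], r.pos0))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, g in spec.chromosomes:
            fh.write(f"@SQ\tSN:{name}\tLN:{g}\n")
        fh.write("@PG\tID:fixture\tPN:fixture\n")
        for i, r in enumerate(reads):
            flag = 16 if r.strand == "-" else 0
            nm = len(r.subs)
            fh.write(
                f"r{i:06d}\t{flag}\t{r.chrom}\t{r.pos0 + 1}\t60\t{r.cigar}"
                f"\t*\t0\t0\t{r.seq}\t{'I' * len(r.seq)}"
                f"\tNM:i:{nm}\tMD:Z:{r.md}\n"
            )


def _write_gtf(path: Path, genes: tuple[GenePlan, ...]) -> None:
    with open(path, "w") as fh:
        for gp in genes:
            attrs = [f'gene_id "{gp.gene_id}"', f'transcript_id "{gp.gene_id}.t1"']
            if gp.name:
                attrs.append(f'gene_name "{gp.name}"')
            for alias in gp.aliases:
                attrs.append(f'gene_alias "{alias}"')
            attr_str = "; ".join(attrs) + ";"
            for s, e in gp.exons:
                fh.write(
                    f"{gp.chrom}\tfixture\texon\t{s}\t{e}\t.\t{gp.strand}\t.\t{attr_str}\n"
                )


def _gene_truth(genes: tuple[GenePlan, ...]) -> tuple[GeneRecord, ...]:
    out = []
    for gp in genes:
        names = {gp.gene_id}
        if gp.name:
            names.add(gp.name)
        names.update(gp.aliases)
        out.append(
            GeneRecord(
                gene_id=gp.gene_id,
                names=tuple(sorted(names)),
                chrom=gp.chrom,
                start=min(s for s, _e in gp.exons),
                end=max(e for _s, e in gp.exons),
                strand=gp.strand,
            )
        )
    return tuple(sorted(out, key=lambda r: r.gene_id))


def _write_truth_tsv(out_dir: Path, truth: FixtureTruth) -> None:
    tdir = out_dir / "truth"
    tdir.mkdir(exist_ok=True)
    for chrom, ts in truth.tracks.items():
        with open(tdir / f"{chrom}.tsv", "w") as fh:
            fh.write(
                "pos\ttotal\tpos_strand\tneg_strand\tmismatch_count\t"
                + "\t".join(f"comp_{b}" for b in COMPOSITION_BASES)
                + "\n"
            )
            for p in range(ts.length):
                comp = "\t".join(
                    str(int(ts.composition[b][p])) for b in COMPOSITION_BASES
                )
                fh.write(
                    f"{p + 1}\t{ts.total[p]}\t{ts.pos_strand[p]}"
                    f"\t{ts.neg_strand[p]}\t{ts.mismatch_count[p]}\t{comp}\n"
                )


def generate_fixture(
    spec: FixtureSpec, out_dir: str | Path, write_truth: bool = False
) -> Fixture:
    """Generate FASTA + SAM (+ GTF) files and exact ground truth."""
    _validate(spec)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    sequences = {
        name: _BASES[rng.integers(0, 4, size=g)] for name, g in spec.chromosomes
    }
    reads = _make_reads(spec, sequences, rng)
    tracks = _naive_truth(spec, reads)
    truth = FixtureTruth(
        tracks=tracks,
        genes=_gene_truth(spec.genes),
        n_reads=len(reads),
        n_mismatches=sum(len(r.subs) for r in reads),
        aligned_bases=sum(
            sum(e - s for s, e in r.blocks) for r in reads
        ),
    )
    fasta = out_dir / "reference.fa"
    sam = out_dir / "alignments.sam"
    _write_fasta(fasta, sequences)
    _write_sam(sam, spec, reads)
    gtf = None
    if spec.genes:
        gtf = out_dir / "genes.gtf"
        _write_gtf(gtf, spec.genes)
    if write_truth:
        _write_truth_tsv(out_dir, truth)
    return Fixture(fasta_path=fasta, sam_path=sam, gtf_path=gtf, truth=truth)


# ---------------------------------------------------------------------------
# Bundled demo sample: three small chromosomes, twenty genes — a stand-in
# for a compiled demo dataset so the tool can be tried without any NGS data.
# ---------------------------------------------------------------------------

def _demo_genes() -> tuple[GenePlan, ...]:
    named = [
        ("g01", "chrI", "+", ((1200, 1500), (1800, 2200)), "Nop58", ("NOP58A",)),
        ("g02", "chrI", "+", ((5200, 5600),), "Snord70", ()),
        ("g03", "chrI", "-", ((5900, 6400), (6700, 7000)), "Snord11", ("RF01182.1",)),
        ("g04", "chrI", "+", ((10020, 10080),), "Snr47", ()),
        ("g05", "chrI", "-", ((12500, 13400),), "Act1", ("ABY1",)),
        ("g06", "chrI", "+", ((15000, 15800), (16100, 16900)), "Pgk1", ()),
        ("g07", "chrI", "-", ((18000, 18700),), "Tdh3", ("GLD1",)),
        ("g08", "chrI", "+", ((20500, 21400),), "Eno2", ()),
        ("g09", "chrII", "+", ((300, 900),), "Cdc19", ("PYK1",)),
        ("g10", "chrII", "-", ((1500, 2400), (2700, 3100)), "Adh1", ()),
        ("g11", "chrII", "+", ((4000, 4800),), "Fba1", ()),
        ("g12", "chrII", "-", ((6000, 6550),), "Tpi1", ()),
        ("g13", "chrII", "+", ((8000, 8900), (9200, 9700)), "Pdc1", ()),
        ("g14", "chrII", "-", ((11000, 11600),), "Hxk2", ()),
        ("g15", "chrII", "+", ((13000, 13850),), "Gpm1", ()),
        ("g16", "chrIII", "+", ((500, 1300),), "Tef1", ("EF1A",)),
        ("g17", "chrIII", "-", ((2000, 2700),), "Rpl28", ()),
        ("g18", "chrIII", "+", ((4100, 4900), (5200, 5600)), "Rps3", ()),
        ("g19", "chrIII", "-", ((6500, 7200),), "Cyc1", ()),
        ("g20", "chrIII", "+", ((8000, 8650),), "Ssa1", ()),
    ]
    return tuple(
        GenePlan(gid, chrom, strand, exons, name, aliases)
        for gid, chrom, strand, exons, name, aliases in named
    )


DEMO_SPEC = FixtureSpec(
    seed=1207,
    chromosomes=(("chrI", 25000), ("chrII", 15000), ("chrIII", 10000)),
    coverage={
        "chrI": (
            CoverageSegment(1000, 2400, 3, "+"),
            CoverageSegment(1100, 2300, 1, "-"),
            CoverageSegment(5000, 7200, 2, "+"),
            CoverageSegment(5500, 7000, 2, "-"),
            CoverageSegment(10000, 10100, 40, "+"),
            CoverageSegment(12000, 19000, 1, "-"),
            CoverageSegment(15000, 17000, 2, "+"),
            CoverageSegment(20400, 21500, 4, "+"),
        ),
        "chrII": (
            CoverageSegment(200, 1000, 3, "+"),
            CoverageSegment(1400, 3200, 2, "-"),
            CoverageSegment(3900, 4900, 5, "+"),
            CoverageSegment(7800, 9900, 1, "+"),
            CoverageSegment(10800, 11800, 2, "-"),
            CoverageSegment(12800, 14000, 3, "+"),
        ),
        "chrIII": (
            CoverageSegment(400, 1400, 2, "+"),
            CoverageSegment(1900, 2800, 3, "-"),
            CoverageSegment(4000, 5700, 2, "+"),
            CoverageSegment(6400, 7300, 4, "-"),
            CoverageSegment(7900, 8700, 1, "+"),
        ),
    },
    read_length=75,
    mismatch_rate=0.01,
    splice_fraction=0.1,
    genes=_demo_genes(),
)


def demo_sample(out_dir: str | Path, write_truth: bool = False) -> Fixture:
    """Generate the bundled demo fixture (~50 kb over three chromosomes)."""
    return generate_fixture(DEMO_SPEC, out_dir, write_truth=write_truth)


def random_fixture_spec(
    seed: int,
    *,
    n_chroms: int = 2,
    min_length: int = 2000,
    max_length: int = 8000,
    max_depth: int = 5,
    with_genes: bool = True,
) -> FixtureSpec:
    """A randomized but fully-specified FixtureSpec, for property tests."""
    rng = np.random.default_rng(seed)
    chroms = tuple(
        (f"chr{i + 1}", int(rng.integers(min_length, max_length + 1)))
        for i in range(n_chroms)
    )
    coverage: dict[str, tuple[CoverageSegment, ...]] = {}
    genes: list[GenePlan] = []
    gi = 0
    for name, g in chroms:
        segs = []
        for _ in range(int(rng.integers(1, 5))):
            a = int(rng.integers(1, g))
            b = min(g, a + int(rng.integers(50, max(51, g // 2))))
            segs.append(
                CoverageSegment(
                    a, b, int(rng.integers(0, max_depth + 1)),
                    "+" if rng.random() < 0.5 else "-",
                )
            )
        coverage[name] = tuple(segs)
        if with_genes:
            for _ in range(int(rng.integers(1, 4))):
                gi += 1
                a = int(rng.integers(1, max(2, g - 200)))
                b = min(g, a + int(rng.integers(50, 200)))
                genes.append(
                    GenePlan(
                        f"rg{gi:03d}", name,
                        "+" if rng.random() < 0.5 else "-",
                        ((a, b),), f"Gene{gi:03d}", (),
                    )
                )
    return FixtureSpec(
        seed=int(rng.integers(0, 2**31 - 1)),
        chromosomes=chroms,
        coverage=coverage,
        read_length=int(rng.integers(30, 120)),
        mismatch_rate=float(rng.uniform(0.0, 0.05)),
        splice_fraction=float(rng.uniform(0.0, 0.3)),
        genes=tuple(genes),
    )
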