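"""Parsing SAM records, MD descriptors, FASTA references and GTF gene models."""

import re

import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import basecov as bc
from basecov.errors import InputError, MismatchDescriptorError

# --------------------------------------------------------------------------
# MD mismatch-descriptor grammar
# --------------------------------------------------------------------------


@pytest.mark.parametrize(
    "md, mismatches, span",
    [
        ("59A15", [(59, "A")], 75),       # the worked example: 60th base (1-based)
        ("75", [], 75),
        ("10A5C3", [(10, "A"), (16, "C")], 20),
        ("0A74", [(0, "A")], 75),
        ("10^ACG5", [], 18),              # deletion group consumes reference span
        ("5^AC0T4", [(7, "T")], 12),      # substitution right after a deletion
        ("0", [], 0),
    ],
)
def test_mismatch_descriptor_examples(md, mismatches, span):
    got_mm, got_span = bc.parse_mismatch_descriptor(md)
    assert got_mm == mismatches
    assert got_span == span


@pytest.mark.parametrize("bad", ["", "A15", "59A", "59A15X", "10^5", "^AC5", "12 3"])
def test_mismatch_descriptor_rejects_bad_grammar(bad):
    with pytest.raises(MismatchDescriptorError, match="position"):
        bc.parse_mismatch_descriptor(bad)


def _naive_md_parse(md):
    """Independent regex-token walk of the MD grammar."""
    tokens = re.findall(r"\d+|\^[ACGTN]+|[ACGTN]", md)
    assert "".join(tokens) == md
    span, out = 0, []
    for tok in tokens:
        if tok.isdigit():
            span += int(tok)
        elif tok.startswith("^"):
            span += len(tok) - 1
        else:
            out.append((span, tok))
            span += 1
    return out, span


@settings(max_examples=1000, derandomize=True, deadline=None)
@given(
    runs=st.lists(st.integers(0, 99), min_size=1, max_size=8),
    events=st.lists(
        st.one_of(
            st.sampled_from("ACGTN"),
            st.text(alphabet="ACGTN", min_size=1, max_size=4).map(lambda s: "^" + s),
        ),
        max_size=7,
    ),
)
def test_mismatch_descriptor_matches_naive_parser(runs, events):
    """Grammar-valid random strings parse identically in both implementations."""
    n = min(len(events), len(runs) - 1)
    md = str(runs[0]) + "".join(e + str(r) for e, r in zip(events[:n], runs[1:]))
    assert bc.parse_mismatch_descriptor(md) == _naive_md_parse(md)


# --------------------------------------------------------------------------
# SAM iteration
# --------------------------------------------------------------------------


def _write_sam(path, records, chroms=(("chr1", 10000),)):
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    lines += [f"@SQ\tSN:{n}\tLN:{g}" for n, g in chroms]
    lines += records
    path.write_text("\n".join(lines) + "\n")
    return path


def test_reverse_read_with_md_tag(tmp_path):
    """A 75M read at pos 100 with MD 59A15: minus strand, one mismatch at
    1-based read position 60 mapping to the expected genomic base."""
    seq = "C" * 75
    sam = _write_sam(
        tmp_path / "a.sam",
        [f"r1\t16\tchr1\t100\t60\t75M\t*\t0\t0\t{seq}\t{'I' * 75}\tMD:Z:59A15"],
    )
    (read,) = list(bc.iterate_alignments(sam))
    assert read.strand == "-"
    assert read.start == 100
    assert read.blocks == ((99, 174),)
    assert read.aligned_length == 75
    assert len(read.mismatches) == 1
    m = read.mismatches[0]
    assert (m.ref_offset, m.ref_base) == (59, "A")
    assert m.ref_offset + 1 == 60  # the worked example, 1-based
    assert m.read_base == "C"


def test_unmapped_records_skipped_and_counted(tmp_path):
    sam = _write_sam(
        tmp_path / "a.sam",
        [
            "r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII",
            f"r2\t0\tchr1\t1\t60\t4M\t*\t0\t0\tACGT\tIIII\tMD:Z:4",
        ],
    )
    stats = bc.ProcessingStats()
    reads = list(bc.iterate_alignments(sam, stats=stats))
    assert len(reads) == 1
    assert stats.skipped_unmapped == 1
    assert stats.processed == 1


def test_spliced_cigar_blocks(tmp_path):
    """10M5N10M at pos 1 -> two blocks [0,10) and [15,25), aligned length 20."""
    sam = _write_sam(
        tmp_path / "a.sam",
        [f"r1\t0\tchr1\t1\t60\t10M5N10M\t*\t0\t0\t{'A' * 20}\t{'I' * 20}\tMD:Z:20"],
    )
    (read,) = list(bc.iterate_alignments(sam))
    assert read.blocks == ((0, 10), (15, 25))
    assert read.aligned_length == 20


def test_deletion_and_clip_cigar_blocks(tmp_path):
    """Deletions consume reference within one block; soft clips consume none."""
    sam = _write_sam(
        tmp_path / "a.sam",
        [
            f"r1\t0\tchr1\t11\t60\t3S10M2D5M\t*\t0\t0\t{'A' * 18}\t{'I' * 18}"
            f"\tMD:Z:10^CA5"
        ],
    )
    (read,) = list(bc.iterate_alignments(sam))
    assert read.blocks == ((10, 27),)       # 10M + 2D + 5M, one covered block
    assert read.match_blocks == ((10, 20), (22, 27))
    assert read.aligned_length == 17


def test_blocks_agree_with_independent_pileup(tmp_path):
    """Our block-derived depth equals samtools-style pileup depth (pysam)."""
    recs = [
        f"r1\t0\tchr1\t5\t60\t10M4N6M\t*\t0\t0\t{'A' * 16}\t{'I' * 16}",
        f"r2\t16\tchr1\t8\t60\t12M\t*\t0\t0\t{'A' * 12}\t{'I' * 12}",
        f"r3\t0\tchr1\t10\t60\t5M3D5M\t*\t0\t0\t{'A' * 10}\t{'I' * 10}",
    ]
    sam = _write_sam(tmp_path / "a.sam", recs, chroms=(("chr1", 100),))
    ours = {}
    for read in bc.iterate_alignments(sam):
        for s, e in read.match_blocks:  # pileup counts query-bearing bases
            for p in range(s, e):
                ours[p] = ours.get(p, 0) + 1
    theirs = {}
    with pysam.AlignmentFile(str(sam)) as af:
        for col in af.pileup(min_base_quality=0):
            depth = sum(
                1
                for pr in col.pileups
                if not pr.is_del and not pr.is_refskip
            )
            if depth:
                theirs[col.reference_pos] = depth
    assert ours == theirs


def test_md_fallback_against_reference(tmp_path):
    """Without an MD tag, mismatches come from comparing SEQ to the FASTA."""
    fasta = tmp_path / "ref.fa"
    fasta.write_text(">chr1\n" + "ACGT" * 25 + "\n")
    ref = bc.read_reference(fasta)
    seq = list(ref.fetch("chr1", 10, 30))
    seq[5] = "T" if seq[5] != "T" else "G"   # one substitution at offset 5
    sam = _write_sam(
        tmp_path / "a.sam",
        [f"r1\t0\tchr1\t11\t60\t20M\t*\t0\t0\t{''.join(seq)}\t{'I' * 20}"],
        chroms=(("chr1", 100),),
    )
    (read,) = list(bc.iterate_alignments(sam, reference=ref))
    assert [(m.ref_offset, m.ref_base) for m in read.mismatches] == [(5, "ACGT"[15 % 4])]
    assert read.mismatches[0].read_base == seq[5]


def test_md_span_disagreement_drops_mismatch_info(tmp_path):
    sam = _write_sam(
        tmp_path / "a.sam",
        [f"r1\t0\tchr1\t1\t60\t20M\t*\t0\t0\t{'A' * 20}\t{'I' * 20}\tMD:Z:10A5"],
    )
    stats = bc.ProcessingStats()
    (read,) = list(bc.iterate_alignments(sam, stats=stats))
    assert read.mismatches == ()
    assert stats.dropped_mismatch_info == 1


def test_fixture_roundtrip_alignments(tmp_path):
    """Alignments written by the generator parse back with identical
    chrom/strand/blocks/mismatches, and MD span equals block length."""
    fx = bc.generate_fixture(bc.random_fixture_spec(11), tmp_path)
    stats = bc.ProcessingStats()
    reads = list(bc.iterate_alignments(fx.sam_path, stats=stats))
    assert stats.processed == fx.truth.n_reads == len(reads)
    assert sum(len(r.mismatches) for r in reads) == fx.truth.n_mismatches
    assert sum(r.aligned_length for r in reads) == fx.truth.aligned_bases


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------


def test_reference_lengths_and_accessor(tmp_path):
    fasta = tmp_path / "r.fa"
    fasta.write_text(">chrA\nACGT\n>chrB desc ignored\nacgtac\ngta\n")
    ref = bc.read_reference(fasta)
    assert ref.lengths == {"chrA": 4, "chrB": 9}
    assert ref.fetch("chrA", 1, 3) == "CG"
    assert ref.fetch("chrB", 0, 9) == "ACGTACGTA"  # wrapped + uppercased


def test_reference_duplicate_names_fatal(tmp_path):
    fasta = tmp_path / "r.fa"
    fasta.write_text(">chrA\nACGT\n>chrA\nACGT\n")
    with pytest.raises(InputError):
        bc.read_reference(fasta)


def test_reference_empty_fatal(tmp_path):
    fasta = tmp_path / "r.fa"
    fasta.write_text("")
    with pytest.raises(InputError):
        bc.read_reference(fasta)


# --------------------------------------------------------------------------
# GTF gene index
# --------------------------------------------------------------------------


def test_gene_span_is_min_max_over_features(tmp_path):
    gtf = tmp_path / "g.gtf"
    attrs = 'gene_id "g1"; gene_name "Nop58";'
    gtf.write_text(
        f"chr1\tx\texon\t100\t200\t.\t+\t.\t{attrs}\n"
        f"chr1\tx\texon\t400\t500\t.\t+\t.\t{attrs}\n"
    )
    index = bc.build_gene_index(gtf)
    (rec,) = index.records
    assert (rec.start, rec.end) == (100, 500)
    assert index.lookup("nop58") is rec  # case-insensitive
    assert index.lookup("NOP58") is rec


def test_empty_gtf_gives_empty_index(tmp_path):
    gtf = tmp_path / "g.gtf"
    gtf.write_text("")
    assert len(bc.build_gene_index(gtf)) == 0


def test_lines_without_gene_id_skipped(tmp_path):
    gtf = tmp_path / "g.gtf"
    gtf.write_text(
        'chr1\tx\texon\t1\t10\t.\t+\t.\ttranscript_id "t1";\n'
        'chr1\tx\texon\t5\t20\t.\t+\t.\tgene_id "g1";\n'
    )
    index = bc.build_gene_index(gtf)
    assert [r.gene_id for r in index.records] == ["g1"]


def test_fixture_gene_index_matches_truth(tmp_path):
    fx = bc.generate_fixture(bc.random_fixture_spec(7), tmp_path)
    index = bc.build_gene_index(fx.gtf_path)
    got = {r.gene_id: r for r in index.records}
    assert set(got) == {r.gene_id for r in fx.truth.genes}
    for want in fx.truth.genes:
        rec = got[want.gene_id]
        assert (rec.chrom, rec.start, rec.end, rec.strand) == (
            want.chrom,
            want.start,
            want.end,
            want.strand,
        )
        assert set(want.names) <= set(rec.names)
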