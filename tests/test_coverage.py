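"""Difference-array coverage construction against the naive per-base oracle."""

import numpy as np
import pytest

import basecov as bc
from basecov.errors import InternalConsistencyError, ReferenceMismatchError
from conftest import assert_tracks_equal, naive_tracks_from_alignments


def _read(chrom="chr1", start0=0, blocks=None, strand="+", mismatches=()):
    blocks = tuple(blocks or ((start0, start0 + 3),))
    return bc.ReadAlignment(
        chrom=chrom,
        start=blocks[0][0] + 1,
        strand=strand,
        blocks=blocks,
        match_blocks=blocks,
        mismatches=tuple(mismatches),
    )


def test_add_read_single_block():
    diff = bc.DiffArray.zeros("chr1", 10)
    bc.add_read(diff, _read(blocks=[(0, 3)]))
    assert list(diff.values) == [1, 0, 0, -1, 0, 0, 0, 0, 0, 0, 0]


def test_add_read_linearity():
    diff = bc.DiffArray.zeros("chr1", 10)
    for _ in range(2):
        bc.add_read(diff, _read(blocks=[(2, 7)]))
    assert diff.values[2] == 2 and diff.values[7] == -2


def test_add_read_touches_two_cells_per_block_regardless_of_length():
    """O(1) per block: the number of modified cells never depends on l."""
    for length in (3, 50, 5000):
        diff = bc.DiffArray.zeros("chr1", 10000)
        bc.add_read(diff, _read(blocks=[(10, 10 + length)]))
        assert int(np.count_nonzero(diff.values)) == 2


def test_add_read_out_of_bounds_rejected():
    diff = bc.DiffArray.zeros("chr1", 10)
    with pytest.raises(ValueError, match="outside"):
        bc.add_read(diff, _read(blocks=[(8, 12)]))


def test_accumulate_prefix_sum():
    diff = bc.DiffArray("chr1", np.array([1, 0, 0, -1, 0], dtype=np.int64))
    assert list(bc.accumulate(diff)) == [1, 1, 1, 0]


def test_accumulate_all_zero():
    diff = bc.DiffArray.zeros("chr1", 5)
    assert list(bc.accumulate(diff)) == [0] * 5


def test_accumulate_negative_prefix_is_fatal():
    diff = bc.DiffArray("chr1", np.array([-1, 1, 0], dtype=np.int64))
    with pytest.raises(InternalConsistencyError):
        bc.accumulate(diff)


def test_length_l_read_covers_exactly_l_positions():
    """A read of length l covers l positions, pinning the fencepost choice."""
    for l in (1, 2, 75):
        diff = bc.DiffArray.zeros("chr1", 200)
        bc.add_read(diff, _read(blocks=[(50, 50 + l)]))
        cov = bc.accumulate(diff)
        assert int(cov.sum()) == l
        assert list(np.flatnonzero(cov)) == list(range(50, 50 + l))


def test_diff_vs_naive_oracle_random_reads():
    """500 random reads on 10 kb: diff-array coverage equals the naive loop."""
    rng = np.random.default_rng(42)
    g = 10000
    reads = []
    for _ in range(500):
        s = int(rng.integers(0, g - 200))
        l = int(rng.integers(1, 150))
        reads.append(
            _read(blocks=[(s, s + l)], strand="+" if rng.random() < 0.5 else "-")
        )
    diff_p = bc.DiffArray.zeros("chr1", g)
    diff_n = bc.DiffArray.zeros("chr1", g)
    for r in reads:
        bc.add_read(diff_p if r.strand == "+" else diff_n, r)
    pos, neg = bc.accumulate(diff_p), bc.accumulate(diff_n)
    naive = naive_tracks_from_alignments(reads, {"chr1": g})["chr1"]
    np.testing.assert_array_equal(pos, naive.pos_strand)
    np.testing.assert_array_equal(neg, naive.neg_strand)
    np.testing.assert_array_equal(pos + neg, naive.total)


def test_count_mismatches_worked_example():
    """75 bp read at start 0 with descriptor 59A15: only position 59 counted."""
    tracks = bc.BaseTrackSet.zeros("chr1", 100)
    md, span = bc.parse_mismatch_descriptor("59A15")
    read = _read(
        blocks=[(0, span)], mismatches=[bc.Mismatch(off, b) for off, b in md]
    )
    bc.count_mismatches([read], tracks)
    assert tracks.mismatch_count[59] == 1
    assert int(tracks.mismatch_count.sum()) == 1


def test_count_mismatches_through_spliced_blocks():
    tracks = bc.BaseTrackSet.zeros("chr1", 100)
    read = _read(
        blocks=[(10, 20), (40, 50)], mismatches=[bc.Mismatch(15, "G")]
    )
    bc.count_mismatches([read], tracks)
    assert tracks.mismatch_count[45] == 1  # offset 15 -> 5 into second block


def test_mismatch_rate_values():
    rate = bc.mismatch_rate(
        np.array([1, 0, 3], dtype="<u4"), np.array([4, 0, 3], dtype="<u4")
    )
    assert rate.dtype == np.dtype("<f4")
    assert list(rate) == [25.0, 0.0, 100.0]


def test_mismatch_rate_matches_scalar_loop():
    rng = np.random.default_rng(3)
    total = rng.integers(0, 30, 500).astype("<u4")
    mis = (total * rng.random(500)).astype("<u4")
    rate = bc.mismatch_rate(mis, total)
    for p in range(500):
        want = 100.0 * int(mis[p]) / int(total[p]) if total[p] else 0.0
        assert rate[p] == pytest.approx(want, rel=1e-6)


# --------------------------------------------------------------------------
# build_base_tracks end to end
# --------------------------------------------------------------------------


def test_empty_sam_gives_zero_tracks_for_every_chromosome(tmp_path):
    fasta = tmp_path / "r.fa"
    fasta.write_text(">cA\n" + "A" * 50 + "\n>cB\n" + "C" * 30 + "\n")
    sam = tmp_path / "a.sam"
    sam.write_text("@HD\tVN:1.6\n@SQ\tSN:cA\tLN:50\n@SQ\tSN:cB\tLN:30\n")
    tracks, stats = bc.build_base_tracks(sam, bc.read_reference(fasta))
    assert set(tracks) == {"cA", "cB"}
    for ts in tracks.values():
        assert int(ts.total.sum()) == 0
        assert int(ts.mismatch_count.sum()) == 0
    assert stats.processed == 0


def test_strand_split_at_overlap(tmp_path):
    fasta = tmp_path / "r.fa"
    fasta.write_text(">c\n" + "A" * 100 + "\n")
    sam = tmp_path / "a.sam"
    sam.write_text(
        "@HD\tVN:1.6\n@SQ\tSN:c\tLN:100\n"
        f"r1\t0\tc\t10\t60\t20M\t*\t0\t0\t{'A' * 20}\t{'I' * 20}\tMD:Z:20\n"
        f"r2\t16\tc\t20\t60\t20M\t*\t0\t0\t{'A' * 20}\t{'I' * 20}\tMD:Z:20\n"
    )
    tracks, _ = bc.build_base_tracks(sam, bc.read_reference(fasta))
    ts = tracks["c"]
    p = 24  # covered by both reads
    assert (ts.total[p], ts.pos_strand[p], ts.neg_strand[p]) == (2, 1, 1)


def test_sam_chromosome_missing_from_fasta_is_fatal(tmp_path):
    fasta = tmp_path / "r.fa"
    fasta.write_text(">cA\n" + "A" * 50 + "\n")
    sam = tmp_path / "a.sam"
    sam.write_text(
        "@HD\tVN:1.6\n@SQ\tSN:cB\tLN:50\n"
        f"r1\t0\tcB\t1\t60\t5M\t*\t0\t0\tAAAAA\tIIIII\n"
    )
    with pytest.raises(ReferenceMismatchError, match="cB"):
        bc.build_base_tracks(sam, bc.read_reference(fasta))


def test_fixture_tracks_match_naive_oracle(tmp_path):
    """Every track of a ~2000-read fixture equals the generator's naive truth."""
    spec = bc.random_fixture_spec(99, n_chroms=2, max_length=8000, max_depth=8)
    fx = bc.generate_fixture(spec, tmp_path)
    ref = bc.read_reference(fx.fasta_path)
    tracks, stats = bc.build_base_tracks(fx.sam_path, ref)
    assert stats.processed == fx.truth.n_reads
    for chrom, ts in tracks.items():
        assert_tracks_equal(ts, fx.truth.tracks[chrom])
        ts.validate()


def test_conservation_of_aligned_bases(tmp_path):
    fx = bc.generate_fixture(bc.random_fixture_spec(5), tmp_path)
    tracks, _ = bc.build_base_tracks(fx.sam_path, bc.read_reference(fx.fasta_path))
    total = sum(int(ts.total.sum()) for ts in tracks.values())
    assert total == fx.truth.aligned_bases


def test_read_order_independence(tmp_path):
    """Shuffling the SAM body yields bit-identical tracks."""
    fx = bc.generate_fixture(bc.random_fixture_spec(21), tmp_path)
    lines = fx.sam_path.read_text().splitlines()
    header = [l for l in lines if l.startswith("@")]
    body = [l for l in lines if not l.startswith("@")]
    rng = np.random.default_rng(0)
    shuffled = [body[i] for i in rng.permutation(len(body))]
    shuf_sam = fx.sam_path.parent / "shuffled.sam"
    shuf_sam.write_text("\n".join(header + shuffled) + "\n")
    ref = bc.read_reference(fx.fasta_path)
    a, _ = bc.build_base_tracks(fx.sam_path, ref)
    b, _ = bc.build_base_tracks(shuf_sam, ref)
    for chrom in a:
        assert_tracks_equal(a[chrom], b[chrom])
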