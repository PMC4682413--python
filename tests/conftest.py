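import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import basecov as bc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def demo(tmp_path_factory):
    """The bundled demo fixture, generated once per session."""
    return bc.demo_sample(tmp_path_factory.mktemp("demo_fixture"))


@pytest.fixture(scope="session")
def demo_store_dir(demo, tmp_path_factory):
    out = tmp_path_factory.mktemp("demo_store")
    bc.compile_sample(
        "demo", demo.sam_path, demo.fasta_path, demo.gtf_path, out
    )
    return out / "demo"


@pytest.fixture(scope="session")
def demo_store(demo_store_dir):
    store = bc.open_store(demo_store_dir)
    yield store
    store.close()


def naive_tracks_from_alignments(reads, lengths, reference=None):
    """Independent per-base oracle: O(r*l) loops over every covered base."""
    tracks = {
        name: bc.BaseTrackSet.zeros(name, g, composition=reference is not None)
        for name, g in lengths.items()
    }
    for r in reads:
        ts = tracks[r.chrom]
        arr = ts.pos_strand if r.strand == "+" else ts.neg_strand
        for s, e in r.blocks:
            for p in range(s, e):
                arr[p] += 1
                ts.total[p] += 1
        mismatch_at = {}
        for m in r.mismatches:
            off = m.ref_offset
            for s, e in r.blocks:
                if off < e - s:
                    ts.mismatch_count[s + off] += 1
                    if m.read_base:
                        mismatch_at[s + off] = m.read_base
                    break
                off -= e - s
        if reference is not None:
            for s, e in r.match_blocks:
                seq = reference.fetch(r.chrom, s, e)
                for i, p in enumerate(range(s, e)):
                    base = mismatch_at.get(p, seq[i])
                    if base in "ACGT":
                        ts.composition[base][p] += 1
    return tracks


def assert_tracks_equal(got: bc.BaseTrackSet, want: bc.BaseTrackSet):
    for name in ("total", "pos_strand", "neg_strand", "mismatch_count"):
        np.testing.assert_array_equal(
            getattr(got, name), getattr(want, name), err_msg=f"{got.chrom}/{name}"
        )
    if got.composition is not None and want.composition is not None:
        for b in "ACGT":
            np.testing.assert_array_equal(
                got.composition[b],
                want.composition[b],
                err_msg=f"{got.chrom}/composition_{b}",
            )
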