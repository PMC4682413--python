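"""Difference-array construction of base-level coverage and mismatch tracks.

The classic pileup increments every covered position of every read, costing
O(r x l) for r reads of length l.  Here each read instead touches a
*difference array*: +1 at each covered block start, -1 one past the block
end — O(1) per block — and a single O(g) prefix sum over the g-base
chromosome turns the accumulated changes into the coverage curve, for O(r+g)
total.  Positive- and negative-strand reads go into separate difference
arrays; the total track is their elementwise sum.

Base-composition tracks (read-base counts per position) reuse the same
trick: a third difference array counts read-base-bearing depth (M/=/X
operations only), composition for base B is that depth wherever the
reference base is B, and sparse corrections at mismatch sites move one count
from the reference base to the substituted read base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .alignment_io import (
    ProcessingStats,
    ReadAlignment,
    ReferenceGenome,
    iterate_alignments,
)
from .errors import (
    InternalConsistencyError,
    ReferenceMismatchError,
    TrackOverflowError,
)

log = logging.getLogger(__name__)

COUNT_DTYPE = np.dtype("<u4")
RATE_DTYPE = np.dtype("<f4")
MAX_DEPTH = np.iinfo(np.uint32).max
COMPOSITION_BASES = "ACGT"


@dataclass
class DiffArray:
    """Coverage *changes*: values[p] is the net depth change entering p.

    Length is g+1 so a block ending at the chromosome end can place its -1
    one past the last base.  After all reads are added the entries sum to 0.
    """

    chrom: str
    values: np.ndarray  # int64, length g+1

    @classmethod
    def zeros(cls, chrom: str, length: int) -> "DiffArray":
        return cls(chrom, np.zeros(length + 1, dtype=np.int64))

    @property
    def length(self) -> int:
        return len(self.values) - 1


def add_read(diff: DiffArray, read: ReadAlignment) -> DiffArray:
    """Record one read: per covered block [s, e), +1 at s and -1 at e.

    Cost is O(1) per block regardless of block length.  Blocks outside
    [0, g) raise ValueError (callers skip and tally the read).
    """
    g = diff.length
    v = diff.values
    for s, e in read.blocks:
        if not (0 <= s < e <= g):
            raise ValueError(
                f"block [{s}, {e}) outside chromosome {diff.chrom} of length {g}"
            )
        v[s] += 1
        v[e] -= 1
    return diff


def add_blocks(diff: DiffArray, blocks: Iterable[tuple[int, int]]) -> None:
    """Same +1/-1 bookkeeping for an arbitrary block list (bounds-checked)."""
    g = diff.length
    v = diff.values
    for s, e in blocks:
        if not (0 <= s < e <= g):
            raise ValueError(f"block [{s}, {e}) outside [0, {g})")
        v[s] += 1
        v[e] -= 1


def accumulate(diff: DiffArray) -> np.ndarray:
    """Prefix-sum the difference array into the coverage curve.

    coverage[0] = diff[0]; coverage[p] = coverage[p-1] + diff[p].  One O(g)
    pass.  A negative running value means the difference array was malformed
    and is a fatal internal error, as is a depth beyond the 32-bit track
    width.
    """
    if int(diff.values.sum()) != 0:
        raise InternalConsistencyError(
            f"difference array for {diff.chrom} does not sum to zero"
        )
    cov = np.cumsum(diff.values[:-1], dtype=np.int64)
    if cov.size:
        lo, hi = int(cov.min()), int(cov.max())
        if lo < 0:
            raise InternalConsistencyError(
                f"negative coverage prefix on {diff.chrom} (malformed diff array)"
            )
        if hi > MAX_DEPTH:
            raise TrackOverflowError(
                f"depth {hi} on {diff.chrom} exceeds the 32-bit track limit"
            )
    return cov.astype(COUNT_DTYPE)


@dataclass
class BaseTrackSet:
    """Base-level tracks for one chromosome.

    total = pos_strand + neg_strand elementwise; mismatch_count[p] never
    exceeds total[p]; composition (optional) holds read-base counts per
    position for A/C/G/T.
    """

    chrom: str
    length: int
    total: np.ndarray
    pos_strand: np.ndarray
    neg_strand: np.ndarray
    mismatch_count: np.ndarray
    composition: dict[str, np.ndarray] | None = None

    @classmethod
    def zeros(cls, chrom: str, length: int, composition: bool = False) -> "BaseTrackSet":
        z = lambda: np.zeros(length, dtype=COUNT_DTYPE)  # noqa: E731
        comp = {b: z() for b in COMPOSITION_BASES} if composition else None
        return cls(chrom, length, z(), z(), z(), z(), comp)

    def validate(self) -> None:
        if not np.array_equal(
            self.total.astype(np.int64),
            self.pos_strand.astype(np.int64) + self.neg_strand.astype(np.int64),
        ):
            raise InternalConsistencyError(f"{self.chrom}: total != pos + neg")
        if np.any(self.mismatch_count > self.total):
            raise InternalConsistencyError(
                f"{self.chrom}: mismatch_count exceeds total depth"
            )


def mismatch_rate(mismatch_count: np.ndarray, total: np.ndarray) -> np.ndarray:
    """Percent mismatch per position: 100*mis/total, 0 where depth is 0."""
    if len(mismatch_count) != len(total):
        raise InternalConsistencyError("mismatch/total track length mismatch")
    rate = np.zeros(len(total), dtype=RATE_DTYPE)
    nz = total > 0
    rate[nz] = (100.0 * mismatch_count[nz] / total[nz]).astype(RATE_DTYPE)
    return rate


def genomic_position(blocks: tuple[tuple[int, int], ...], ref_offset: int) -> int | None:
    """Map a covered-block offset to its genomic position, or None if past
    the end of the alignment."""
    for s, e in blocks:
        if ref_offset < e - s:
            return s + ref_offset
        ref_offset -= e - s
    return None


def count_mismatches(
    reads: Iterable[ReadAlignment], tracks: BaseTrackSet
) -> BaseTrackSet:
    """Add each read's mismatches into the per-position mismatch track."""
    for read in reads:
        for m in read.mismatches:
            p = genomic_position(read.blocks, m.ref_offset)
            if p is None or not (0 <= p < tracks.length):
                log.warning(
                    "mismatch offset %d outside alignment on %s; ignored",
                    m.ref_offset,
                    read.chrom,
                )
                continue
            tracks.mismatch_count[p] += 1
    return tracks


@dataclass
class _ChromAccumulator:
    pos: DiffArray
    neg: DiffArray
    match: DiffArray | None
    mm_pos: list[int]
    mm_ref: list[str]
    mm_read: list[str]


def build_base_tracks(
    sam_path: str | Path,
    reference: ReferenceGenome,
    *,
    composition: bool = True,
    include_secondary: bool = True,
    stats: ProcessingStats | None = None,
) -> tuple[dict[str, BaseTrackSet], ProcessingStats]:
    """One streaming pass over a SAM file -> per-chromosome BaseTrackSets.

    Every FASTA chromosome gets a track set (all-zero when no reads map to
    it).  A SAM chromosome absent from the FASTA is fatal.  Reads with
    blocks outside the chromosome are skipped and tallied.
    """
    stats = stats if stats is not None else ProcessingStats()
    lengths = reference.lengths
    acc: dict[str, _ChromAccumulator] = {}

    def get_acc(chrom: str) -> _ChromAccumulator:
        a = acc.get(chrom)
        if a is None:
            g = lengths[chrom]
            a = acc[chrom] = _ChromAccumulator(
                pos=DiffArray.zeros(chrom, g),
                neg=DiffArray.zeros(chrom, g),
                match=DiffArray.zeros(chrom, g) if composition else None,
                mm_pos=[],
                mm_ref=[],
                mm_read=[],
            )
        return a

    for read in iterate_alignments(
        sam_path, reference=reference, include_secondary=include_secondary, stats=stats
    ):
        if read.chrom not in lengths:
            raise ReferenceMismatchError(
                f"alignments reference chromosome {read.chrom!r} "
                f"which is absent from the FASTA reference"
            )
        a = get_acc(read.chrom)
        try:
            add_read(a.pos if read.strand == "+" else a.neg, read)
        except ValueError as exc:
            stats.processed -= 1
            stats.skipped_error += 1
            stats.note(f"{read.chrom}:{read.start}: {exc}")
            continue
        if a.match is not None and read.match_blocks:
            add_blocks(a.match, read.match_blocks)
        for m in read.mismatches:
            p = genomic_position(read.blocks, m.ref_offset)
            if p is None:
                stats.dropped_mismatch_info += 1
                continue
            a.mm_pos.append(p)
            a.mm_ref.append(m.ref_base)
            a.mm_read.append(m.read_base if m.read_base else "?")

    out: dict[str, BaseTrackSet] = {}
    for chrom, g in lengths.items():
        a = acc.get(chrom)
        if a is None:
            out[chrom] = BaseTrackSet.zeros(chrom, g, composition=composition)
            continue
        pos = accumulate(a.pos)
        neg = accumulate(a.neg)
        total64 = pos.astype(np.int64) + neg.astype(np.int64)
        if total64.size and int(total64.max()) > MAX_DEPTH:
            raise TrackOverflowError(f"total depth overflow on {chrom}")
        total = total64.astype(COUNT_DTYPE)
        mm = np.bincount(
            np.asarray(a.mm_pos, dtype=np.int64), minlength=g
        ).astype(COUNT_DTYPE) if a.mm_pos else np.zeros(g, dtype=COUNT_DTYPE)
        comp = None
        if composition:
            comp = _composition_tracks(
                reference, chrom, a, stats
            )
        ts = BaseTrackSet(chrom, g, total, pos, neg, mm, comp)
        ts.validate()
        out[chrom] = ts
    return out, stats


def _composition_tracks(
    reference: ReferenceGenome,
    chrom: str,
    a: _ChromAccumulator,
    stats: ProcessingStats,
) -> dict[str, np.ndarray]:
    match_cov = accumulate(a.match).astype(np.int64)
    seq = np.frombuffer(reference.sequence(chrom).encode("ascii"), dtype="S1")
    mm_pos = np.asarray(a.mm_pos, dtype=np.int64)
    mm_ref = np.asarray(a.mm_ref, dtype="S1")
    mm_read = np.asarray(a.mm_read, dtype="S1")
    known = mm_read != b"?" if len(mm_pos) else np.zeros(0, dtype=bool)
    comp: dict[str, np.ndarray] = {}
    clipped = 0
    for base in COMPOSITION_BASES:
        b = base.encode("ascii")
        track = np.where(seq == b, match_cov, 0)
        if len(mm_pos):
            np.subtract.at(track, mm_pos[known & (mm_ref == b)], 1)
            np.add.at(track, mm_pos[known & (mm_read == b)], 1)
        neg = track < 0
        if np.any(neg):
            clipped += int(neg.sum())
            track[neg] = 0
        comp[base] = track.astype(COUNT_DTYPE)
    if clipped:
        stats.note(
            f"{chrom}: {clipped} composition cells clipped at zero "
            f"(MD tags inconsistent with the reference)"
        )
    return comp
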