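"""Reading and normalizing the three standard inputs: SAM, FASTA, GTF.

Alignments are normalized into :class:`ReadAlignment` records holding the
reference-consuming blocks (0-based half-open genomic intervals) and the
per-read mismatch list parsed from the MD tag.  Coordinate conventions:
everything internal is 0-based half-open; the 1-based SAM POS is kept on the
record as ``start`` for diagnostics, and user-facing query coordinates are
converted at the query-engine boundary.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import pysam
from pyfaidx import Fasta

from .errors import InputError, MismatchDescriptorError

log = logging.getLogger(__name__)

_MD_BASES = frozenset("ACGTN")

# CIGAR operation codes (pysam numeric encoding)
_OP_MATCH = frozenset((0, 7, 8))   # M, =, X : consume reference and query
_OP_DEL = 2                        # D      : consumes reference only, covered
_OP_SKIP = 3                       # N      : consumes reference, splits blocks
_OP_QUERY = frozenset((1, 4))      # I, S   : consume query only


class Mismatch(NamedTuple):
    """A substituted base within an aligned read.

    ``ref_offset`` is the 0-based offset from the alignment start measured in
    covered reference bases (i.e. along the concatenation of the read's
    blocks; skipped N-gaps do not count, deleted bases do, exactly as in the
    MD tag).  ``ref_base`` is the reference base at that position; the read
    base is carried when the record's SEQ field is available.
    """

    ref_offset: int
    ref_base: str
    read_base: str | None = None


@dataclass(frozen=True)
class ReadAlignment:
    """One mapped read, normalized.

    blocks: reference intervals [s, e) actually covered by the read
        (match/mismatch and deletion operations; N-skips split blocks).
    match_blocks: the subset of covered intervals where a read base exists
        (M/=/X only) — used for base-composition tracks.
    """

    chrom: str
    start: int                       # 1-based POS as in the SAM line
    strand: str                      # '+' or '-'
    blocks: tuple[tuple[int, int], ...]
    match_blocks: tuple[tuple[int, int], ...]
    mismatches: tuple[Mismatch, ...] = ()

    @property
    def aligned_length(self) -> int:
        """Total reference bases consumed (sum of block lengths)."""
        return sum(e - s for s, e in self.blocks)


@dataclass
class ProcessingStats:
    """Tally of what happened while streaming a SAM file."""

    processed: int = 0
    skipped_unmapped: int = 0
    skipped_secondary: int = 0
    skipped_error: int = 0
    dropped_mismatch_info: int = 0
    messages: list[str] = field(default_factory=list)

    def note(self, msg: str, cap: int = 50) -> None:
        if len(self.messages) < cap:
            self.messages.append(msg)

    @property
    def skipped(self) -> int:
        return self.skipped_unmapped + self.skipped_secondary + self.skipped_error


def parse_mismatch_descriptor(md: str) -> tuple[list[tuple[int, str]], int]:
    """Parse an MD mismatch-descriptor string such as ``"59A15"``.

    Returns ``(mismatches, implied_span)`` where each mismatch is
    ``(ref_offset, ref_base)`` with a 0-based offset from the alignment start
    (counting deleted bases, which appear in ``^``-groups), and
    ``implied_span`` is the total number of reference bases the descriptor
    accounts for.  ``"59A15"`` parses to ``([(59, 'A')], 75)`` — i.e. the
    60th 1-based position of a 75 bp read is a mismatch.

    Raises :class:`MismatchDescriptorError` naming the offending character
    position for strings outside the grammar
    ``number ((base | '^' base+) number)*``.
    """

    def fail(pos: int, what: str) -> None:
        raise MismatchDescriptorError(
            f"invalid mismatch descriptor {md!r}: {what} at position {pos}"
        )

    mismatches: list[tuple[int, str]] = []
    span = 0
    i, n = 0, len(md)
    while True:
        j = i
        while j < n and md[j].isdigit():
            j += 1
        if j == i:
            fail(i, "expected a match-run length")
        span += int(md[i:j])
        i = j
        if i == n:
            break
        c = md[i]
        if c in _MD_BASES:
            mismatches.append((span, c))
            span += 1
            i += 1
        elif c == "^":
            i += 1
            s = i
            while i < n and md[i] in _MD_BASES:
                i += 1
            if i == s:
                fail(i, "expected deleted bases after '^'")
            span += i - s
        else:
            fail(i, f"unexpected character {c!r}")
    return mismatches, span


def _walk_cigar(
    pos0: int, cigartuples: list[tuple[int, int]]
) -> tuple[
    list[tuple[int, int]],
    list[tuple[int, int]],
    list[tuple[int, int, int]],
]:
    """Derive (blocks, match_blocks, match_segments) from a CIGAR.

    match_segments are ``(block_offset_start, length, query_start)`` triples
    in covered-block coordinates, used to map MD offsets to query bases.
    """
    blocks: list[tuple[int, int]] = []
    match_blocks: list[tuple[int, int]] = []
    segs: list[tuple[int, int, int]] = []
    cur_start = g = pos0
    q = boff = 0
    for op, ln in cigartuples:
        if op in _OP_MATCH:
            if match_blocks and match_blocks[-1][1] == g:
                match_blocks[-1] = (match_blocks[-1][0], g + ln)
            else:
                match_blocks.append((g, g + ln))
            segs.append((boff, ln, q))
            g += ln
            q += ln
            boff += ln
        elif op == _OP_DEL:
            g += ln
            boff += ln
        elif op == _OP_SKIP:
            if g > cur_start:
                blocks.append((cur_start, g))
            g += ln
            cur_start = g
        elif op in _OP_QUERY:
            q += ln
        # H (5) and P (6) consume nothing relevant
    if g > cur_start:
        blocks.append((cur_start, g))
    return blocks, match_blocks, segs


def _read_base_at(
    segs: list[tuple[int, int, int]], seq: str | None, ref_offset: int
) -> str | None:
    """Query base at a covered-block offset, or None if no base (deletion)."""
    if seq is None or not segs:
        return None
    starts = [s[0] for s in segs]
    k = bisect_right(starts, ref_offset) - 1
    if k < 0:
        return None
    boff, ln, q = segs[k]
    if ref_offset < boff + ln:
        return seq[q + (ref_offset - boff)]
    return None


def _mismatches_from_reference(
    rec: pysam.AlignedSegment,
    reference: "ReferenceGenome",
    blocks: list[tuple[int, int]],
) -> list[Mismatch]:
    """Fallback when no MD tag is present: compare SEQ to the FASTA."""
    seq = rec.query_sequence
    if not seq:
        return []
    # covered-block offset of each block start
    cum = []
    acc = 0
    for s, e in blocks:
        cum.append((s, e, acc))
        acc += e - s
    out: list[Mismatch] = []
    for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
        rb = reference.fetch(rec.reference_name, rpos, rpos + 1)
        qb = seq[qpos].upper()
        if qb != rb:
            for s, e, off in cum:
                if s <= rpos < e:
                    out.append(Mismatch(off + (rpos - s), rb, qb))
                    break
    return out


def iterate_alignments(
    sam_path: str | Path,
    reference: "ReferenceGenome | None" = None,
    include_secondary: bool = True,
    stats: ProcessingStats | None = None,
) -> Iterator[ReadAlignment]:
    """Stream mapped reads from a SAM (or BAM) file as ReadAlignments.

    Unmapped records are skipped and tallied.  Mismatches come from the MD
    tag when present; otherwise, when ``reference`` is given, from comparing
    the read sequence against the FASTA over the aligned pairs; otherwise the
    read carries no mismatch information.  Records whose MD implied span
    disagrees with the CIGAR-covered length keep their coverage but drop
    their mismatch list (tallied in ``stats.dropped_mismatch_info``).
    """
    stats = stats if stats is not None else ProcessingStats()
    try:
        sam = pysam.AlignmentFile(str(sam_path), "r", check_sq=False)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read alignments from {sam_path}: {exc}") from exc
    with sam:
        try:
            for idx, rec in enumerate(sam):
                if rec.is_unmapped or rec.reference_name is None:
                    stats.skipped_unmapped += 1
                    continue
                if not include_secondary and (rec.is_secondary or rec.is_supplementary):
                    stats.skipped_secondary += 1
                    continue
                ct = rec.cigartuples
                if not ct:
                    stats.skipped_error += 1
                    stats.note(f"record {idx} ({rec.query_name}): missing CIGAR")
                    continue
                blocks, match_blocks, segs = _walk_cigar(rec.reference_start, ct)
                if not blocks:
                    stats.skipped_error += 1
                    stats.note(
                        f"record {idx} ({rec.query_name}): CIGAR consumes no reference"
                    )
                    continue
                covered = sum(e - s for s, e in blocks)
                mism: list[Mismatch] = []
                if rec.has_tag("MD"):
                    try:
                        pairs, span = parse_mismatch_descriptor(str(rec.get_tag("MD")))
                    except MismatchDescriptorError as exc:
                        stats.dropped_mismatch_info += 1
                        stats.note(f"record {idx} ({rec.query_name}): {exc}")
                        pairs, span = [], covered
                    if span != covered:
                        stats.dropped_mismatch_info += 1
                        stats.note(
                            f"record {idx} ({rec.query_name}): MD span {span} "
                            f"!= aligned length {covered}; mismatch info dropped"
                        )
                    else:
                        seq = rec.query_sequence
                        mism = [
                            Mismatch(off, base, _read_base_at(segs, seq, off))
                            for off, base in pairs
                        ]
                elif reference is not None and rec.reference_name in reference:
                    mism = _mismatches_from_reference(rec, reference, blocks)
                stats.processed += 1
                yield ReadAlignment(
                    chrom=rec.reference_name,
                    start=rec.reference_start + 1,
                    strand="-" if rec.is_reverse else "+",
                    blocks=tuple(blocks),
                    match_blocks=tuple(match_blocks),
                    mismatches=tuple(mism),
                )
        except (OSError, ValueError) as exc:
            raise InputError(f"malformed alignment record in {sam_path}: {exc}") from exc


class ReferenceGenome:
    """A FASTA reference with exact lengths and uppercase random access."""

    def __init__(self, fasta_path: str | Path):
        self.path = Path(fasta_path)
        try:
            self._fa = Fasta(
                str(fasta_path), as_raw=True, sequence_always_upper=True
            )
        except Exception as exc:  # pyfaidx raises assorted types
            raise InputError(f"cannot index FASTA {fasta_path}: {exc}") from exc
        if len(self._fa.keys()) == 0:
            raise InputError(f"FASTA {fasta_path} contains no sequences")
        self.lengths: dict[str, int] = {
            name: len(self._fa[name]) for name in self._fa.keys()
        }

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        """Uppercase bases over a 0-based half-open range."""
        return str(self._fa[chrom][start0:end0])

    def sequence(self, chrom: str) -> str:
        return str(self._fa[chrom][:])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def close(self) -> None:
        self._fa.close()


def read_reference(fasta_path: str | Path) -> ReferenceGenome:
    """Open a FASTA reference (duplicate sequence names are fatal)."""
    return ReferenceGenome(fasta_path)


@dataclass(frozen=True)
class GeneRecord:
    """One gene: full feature span plus every name it can be found under."""

    gene_id: str
    names: tuple[str, ...]
    chrom: str
    start: int   # 1-based inclusive
    end: int     # 1-based inclusive
    strand: str

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "names": list(self.names),
            "chrom": self.chrom,
            "start": self.start,
            "end": self.end,
            "strand": self.strand,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneRecord":
        return cls(
            gene_id=d["gene_id"],
            names=tuple(d["names"]),
            chrom=d["chrom"],
            start=int(d["start"]),
            end=int(d["end"]),
            strand=d["strand"],
        )


class GeneIndex:
    """Case-insensitive name/alias lookup over GeneRecords."""

    def __init__(self, records: list[GeneRecord]):
        self.records = list(records)
        self._by_name: dict[str, GeneRecord] = {}
        for rec in self.records:
            for name in rec.names:
                self._by_name.setdefault(name.lower(), rec)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def all_names(self) -> list[str]:
        return sorted({n for rec in self.records for n in rec.names})

    def lookup(self, name: str) -> GeneRecord | None:
        return self._by_name.get(name.lower())

    def complete(self, prefix: str, limit: int = 20) -> list[str]:
        p = prefix.lower()
        hits = [n for n in self.all_names if n.lower().startswith(p)]
        return hits[:limit]

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneRecord]:
        """Genes overlapping a 1-based inclusive range, sorted by start."""
        out = [
            r
            for r in self.records
            if r.chrom == chrom and r.start <= end and r.end >= start
        ]
        out.sort(key=lambda r: (r.start, r.end, r.gene_id))
        return out

    def to_json(self) -> list[dict]:
        return [r.to_dict() for r in self.records]

    @classmethod
    def from_json(cls, data: list[dict]) -> "GeneIndex":
        return cls([GeneRecord.from_dict(d) for d in data])


def build_gene_index(gtf_path: str | Path) -> GeneIndex:
    """Aggregate a GTF into one GeneRecord per gene_id.

    The record span is the min/max over all of the gene's feature lines;
    names collect gene_id, gene_name, and any alias-like attribute
    (``*alias*`` or ``gene_synonym``).  Lines without gene_id are skipped
    with a warning.
    """
    from gffutils.iterators import DataIterator

    path = Path(gtf_path)
    if not path.exists():
        raise InputError(f"GTF file not found: {gtf_path}")
    agg: dict[str, dict] = {}
    skipped = 0
    try:
        if path.stat().st_size > 0:
            for feat in DataIterator(str(path)):
                attrs = feat.attributes
                gids = attrs.get("gene_id") if attrs else None
                if not gids:
                    skipped += 1
                    continue
                gid = gids[0]
                entry = agg.get(gid)
                if entry is None:
                    entry = agg[gid] = {
                        "chrom": feat.seqid,
                        "start": feat.start,
                        "end": feat.end,
                        "strand": feat.strand if feat.strand in "+-" else "+",
                        "names": {gid},
                    }
                else:
                    entry["start"] = min(entry["start"], feat.start)
                    entry["end"] = max(entry["end"], feat.end)
                for key in attrs.keys():
                    lk = key.lower()
                    if lk == "gene_name" or "alias" in lk or lk == "gene_synonym":
                        entry["names"].update(attrs[key])
    except InputError:
        raise
    except Exception as exc:
        raise InputError(f"cannot parse GTF {gtf_path}: {exc}") from exc
    if skipped:
        log.warning("%d GTF lines without gene_id skipped", skipped)
    records = [
        GeneRecord(
            gene_id=gid,
            names=tuple(sorted(e["names"])),
            chrom=e["chrom"],
            start=int(e["start"]),
            end=int(e["end"]),
            strand=e["strand"],
        )
        for gid, e in sorted(agg.items())
    ]
    return GeneIndex(records)
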