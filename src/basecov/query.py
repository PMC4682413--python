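"""Region and gene queries against a compiled store.

The engine resolves a user region (coordinates with auto-swap and clamping,
or a gene name resolved case-insensitively against the compiled index),
picks the pyramid level whose bin count over the range stays within the
point budget, fetches only the needed byte range from the store, and — when
the level's bins still exceed the caller's ``max_points`` (a screen width,
typically) — max-pools on the fly.  Because every aggregation step is a
maximum, every returned value equals the maximum base-level value over its
reported genomic span, at any zoom.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np

from .alignment_io import GeneIndex, GeneRecord
from .coverage import COMPOSITION_BASES, mismatch_rate
from .errors import (
    GeneIndexMissingError,
    QueryError,
    UnknownChromosomeError,
    UnknownGeneError,
)
from .pyramid import RATE_TRACK, select_level, window_max
from .store import Store

DEFAULT_MAX_POINTS = 20000
DEFAULT_COMPOSITION_THRESHOLD = 500

_POINT_TRACKS = ("total", "pos_strand", "neg_strand", "mis_rate")


@dataclass(frozen=True)
class RegionQuery:
    """A user request: coordinates or a gene name, plus a point budget."""

    sample_id: str
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    gene: str | None = None
    max_points: int = DEFAULT_MAX_POINTS


class PointRecord(NamedTuple):
    span_start: int   # 1-based inclusive
    span_end: int     # 1-based inclusive
    total: int
    pos_strand: int
    neg_strand: int
    mis_rate: float
    composition: dict[str, int] | None


@dataclass
class QueryResult:
    """Resolved region, level used, and column-oriented point arrays.

    Spans are bin-aligned: each point's span is the full genomic extent of
    its bin (or pooled bin group), clipped to the chromosome, so the first
    and last spans may extend slightly past the requested edges.  Every
    value equals the base-level maximum over its span.
    """

    chrom: str
    start: int
    end: int
    level_used: int
    bin_width: int
    span_start: np.ndarray
    span_end: np.ndarray
    total: np.ndarray
    pos_strand: np.ndarray
    neg_strand: np.ndarray
    mis_rate: np.ndarray
    composition: dict[str, np.ndarray] | None = None
    genes: tuple[GeneRecord, ...] = ()

    @property
    def n_points(self) -> int:
        return len(self.span_start)

    def records(self) -> Iterator[PointRecord]:
        comp = self.composition
        for i in range(self.n_points):
            yield PointRecord(
                int(self.span_start[i]),
                int(self.span_end[i]),
                int(self.total[i]),
                int(self.pos_strand[i]),
                int(self.neg_strand[i]),
                float(self.mis_rate[i]),
                {b: int(comp[b][i]) for b in COMPOSITION_BASES} if comp else None,
            )


def resolve_region(
    store: Store,
    chrom: str | None = None,
    start: int | None = None,
    end: int | None = None,
    gene: str | None = None,
) -> tuple[str, int, int]:
    """Resolve to (chrom, start, end), 1-based inclusive, within bounds.

    Coordinates: start/end are swapped when reversed and clamped to
    [1, chromosome length].  Gene names match any name or alias,
    case-insensitively, and resolve to the gene's full feature span.
    Idempotent: resolving an already-resolved region changes nothing.
    """
    if gene is not None:
        gi = store.gene_index
        if gi is None:
            raise GeneIndexMissingError(
                f"sample {store.sample_id!r} was compiled without a GTF; "
                f"gene queries are unavailable"
            )
        rec = gi.lookup(gene)
        if rec is None:
            suggestions = gi.complete(gene, 5) or difflib.get_close_matches(
                gene, gi.all_names, n=5
            )
            hint = f"; did you mean: {', '.join(suggestions)}?" if suggestions else ""
            raise UnknownGeneError(f"unknown gene {gene!r}{hint}")
        chrom, start, end = rec.chrom, rec.start, rec.end
    if chrom is None or start is None or end is None:
        raise QueryError("a query needs either chrom/start/end or a gene name")
    g = store.chrom_length(chrom)  # raises UnknownChromosomeError with names
    start, end = int(start), int(end)
    if start > end:
        start, end = end, start
    start = min(max(start, 1), g)
    end = min(max(end, 1), g)
    return chrom, start, end


def complete_gene(
    prefix: str, gene_index: GeneIndex | None, limit: int = 20
) -> list[str]:
    """Case-insensitive prefix completion over all gene names and aliases."""
    if gene_index is None:
        raise GeneIndexMissingError("no gene index compiled; cannot complete names")
    return gene_index.complete(prefix, limit)


def query_region(
    store: Store,
    chrom: str,
    start: int,
    end: int,
    max_points: int = DEFAULT_MAX_POINTS,
    composition_threshold: int = DEFAULT_COMPOSITION_THRESHOLD,
) -> QueryResult:
    """Fetch tracks over a resolved 1-based inclusive region.

    The pyramid level is the finest whose bins over the region fit the
    store's threshold; if the covered bin count still exceeds
    ``max_points``, adjacent bins are max-pooled.  %mis is computed from
    counts at level 0 and read from the stored rate track at deeper levels.
    Composition is attached only for unpooled base-level results narrower
    than ``composition_threshold``.
    """
    if max_points < 1:
        raise QueryError("max_points must be >= 1")
    c = store.chrom(chrom)
    g = c.length
    if not (1 <= start <= end <= g):
        raise QueryError(
            f"region {chrom}:{start}-{end} outside chromosome of length {g}"
        )
    width = end - start + 1
    m = store.manifest
    level = select_level(
        width, factor=m.factor, threshold=m.threshold, n_levels=len(c.levels)
    )
    bw = c.levels[level].bin_width
    bin_start = (start - 1) // bw
    bin_end = (end + bw - 1) // bw

    arrays: dict[str, np.ndarray] = {}
    for t in ("total", "pos_strand", "neg_strand"):
        arrays[t] = store.read_slice(chrom, level, bin_start, bin_end, t)
    mm = store.read_slice(chrom, level, bin_start, bin_end, "mismatch_count")
    if level == 0:
        arrays["mis_rate"] = mismatch_rate(mm, arrays["total"])
    else:
        arrays["mis_rate"] = store.read_slice(
            chrom, level, bin_start, bin_end, RATE_TRACK
        )

    n = bin_end - bin_start
    pool = -(-n // max_points)  # bins per returned point
    if pool > 1:
        for t in _POINT_TRACKS:
            arrays[t] = window_max(arrays[t], pool)
    starts_bin = np.arange(bin_start, bin_end, pool, dtype=np.int64)
    ends_bin = np.minimum(starts_bin + pool, bin_end)
    span_start = starts_bin * bw + 1
    span_end = np.minimum(ends_bin * bw, g)

    composition = None
    if (
        width < composition_threshold
        and level == 0
        and pool == 1
        and m.composition
    ):
        composition = {
            b: store.read_slice(
                chrom, 0, bin_start, bin_end, f"composition_{b}"
            )
            for b in COMPOSITION_BASES
        }

    gi = store.gene_index
    genes = tuple(gi.overlapping(chrom, start, end)) if gi is not None else ()

    return QueryResult(
        chrom=chrom,
        start=start,
        end=end,
        level_used=level,
        bin_width=bw,
        span_start=span_start,
        span_end=span_end,
        total=arrays["total"],
        pos_strand=arrays["pos_strand"],
        neg_strand=arrays["neg_strand"],
        mis_rate=arrays["mis_rate"],
        composition=composition,
        genes=genes,
    )


def query(store: Store, q: RegionQuery, **kwargs) -> QueryResult:
    """Resolve and execute a RegionQuery in one step."""
    chrom, start, end = resolve_region(
        store, chrom=q.chrom, start=q.start, end=q.end, gene=q.gene
    )
    return query_region(store, chrom, start, end, max_points=q.max_points, **kwargs)


TSV_COLUMNS = (
    "chrom",
    "start",
    "end",
    "total",
    "pos_strand",
    "neg_strand",
    "mis_rate_percent",
)


def export_region(
    result: QueryResult, format: str = "tsv", track: str = "total"
) -> list[str]:
    """Render a result as text lines.

    ``tsv``: header + one row per point, 1-based inclusive spans, all
    tracks (composition columns appended when present).  ``bedgraph``: one
    track per call (``track`` selects it), native 0-based half-open
    coordinates, with a track definition line.
    """
    if result.n_points == 0:
        raise QueryError("cannot export an empty result")
    if format == "tsv":
        cols = list(TSV_COLUMNS)
        comp = result.composition
        if comp is not None:
            cols += [f"comp_{b}" for b in COMPOSITION_BASES]
        lines = ["\t".join(cols)]
        for i in range(result.n_points):
            row = [
                result.chrom,
                str(int(result.span_start[i])),
                str(int(result.span_end[i])),
                str(int(result.total[i])),
                str(int(result.pos_strand[i])),
                str(int(result.neg_strand[i])),
                f"{float(result.mis_rate[i]):.9g}",
            ]
            if comp is not None:
                row += [str(int(comp[b][i])) for b in COMPOSITION_BASES]
            lines.append("\t".join(row))
        return lines
    if format == "bedgraph":
        valid = set(_POINT_TRACKS)
        if track not in valid:
            raise QueryError(f"unknown track {track!r}; choose from {sorted(valid)}")
        values = getattr(result, track)
        lines = [
            f'track type=bedGraph name="{track}" description='
            f'"{track} {result.chrom}:{result.start}-{result.end}"'
        ]
        is_rate = track == "mis_rate"
        for i in range(result.n_points):
            v = f"{float(values[i]):.9g}" if is_rate else str(int(values[i]))
            lines.append(
                f"{result.chrom}\t{int(result.span_start[i]) - 1}"
                f"\t{int(result.span_end[i])}\t{v}"
            )
        return lines
    raise QueryError(f"unknown export format {format!r} (expected tsv or bedgraph)")
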