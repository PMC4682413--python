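"""Multi-resolution profile pyramid.

Level 0 is the base-level profile (one point per base).  Each further level
bins the previous one by a constant factor (default 20) and keeps the
*maximum* of each window, so a bin at any level equals the maximum of the
base-level values over its genomic span (max composes).  Levels are added
until a level has at most ``threshold`` (default 20000) bins, which bounds
the number of points any single level hands to a viewer.  Total storage is
1 + 1/20 + 1/400 + ... ~ 1.05x the base level.

Count tracks aggregate as integer maxima.  The mismatch-rate track (%mis)
is aggregated as a real-valued max of the per-base rates, because a maximum
of counts cannot reconstruct a maximum rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coverage import BaseTrackSet, mismatch_rate

DEFAULT_FACTOR = 20
DEFAULT_THRESHOLD = 20000

COUNT_TRACKS = ("total", "pos_strand", "neg_strand", "mismatch_count")
RATE_TRACK = "mis_rate"
COMPOSITION_TRACKS = ("composition_A", "composition_C", "composition_G", "composition_T")


def window_max(values: np.ndarray, width: int) -> np.ndarray:
    """Non-overlapping window maximum; the last window may be partial.

    Padding with zeros is safe for the non-negative tracks used here: a
    partial window's max over its real children is unchanged.
    """
    if width < 1:
        raise ValueError("window width must be >= 1")
    n = len(values)
    if n == 0:
        return values.copy()
    n_bins = -(-n // width)
    pad = n_bins * width - n
    if pad:
        values = np.concatenate([values, np.zeros(pad, dtype=values.dtype)])
    return values.reshape(n_bins, width).max(axis=1)


@dataclass
class ProfileLevel:
    """One resolution level: per-track per-bin maxima at bin width factor^k."""

    level: int
    bin_width: int
    n_bins: int
    tracks: dict[str, np.ndarray]


@dataclass
class ProfilePyramid:
    chrom: str
    length: int
    factor: int
    threshold: int
    levels: list[ProfileLevel] = field(default_factory=list)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def select_level(self, range_width: int) -> int:
        return select_level(
            range_width,
            factor=self.factor,
            threshold=self.threshold,
            n_levels=self.n_levels,
        )


def build_pyramid(
    tracks: BaseTrackSet,
    factor: int = DEFAULT_FACTOR,
    threshold: int = DEFAULT_THRESHOLD,
) -> ProfilePyramid:
    """Build the max pyramid over a chromosome's base tracks.

    Level 0 reuses the BaseTrackSet arrays (composition included when
    present; %mis at level 0 is derived from the counts on demand).  Levels
    k >= 1 carry the four count maxima plus a real-valued mis_rate max, and
    are added while the previous level still exceeds ``threshold`` bins.
    """
    if factor < 2:
        raise ValueError("pyramid factor must be >= 2")
    if threshold < 1:
        raise ValueError("pyramid threshold must be >= 1")
    g = tracks.length
    level0: dict[str, np.ndarray] = {
        "total": tracks.total,
        "pos_strand": tracks.pos_strand,
        "neg_strand": tracks.neg_strand,
        "mismatch_count": tracks.mismatch_count,
    }
    if tracks.composition is not None:
        for base, arr in tracks.composition.items():
            level0[f"composition_{base}"] = arr
    pyr = ProfilePyramid(tracks.chrom, g, factor, threshold)
    pyr.levels.append(ProfileLevel(0, 1, g, level0))

    cur = {name: level0[name] for name in COUNT_TRACKS}
    cur_rate = mismatch_rate(tracks.mismatch_count, tracks.total)
    k = 0
    while pyr.levels[-1].n_bins > threshold:
        k += 1
        nxt = {name: window_max(arr, factor) for name, arr in cur.items()}
        nxt_rate = window_max(cur_rate, factor)
        level_tracks = dict(nxt)
        level_tracks[RATE_TRACK] = nxt_rate
        pyr.levels.append(
            ProfileLevel(k, factor**k, len(nxt_rate), level_tracks)
        )
        cur, cur_rate = nxt, nxt_rate
    return pyr


def select_level(
    range_width: int,
    *,
    factor: int = DEFAULT_FACTOR,
    threshold: int = DEFAULT_THRESHOLD,
    n_levels: int,
) -> int:
    """Smallest level whose bin count over the range stays within threshold.

    Level k serves widths up to threshold * factor^k: the base level covers
    ranges up to 20000 bp, level 1 up to 400000 bp, and so on; clamped to
    the deepest available level.
    """
    if range_width < 1:
        raise ValueError("range width must be >= 1")
    limit = threshold
    for k in range(n_levels):
        if range_width <= limit:
            return k
        limit *= factor
    return n_levels - 1


def storage_ratio(pyramid: ProfilePyramid) -> float:
    """Total stored points across levels relative to the base level."""
    base = pyramid.levels[0].n_bins
    return sum(lvl.n_bins for lvl in pyramid.levels) / base
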