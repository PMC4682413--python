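"""Binary random-access track store ("memory dump" layout).

A compiled sample is a directory: ``manifest.json`` plus one ``.rcv`` data
file per chromosome.  Each data file is an 8-byte magic and a little-endian
uint32 format version, followed by every level's tracks as contiguous
fixed-width little-endian arrays — exactly the in-memory representation, so
any bin range of any track is one ``seek`` + one ``read`` computed from the
manifest offsets, independent of file size.  Count tracks are uint32,
mismatch-rate tracks float32, matching the in-memory widths.

Writing is atomic (temp file + rename); a store survives process restarts
with no recomputation.
"""

from __future__ import annotations

import json
import os
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import BinaryIO

import numpy as np

from .alignment_io import GeneIndex
from .errors import (
    IncompatibleStoreError,
    SliceBoundsError,
    StoreError,
    StoreExistsError,
    UnknownChromosomeError,
    UnknownSampleError,
    UnknownTrackError,
)
from .pyramid import COMPOSITION_TRACKS, COUNT_TRACKS, RATE_TRACK, ProfilePyramid

MAGIC = b"BCOVTRK\x01"
FORMAT_VERSION = 1
_HEADER_SIZE = len(MAGIC) + 4

_DTYPES = {"<u4": np.dtype("<u4"), "<f4": np.dtype("<f4")}


def _track_dtype(name: str) -> str:
    return "<f4" if name == RATE_TRACK else "<u4"


@dataclass
class TrackLayout:
    offset: int
    dtype: str


@dataclass
class LevelLayout:
    level: int
    bin_width: int
    n_bins: int
    tracks: dict[str, TrackLayout]


@dataclass
class ChromLayout:
    name: str
    length: int
    data_file: str
    levels: list[LevelLayout]


@dataclass
class StoreManifest:
    """Self-describing metadata for a compiled sample."""

    format_version: int
    sample_id: str
    created: str
    factor: int
    threshold: int
    composition: bool
    chromosomes: list[ChromLayout] = field(default_factory=list)
    gene_index_path: str | None = None

    def to_dict(self) -> dict:
        return {
            "format_version": self.format_version,
            "sample_id": self.sample_id,
            "created": self.created,
            "factor": self.factor,
            "threshold": self.threshold,
            "composition": self.composition,
            "chromosomes": [
                {
                    "name": c.name,
                    "length": c.length,
                    "data_file": c.data_file,
                    "levels": [
                        {
                            "level": lv.level,
                            "bin_width": lv.bin_width,
                            "n_bins": lv.n_bins,
                            "tracks": {
                                t: {"offset": tl.offset, "dtype": tl.dtype}
                                for t, tl in lv.tracks.items()
                            },
                        }
                        for lv in c.levels
                    ],
                }
                for c in self.chromosomes
            ],
            "gene_index_path": self.gene_index_path,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StoreManifest":
        return cls(
            format_version=int(d["format_version"]),
            sample_id=d["sample_id"],
            created=d["created"],
            factor=int(d["factor"]),
            threshold=int(d["threshold"]),
            composition=bool(d["composition"]),
            chromosomes=[
                ChromLayout(
                    name=c["name"],
                    length=int(c["length"]),
                    data_file=c["data_file"],
                    levels=[
                        LevelLayout(
                            level=int(lv["level"]),
                            bin_width=int(lv["bin_width"]),
                            n_bins=int(lv["n_bins"]),
                            tracks={
                                t: TrackLayout(int(tl["offset"]), tl["dtype"])
                                for t, tl in lv["tracks"].items()
                            },
                        )
                        for lv in c["levels"]
                    ],
                )
                for c in d["chromosomes"]
            ],
            gene_index_path=d.get("gene_index_path"),
        )


def _safe_filename(index: int, chrom: str) -> str:
    return f"{index:04d}_{re.sub(r'[^A-Za-z0-9._-]', '_', chrom)}.rcv"


def _atomic_write(path: Path, payload: bytes) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "wb") as fh:
        fh.write(payload)
        fh.flush()
        os.fsync(fh.fileno())
    os.replace(tmp, path)


def _ordered_tracks(level: int, names: set[str]) -> list[str]:
    order = list(COUNT_TRACKS)
    if level >= 1:
        order.append(RATE_TRACK)
    else:
        order.extend(COMPOSITION_TRACKS)
    return [t for t in order if t in names]


def write_store(
    pyramids: dict[str, ProfilePyramid],
    sample_id: str,
    out_dir: str | Path,
    gene_index: GeneIndex | None = None,
    overwrite: bool = False,
) -> StoreManifest:
    """Serialize compiled pyramids into a store directory.

    Refuses to clobber an existing compiled sample unless ``overwrite``.
    """
    store_dir = Path(out_dir)
    manifest_path = store_dir / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise StoreExistsError(
            f"sample {sample_id!r} already compiled at {store_dir}; "
            f"pass overwrite to replace it"
        )
    store_dir.mkdir(parents=True, exist_ok=True)
    if not pyramids:
        raise StoreError("nothing to write: no chromosomes compiled")

    manifest = StoreManifest(
        format_version=FORMAT_VERSION,
        sample_id=sample_id,
        created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        factor=next(iter(pyramids.values())).factor,
        threshold=next(iter(pyramids.values())).threshold,
        composition=any(
            "composition_A" in p.levels[0].tracks for p in pyramids.values()
        ),
    )
    for i, (chrom, pyr) in enumerate(pyramids.items()):
        fname = _safe_filename(i, chrom)
        chunks: list[bytes] = [MAGIC, np.uint32(FORMAT_VERSION).tobytes()]
        offset = _HEADER_SIZE
        levels: list[LevelLayout] = []
        for lv in pyr.levels:
            layout: dict[str, TrackLayout] = {}
            for t in _ordered_tracks(lv.level, set(lv.tracks)):
                dtype = _track_dtype(t)
                data = np.ascontiguousarray(lv.tracks[t], dtype=_DTYPES[dtype])
                if len(data) != lv.n_bins:
                    raise StoreError(
                        f"{chrom} level {lv.level} track {t}: "
                        f"{len(data)} values for {lv.n_bins} bins"
                    )
                chunks.append(data.tobytes())
                layout[t] = TrackLayout(offset, dtype)
                offset += data.nbytes
            levels.append(LevelLayout(lv.level, lv.bin_width, lv.n_bins, layout))
        try:
            _atomic_write(store_dir / fname, b"".join(chunks))
        except OSError as exc:
            raise StoreError(f"cannot write {store_dir / fname}: {exc}") from exc
        manifest.chromosomes.append(ChromLayout(chrom, pyr.length, fname, levels))

    if gene_index is not None:
        _atomic_write(
            store_dir / "genes.json",
            json.dumps(gene_index.to_json(), indent=0).encode(),
        )
        manifest.gene_index_path = "genes.json"
    _atomic_write(
        manifest_path, json.dumps(manifest.to_dict(), indent=1).encode()
    )
    return manifest


class Store:
    """Random-access reader over a compiled sample directory."""

    def __init__(self, store_dir: str | Path, manifest: StoreManifest):
        self.dir = Path(store_dir)
        self.manifest = manifest
        self._chroms = {c.name: c for c in manifest.chromosomes}
        self._files: dict[str, BinaryIO] = {}
        self._gene_index: GeneIndex | None = None
        self._gene_index_loaded = False

    @classmethod
    def open(cls, store_dir: str | Path) -> "Store":
        store_dir = Path(store_dir)
        manifest_path = store_dir / "manifest.json"
        if not manifest_path.exists():
            raise UnknownSampleError(f"no compiled sample at {store_dir}")
        try:
            manifest = StoreManifest.from_dict(json.loads(manifest_path.read_text()))
        except (ValueError, KeyError) as exc:
            raise StoreError(f"corrupt manifest at {manifest_path}: {exc}") from exc
        if manifest.format_version != FORMAT_VERSION:
            raise IncompatibleStoreError(
                f"store format version {manifest.format_version} "
                f"(this build reads version {FORMAT_VERSION})"
            )
        return cls(store_dir, manifest)

    # -- introspection -------------------------------------------------
    @property
    def sample_id(self) -> str:
        return self.manifest.sample_id

    @property
    def chrom_names(self) -> list[str]:
        return [c.name for c in self.manifest.chromosomes]

    def chrom(self, name: str) -> ChromLayout:
        try:
            return self._chroms[name]
        except KeyError:
            raise UnknownChromosomeError(
                f"unknown chromosome {name!r}; valid names: "
                + ", ".join(self.chrom_names)
            ) from None

    def chrom_length(self, name: str) -> int:
        return self.chrom(name).length

    @property
    def gene_index(self) -> GeneIndex | None:
        if not self._gene_index_loaded:
            self._gene_index_loaded = True
            if self.manifest.gene_index_path:
                path = self.dir / self.manifest.gene_index_path
                self._gene_index = GeneIndex.from_json(json.loads(path.read_text()))
        return self._gene_index

    # -- data access ---------------------------------------------------
    def _file(self, chrom: ChromLayout) -> BinaryIO:
        fh = self._files.get(chrom.name)
        if fh is None:
            path = self.dir / chrom.data_file
            fh = open(path, "rb")
            header = fh.read(_HEADER_SIZE)
            if header[: len(MAGIC)] != MAGIC:
                fh.close()
                raise IncompatibleStoreError(f"{path}: bad magic, not a track file")
            version = int(np.frombuffer(header[len(MAGIC):], dtype="<u4")[0])
            if version != FORMAT_VERSION:
                fh.close()
                raise IncompatibleStoreError(
                    f"{path}: format version {version}, expected {FORMAT_VERSION}"
                )
            self._files[chrom.name] = fh
        return fh

    def read_slice(
        self, chrom: str, level: int, bin_start: int, bin_end: int, track: str
    ) -> np.ndarray:
        """Read bins [bin_start, bin_end) of one track at one level.

        Reads exactly the byte range computed from the manifest offsets —
        O(slice length), never O(file size).  Empty or out-of-range slices
        are errors.
        """
        c = self.chrom(chrom)
        if not (0 <= level < len(c.levels)):
            raise SliceBoundsError(
                f"{chrom}: level {level} out of range (0..{len(c.levels) - 1})"
            )
        lv = c.levels[level]
        if not (0 <= bin_start < bin_end <= lv.n_bins):
            raise SliceBoundsError(
                f"{chrom} level {level}: slice [{bin_start}, {bin_end}) "
                f"invalid for {lv.n_bins} bins"
            )
        tl = lv.tracks.get(track)
        if tl is None:
            raise UnknownTrackError(
                f"{chrom} level {level}: no track {track!r}; available: "
                + ", ".join(sorted(lv.tracks))
            )
        dtype = _DTYPES[tl.dtype]
        n = bin_end - bin_start
        fh = self._file(c)
        fh.seek(tl.offset + bin_start * dtype.itemsize)
        buf = fh.read(n * dtype.itemsize)
        if len(buf) != n * dtype.itemsize:
            raise StoreError(
                f"{chrom}: truncated read at level {level} track {track}"
            )
        return np.frombuffer(buf, dtype=dtype)

    def close(self) -> None:
        for fh in self._files.values():
            fh.close()
        self._files.clear()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def open_store(store_dir: str | Path) -> Store:
    return Store.open(store_dir)
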