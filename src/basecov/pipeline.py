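"""Compilation stage: SAM + FASTA (+ GTF) -> compiled track store.

This is the one-time, heavy half of the two-stage design.  Everything a
query will ever need — strand-separated coverage, mismatch counts and
rates, the max pyramid, the gene index — is computed here and written to
the store; the query stage never touches the raw inputs again.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .alignment_io import ProcessingStats, build_gene_index, read_reference
from .coverage import build_base_tracks
from .pyramid import DEFAULT_FACTOR, DEFAULT_THRESHOLD, build_pyramid
from .store import StoreManifest, write_store

log = logging.getLogger(__name__)


def compile_sample(
    sample_id: str,
    sam_path: str | Path,
    fasta_path: str | Path,
    gtf_path: str | Path | None = None,
    out_dir: str | Path = ".",
    *,
    composition: bool = True,
    include_secondary: bool = True,
    overwrite: bool = False,
    factor: int = DEFAULT_FACTOR,
    threshold: int = DEFAULT_THRESHOLD,
) -> tuple[StoreManifest, ProcessingStats]:
    """Run the full compilation stage for one sample.

    The store is written to ``out_dir / sample_id``.  Returns the manifest
    and the read-processing tally.
    """
    store_dir = Path(out_dir) / sample_id
    reference = read_reference(fasta_path)
    try:
        tracks, stats = build_base_tracks(
            sam_path,
            reference,
            composition=composition,
            include_secondary=include_secondary,
        )
    finally:
        reference.close()
    pyramids = {
        chrom: build_pyramid(ts, factor=factor, threshold=threshold)
        for chrom, ts in tracks.items()
    }
    gene_index = build_gene_index(gtf_path) if gtf_path is not None else None
    manifest = write_store(
        pyramids, sample_id, store_dir, gene_index=gene_index, overwrite=overwrite
    )
    log.info(
        "compiled %s: %d reads used, %d skipped, %d chromosomes",
        sample_id,
        stats.processed,
        stats.skipped,
        len(pyramids),
    )
    return manifest, stats
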