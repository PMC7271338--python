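"""Cross-sister intersection of non-parental blocks/alleles and gene mapping.

Non-parental blocks and variants private to one line are noise for the
purpose of explaining traits shared by the whole sibship; the signal is
what every sister carries. This module intersects non-parental window
sets and non-parental variant key sets across sister lines (a venn-style
strict intersection) and maps shared variants onto gene intervals from a
GFF3 annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from intervaltree import IntervalTree

from tetramosaic.blocks import BlockTrack, BlockType
from tetramosaic.markers import MarkerCall, Origin
from tetramosaic.vcfio import Key, VariantSite

__all__ = [
    "IntervalRecord",
    "read_gff3_genes",
    "shared_np_windows",
    "shared_np_variants",
    "variants_to_genes",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntervalRecord:
    """A genomic interval (gene model or QTL) with 1-based inclusive ends."""

    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    id: str
    category: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval {self.id}: start {self.start} > end {self.end}"
            )

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def read_gff3_genes(path: str | Path) -> list[IntervalRecord]:
    """Read ``gene`` features from a GFF3 file as 1-based inclusive spans."""
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = [
        IntervalRecord(f.seqid, f.start, f.end, f.id, category="gene")
        for f in db.features_of_type("gene")
    ]
    genes.sort(key=lambda g: (g.chrom, g.start, g.end, g.id))
    return genes


def shared_np_windows(tracks: Sequence[BlockTrack]) -> set[tuple[str, int]]:
    """Windows typed non-parental in every track.

    All tracks must share one scaffold (chromosome lengths and window
    size), otherwise window indices are not comparable.
    """
    if not tracks:
        raise ValueError("need at least one track")
    sig = tracks[0].scaffold_signature()
    for t in tracks[1:]:
        if t.scaffold_signature() != sig:
            raise ValueError(
                f"mismatched scaffolds: {t.sister!r} vs {tracks[0].sister!r}"
            )
    shared: set[tuple[str, int]] | None = None
    for t in tracks:
        np_wins = {
            (w.chrom, w.window_index)
            for w in t
            if w.block_type is BlockType.NON_PARENTAL
        }
        shared = np_wins if shared is None else shared & np_wins
    return shared or set()


def shared_np_variants(
    marker_streams: Mapping[str, Iterable[MarkerCall]],
) -> set[Key]:
    """Strict intersection over sisters of non-parental variant keys."""
    if not marker_streams:
        raise ValueError("need at least one sister's marker calls")
    shared: set[Key] | None = None
    for sister, stream in marker_streams.items():
        keys = {c.key for c in stream if c.origin is Origin.NON_PARENTAL}
        shared = keys if shared is None else shared & keys
    return shared or set()


def variants_to_genes(
    variants: Iterable[VariantSite],
    genes: Sequence[IntervalRecord],
    effect_filter: str | None = None,
) -> dict[str, int]:
    """Map variants onto gene intervals; returns gene id -> variant count.

    A gene is reported iff at least one (effect-filtered) variant position
    lies within its 1-based inclusive span. A variant inside two
    overlapping genes counts once per gene. Variants on chromosomes absent
    from the annotation are counted as intergenic and logged.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # half-open tree interval [start, end+1) covers the inclusive span
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.id)
    counts: dict[str, int] = {}
    intergenic = 0
    unknown_chrom = 0
    for v in variants:
        if effect_filter is not None and v.effect != effect_filter:
            continue
        tree = trees.get(v.chrom)
        if tree is None:
            unknown_chrom += 1
            continue
        hits = tree[v.pos]
        if not hits:
            intergenic += 1
            continue
        for hit in hits:
            counts[hit.data] = counts.get(hit.data, 0) + 1
    if unknown_chrom:
        log.info("%d variants on chromosomes absent from the annotation "
                 "(counted as intergenic)", unknown_chrom)
    if intergenic:
        log.info("%d variants outside all gene intervals", intergenic)
    return counts
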