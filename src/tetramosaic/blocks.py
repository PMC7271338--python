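"""Window-based chromosomal block typing.

Chromosomes are tiled with non-overlapping windows (default 10 kb — the
step equals the width, so the "sliding" windows do not overlap). Markers
are binned by position and each window is typed from its class tallies:

* fewer than ``min_markers`` informative markers -> ``no-data``;
* the majority class must be supported by at least ``support_threshold``
  (default 75%, inclusive) of the window's informative markers, else
  ``ambiguous``;
* ties for the majority -> ``ambiguous`` (no priority order is imposed);
* a non-parental majority additionally requires at least
  ``min_np_markers`` (default 5, i.e. more than four) non-parental
  markers, else ``ambiguous``.

Windows use 0-based half-open coordinates internally; BED output keeps
that convention.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from tetramosaic.markers import MarkerCall, Origin

__all__ = [
    "BlockType",
    "WindowBlock",
    "BlockTrack",
    "tile_windows",
    "type_window",
    "infer_track",
    "summarize_track",
    "merge_runs",
    "write_bed",
]

DEFAULT_WINDOW_SIZE = 10_000
DEFAULT_SUPPORT = 0.75
DEFAULT_MIN_MARKERS = 1
DEFAULT_MIN_NP_MARKERS = 5


class BlockType(enum.Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    NON_PARENTAL = "non-parental"
    AMBIGUOUS = "ambiguous"
    NO_DATA = "no-data"


@dataclass(frozen=True)
class WindowBlock:
    """One genomic window with marker tallies and an assigned block type."""

    chrom: str
    window_index: int
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    n_maternal: int = 0
    n_paternal: int = 0
    n_np: int = 0
    block_type: BlockType = BlockType.NO_DATA
    support: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def total_markers(self) -> int:
        return self.n_maternal + self.n_paternal + self.n_np


@dataclass
class BlockTrack:
    """Per-sister ordered window blocks tiling each chromosome."""

    sister: str
    chrom_lengths: dict[str, int]
    window_size: int
    windows: dict[str, list[WindowBlock]]

    def scaffold_signature(self) -> tuple:
        return (tuple(sorted(self.chrom_lengths.items())), self.window_size)

    def __iter__(self):
        for chrom in sorted(self.windows):
            yield from self.windows[chrom]


def tile_windows(
    chrom_lengths: Mapping[str, int],
    window_size: int = DEFAULT_WINDOW_SIZE,
    sister: str = "",
) -> BlockTrack:
    """Build an empty scaffold: ceil(length / window_size) windows per
    chromosome, the last one truncated to the chromosome end."""
    if window_size <= 0:
        raise ValueError(f"window_size must be positive, got {window_size}")
    windows: dict[str, list[WindowBlock]] = {}
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        n_win = -(-length // window_size)  # ceil
        windows[chrom] = [
            WindowBlock(
                chrom=chrom,
                window_index=i,
                start=i * window_size,
                end=min((i + 1) * window_size, length),
            )
            for i in range(n_win)
        ]
    return BlockTrack(sister, dict(chrom_lengths), window_size, windows)


def type_window(
    n_maternal: int,
    n_paternal: int,
    n_np: int,
    support_threshold: float = DEFAULT_SUPPORT,
    min_markers: int = DEFAULT_MIN_MARKERS,
    min_np_markers: int = DEFAULT_MIN_NP_MARKERS,
) -> tuple[BlockType, float | None]:
    """Assign a block type from marker counts; returns (type, support).

    Support is the majority-class fraction of informative markers, or
    ``None`` for a no-data window.
    """
    if min(n_maternal, n_paternal, n_np) < 0:
        raise ValueError("marker counts must be non-negative")
    total = n_maternal + n_paternal + n_np
    if total < min_markers or total == 0:
        return BlockType.NO_DATA, None
    counts = {
        BlockType.MATERNAL: n_maternal,
        BlockType.PATERNAL: n_paternal,
        BlockType.NON_PARENTAL: n_np,
    }
    top = max(counts.values())
    support = top / total
    leaders = [t for t, c in counts.items() if c == top]
    if len(leaders) > 1:
        return BlockType.AMBIGUOUS, support
    candidate = leaders[0]
    if support < support_threshold:
        return BlockType.AMBIGUOUS, support
    if candidate is BlockType.NON_PARENTAL and n_np < min_np_markers:
        return BlockType.AMBIGUOUS, support
    return candidate, support


def infer_track(
    markers: Iterable[MarkerCall],
    scaffold: BlockTrack,
    support_threshold: float = DEFAULT_SUPPORT,
    min_markers: int = DEFAULT_MIN_MARKERS,
    min_np_markers: int = DEFAULT_MIN_NP_MARKERS,
    sister: str | None = None,
) -> BlockTrack:
    """Bin markers into the scaffold's windows and type every window.

    A marker at 1-based position ``pos`` falls in window
    ``(pos - 1) // window_size``. Markers beyond the chromosome end or on
    unknown chromosomes raise ``ValueError``.
    """
    ws = scaffold.window_size
    tallies: dict[tuple[str, int], list[int]] = {}
    marker_sister = sister
    for call in markers:
        if marker_sister is None:
            marker_sister = call.sister
        if call.origin is Origin.UNINFORMATIVE:
            continue
        chrom, pos = call.chrom, call.pos
        if chrom not in scaffold.chrom_lengths:
            raise ValueError(f"marker on unknown chromosome {chrom!r}")
        if pos > scaffold.chrom_lengths[chrom]:
            raise ValueError(
                f"marker at {chrom}:{pos} beyond chromosome end "
                f"{scaffold.chrom_lengths[chrom]}"
            )
        idx = (pos - 1) // ws
        t = tallies.setdefault((chrom, idx), [0, 0, 0])
        if call.origin is Origin.MATERNAL:
            t[0] += 1
        elif call.origin is Origin.PATERNAL:
            t[1] += 1
        else:
            t[2] += 1
    windows: dict[str, list[WindowBlock]] = {}
    for chrom, wins in scaffold.windows.items():
        typed = []
        for w in wins:
            n_m, n_p, n_np = tallies.get((chrom, w.window_index), (0, 0, 0))
            btype, support = type_window(
                n_m, n_p, n_np, support_threshold, min_markers, min_np_markers
            )
            typed.append(
                replace(w, n_maternal=n_m, n_paternal=n_p, n_np=n_np,
                        block_type=btype, support=support)
            )
        windows[chrom] = typed
    return BlockTrack(
        marker_sister or scaffold.sister,
        dict(scaffold.chrom_lengths),
        ws,
        windows,
    )


def summarize_track(track: BlockTrack) -> dict[BlockType, dict[str, int]]:
    """Per-type window counts and bp coverage.

    Coverage sums window lengths, so the per-type coverages add up exactly
    to the genome length.
    """
    out = {t: {"n_windows": 0, "coverage_bp": 0} for t in BlockType}
    for w in track:
        out[w.block_type]["n_windows"] += 1
        out[w.block_type]["coverage_bp"] += w.length
    return out


def merge_runs(track: BlockTrack) -> list[tuple[str, int, int, BlockType]]:
    """Optional post-process: merge adjacent same-type windows into maximal
    segments ``(chrom, start, end, type)``. Window counts, not merged runs,
    are the primary reporting basis."""
    segments: list[tuple[str, int, int, BlockType]] = []
    for chrom in sorted(track.windows):
        run_start = run_end = None
        run_type = None
        for w in track.windows[chrom]:
            if run_type is w.block_type and run_end == w.start:
                run_end = w.end
            else:
                if run_type is not None:
                    segments.append((chrom, run_start, run_end, run_type))
                run_start, run_end, run_type = w.start, w.end, w.block_type
        if run_type is not None:
            segments.append((chrom, run_start, run_end, run_type))
    return segments


def write_bed(track: BlockTrack, path: str | Path) -> None:
    """Write a track as BED (0-based half-open) with type, support and
    per-class marker counts."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\ttype\tsupport\tn_maternal\tn_paternal\tn_np\n")
        for w in track:
            support = "" if w.support is None else f"{w.support:.4f}"
            fh.write(
                f"{w.chrom}\t{w.start}\t{w.end}\t{w.block_type.value}\t"
                f"{support}\t{w.n_maternal}\t{w.n_paternal}\t{w.n_np}\n"
            )
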