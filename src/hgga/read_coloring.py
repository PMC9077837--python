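"""Localize reads on the genetic linkage map.

Each read is aligned to the draft assembly the map is anchored on; the bins
of the markers overlapping (or, for sparse maps, nearest to) its best
alignment become the read's *color*.  Colors are the unit of clustering for
the hierarchy: they give each read a chromosome and an approximate map
position without ever computing read-to-read distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .formats_io import PafAlignment, ReadRecord, RunConfig, log
from .linkage_map import LinkageMap, Marker

UNPLACED = "*"


@dataclass(frozen=True)
class ReadColor:
    """A read's chromosome plus the sorted set of map bins associated with
    it; ``source`` records how the color was derived."""

    read_id: str
    chromosome: str
    bins: tuple[int, ...]
    source: str  # {overlap, closest, unplaced}

    def __post_init__(self) -> None:
        if (self.chromosome == UNPLACED) != (len(self.bins) == 0):
            raise ValueError("bins must be non-empty iff the read is placed")
        if tuple(sorted(set(self.bins))) != self.bins:
            raise ValueError("bins must be sorted and unique")

    @property
    def placed(self) -> bool:
        return self.chromosome != UNPLACED

    @property
    def key_bin(self) -> int:
        """The owning bin used for packing reads into leaves."""
        return self.bins[0]


def unplaced(read_id: str) -> ReadColor:
    return ReadColor(read_id, UNPLACED, (), "unplaced")


def select_alignment(alignments: Sequence[PafAlignment]) -> PafAlignment | None:
    """Pick the single best alignment of a read: most matching bases, ties by
    longer block, then lexicographically smallest target id."""
    if not alignments:
        return None
    ids = {a.query_id for a in alignments}
    if len(ids) > 1:
        raise ValueError(f"alignments from multiple reads: {sorted(ids)}")
    return min(alignments, key=lambda a: (-a.n_matches, -a.block_len, a.target_id))


def marker_distance(marker: Marker, alignment: PafAlignment) -> int:
    """bp distance from a marker to the alignment's target interval; 0 when
    the marker lies inside it."""
    return max(0, alignment.target_start - marker.position,
               marker.position - (alignment.target_end - 1))


def _color_from_markers(read_id: str, markers: list[Marker],
                        source: str) -> ReadColor | None:
    chroms = {m.chromosome for m in markers}
    if len(chroms) > 1:
        # Overlapped markers from more than one chromosome: chimeric draft
        # contig or misalignment; demote rather than guess.
        return None
    return ReadColor(read_id, chroms.pop(),
                     tuple(sorted({m.bin_index for m in markers})), source)


class ConflictingColor(Exception):
    """Markers from more than one chromosome overlap one alignment."""


def color_by_overlap(alignment: PafAlignment, lmap: LinkageMap,
                     _by_contig: dict[str, list[Marker]] | None = None,
                     ) -> ReadColor | None:
    """Color from the markers whose position lies inside the alignment's
    target interval; ``None`` when no marker is overlapped."""
    by_contig = _by_contig if _by_contig is not None else lmap.markers_by_contig()
    markers = [m for m in by_contig.get(alignment.target_id, [])
               if alignment.target_start <= m.position < alignment.target_end]
    if not markers:
        return None
    color = _color_from_markers(alignment.query_id, markers, "overlap")
    if color is None:
        raise ConflictingColor(alignment.query_id)
    return color


def color_by_closest(alignment: PafAlignment, lmap: LinkageMap,
                     tolerance_bp: int = 100,
                     _by_contig: dict[str, list[Marker]] | None = None,
                     ) -> ReadColor | None:
    """Color from all markers roughly as close to the alignment as the
    closest marker (within ``tolerance_bp`` of the minimum distance d*).

    When a marker lies inside the interval, d* = 0 and this reduces to the
    overlap coloring plus near-flank markers.  Returns ``None`` only when the
    target contig carries no markers at all.
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be >= 0")
    by_contig = _by_contig if _by_contig is not None else lmap.markers_by_contig()
    contig_markers = by_contig.get(alignment.target_id, [])
    if not contig_markers:
        return None
    dists = [marker_distance(m, alignment) for m in contig_markers]
    d_star = min(dists)
    markers = [m for m, d in zip(contig_markers, dists) if d <= d_star + tolerance_bp]
    color = _color_from_markers(alignment.query_id, markers, "closest")
    if color is None:
        raise ConflictingColor(alignment.query_id)
    return color


def color_reads(reads: Iterable[ReadRecord | str],
                alignments: Iterable[PafAlignment],
                lmap: LinkageMap,
                config: RunConfig | None = None) -> list[ReadColor]:
    """Color every read: one :class:`ReadColor` per read, in read order.

    In ``overlap`` mode, a read whose alignment contains no marker falls back
    to closest-marker coloring (sparse maps would otherwise leave most reads
    unplaced).  Reads with no alignment, on contigs without markers, or with
    conflicting (multi-chromosome) marker sets come out UNPLACED; conflicts
    are counted in the log.
    """
    config = config or RunConfig()
    by_contig = lmap.markers_by_contig()
    by_read: dict[str, list[PafAlignment]] = {}
    for a in alignments:
        by_read.setdefault(a.query_id, []).append(a)

    colors: list[ReadColor] = []
    n_conflicts = 0
    for read in reads:
        read_id = read if isinstance(read, str) else read.read_id
        best = select_alignment(by_read.get(read_id, []))
        if best is None:
            colors.append(unplaced(read_id))
            continue
        try:
            color = None
            if config.coloring_mode == "overlap":
                color = color_by_overlap(best, lmap, _by_contig=by_contig)
            if color is None:
                color = color_by_closest(best, lmap, config.closest_tolerance_bp,
                                         _by_contig=by_contig)
        except ConflictingColor:
            n_conflicts += 1
            color = None
        colors.append(color if color is not None else unplaced(read_id))
    if n_conflicts:
        log.info("demoted %d reads with markers on more than one chromosome",
                 n_conflicts)
    n_unplaced = sum(not c.placed for c in colors)
    log.info("colored %d reads (%d unplaced)", len(colors), n_unplaced)
    return colors


def save_colors(colors: Iterable[ReadColor], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\tchromosome\tbins\tsource\n")
        for c in colors:
            bins = ",".join(map(str, c.bins)) if c.bins else "*"
            fh.write(f"{c.read_id}\t{c.chromosome}\t{bins}\t{c.source}\n")


def load_colors(path: str | Path) -> list[ReadColor]:
    colors = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            read_id, chrom, bins, source = line.rstrip("\n").split("\t")
            parsed = () if bins == "*" else tuple(int(b) for b in bins.split(","))
            colors.append(ReadColor(read_id, chrom, parsed, source))
    return colors
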