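"""Genetic linkage map data model, TSV serialization and map simulation.

A genetic linkage map consists of markers (e.g. SNVs) anchored on the contigs
of a draft assembly.  Markers are divided into chromosomes and, within each
chromosome, into ordered bins: the order of the bins is known while the order
of markers within a bin is not.  The map is the guide structure for read
clustering — nothing downstream looks at marker sequence, only positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_data import TruthGenome

MAP_COLUMNS = ["chromosome", "bin", "contig", "position"]


@dataclass(frozen=True)
class Marker:
    """A genetic marker: its chromosome and bin on the map, and its physical
    anchor (draft contig + 0-based bp position)."""

    chromosome: str
    bin_index: int
    draft_contig: str
    position: int


@dataclass
class LinkageMap:
    """Ordered chromosomes, each an ordered list of bins of markers."""

    chromosomes: list[str]
    bins_per_chromosome: dict[str, list[list[Marker]]]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for chrom in self.chromosomes:
            bins = self.bins_per_chromosome.get(chrom, [])
            for i, markers in enumerate(bins):
                if not markers:
                    raise ValueError(f"{chrom}: bin {i} is empty")
                for m in markers:
                    if m.chromosome != chrom:
                        raise ValueError(f"marker {m} filed under chromosome {chrom}")
                    if m.bin_index != i:
                        raise ValueError(
                            f"{chrom}: bin indices must be 0..B-1 with no gaps "
                            f"(marker at position {m.position} has bin {m.bin_index}, "
                            f"expected {i})")

    @property
    def n_markers(self) -> int:
        return sum(len(b) for bins in self.bins_per_chromosome.values() for b in bins)

    def markers_by_contig(self) -> dict[str, list[Marker]]:
        """Markers grouped by draft contig, sorted by position (used by the
        read-coloring scans)."""
        out: dict[str, list[Marker]] = {}
        for chrom in self.chromosomes:
            for markers in self.bins_per_chromosome[chrom]:
                for m in markers:
                    out.setdefault(m.draft_contig, []).append(m)
        for contig in out:
            out[contig].sort(key=lambda m: m.position)
        return out


def simulate_map(
    genome: "TruthGenome",
    n_markers: int,
    min_marker_gap_bp: int = 20,
    bin_gap_bp: int = 200,
    seed: int = 0,
    gap_from_first: bool = True,
) -> LinkageMap:
    """Simulate a genetic linkage map by random marker placement.

    Markers are positioned uniformly at random over the genome until
    ``n_markers`` are placed, then sorted by position.  Any marker closer
    than ``min_marker_gap_bp`` to the most recent retained marker is removed
    (a run of close markers collapses to its first).  Bins are then formed by
    a left-to-right scan per chromosome: markers join the current bin until
    one lies at least ``bin_gap_bp`` away from the reference point, which is
    the first marker of the current bin when ``gap_from_first`` (bounded bin
    span) or the previous marker otherwise.

    Marker positions are truth-genome coordinates here; the draft-relative
    anchors are produced by the draft liftover (see
    :func:`hgga.synthetic_data.make_draft`).
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    chrom_ids = list(genome.chromosomes)
    if not chrom_ids:
        raise ValueError("genome has no chromosomes")
    lengths = np.array([len(genome.chromosomes[c]) for c in chrom_ids], dtype=np.int64)
    rng = np.random.default_rng(seed)
    # uniform over the genome = chromosome chosen by length, position uniform
    chrom_choice = rng.choice(len(chrom_ids), size=n_markers, p=lengths / lengths.sum())
    positions = rng.integers(0, lengths[chrom_choice])

    bins_per_chromosome: dict[str, list[list[Marker]]] = {c: [] for c in chrom_ids}
    n_retained = 0
    for ci, chrom in enumerate(chrom_ids):
        pos = np.sort(positions[chrom_choice == ci])
        retained = _prune_close(pos, min_marker_gap_bp)
        n_retained += len(retained)
        bins_per_chromosome[chrom] = _bin_markers(
            chrom, retained, bin_gap_bp, gap_from_first)
    if n_retained < n_markers:
        warnings.warn(
            f"pruned {n_markers - n_retained} markers closer than "
            f"{min_marker_gap_bp} bp to their predecessor; map has "
            f"{n_retained} markers")
    return LinkageMap(chrom_ids, bins_per_chromosome)


def _prune_close(sorted_positions: np.ndarray, min_gap: int) -> list[int]:
    """Single left-to-right pass keeping markers >= min_gap from the most
    recent retained one."""
    retained: list[int] = []
    for p in sorted_positions.tolist():
        if not retained or p - retained[-1] >= min_gap:
            retained.append(p)
    return retained


def _bin_markers(chrom: str, positions: list[int], bin_gap: int,
                 gap_from_first: bool) -> list[list[Marker]]:
    bins: list[list[int]] = []
    current: list[int] = []
    for p in positions:
        if current:
            ref = current[0] if gap_from_first else current[-1]
            if p - ref >= bin_gap:
                bins.append(current)
                current = [p]
                continue
        current.append(p)
    if current:
        bins.append(current)
    return [
        [Marker(chrom, bi, chrom, p) for p in bin_positions]
        for bi, bin_positions in enumerate(bins)
    ]


def per_marker_bins(lmap: LinkageMap) -> LinkageMap:
    """Rebin a map so every marker has its own bin (the convention used for
    real maps that give each marker a physical position instead of a bin);
    marker order is preserved."""
    out: dict[str, list[list[Marker]]] = {}
    for chrom in lmap.chromosomes:
        singles: list[list[Marker]] = []
        for markers in lmap.bins_per_chromosome[chrom]:
            for m in markers:
                singles.append([Marker(m.chromosome, len(singles), m.draft_contig,
                                       m.position)])
        out[chrom] = singles
    return LinkageMap(list(lmap.chromosomes), out)


def save_map(lmap: LinkageMap, path: str | Path) -> None:
    rows = [
        (m.chromosome, m.bin_index, m.draft_contig, m.position)
        for chrom in lmap.chromosomes
        for markers in lmap.bins_per_chromosome[chrom]
        for m in markers
    ]
    df = pd.DataFrame(rows, columns=MAP_COLUMNS)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(MAP_COLUMNS) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def load_map(path: str | Path) -> LinkageMap:
    """Load a map TSV (columns chromosome, bin, contig, position).  Rows may
    be unsorted on disk; they are sorted on load.  Chromosome order follows
    first appearance in the file."""
    df = pd.read_csv(path, sep="\t", comment=None, header=None, names=MAP_COLUMNS,
                     skiprows=_count_comment_rows(path),
                     dtype={"chromosome": str, "bin": int, "contig": str,
                            "position": int})
    chromosomes = list(dict.fromkeys(df["chromosome"]))
    order = {c: i for i, c in enumerate(chromosomes)}
    df = df.sort_values(
        by=["chromosome", "bin", "position"],
        key=lambda col: col.map(order) if col.name == "chromosome" else col,
        kind="stable")
    bins_per_chromosome: dict[str, list[list[Marker]]] = {}
    for chrom, sub in df.groupby("chromosome", sort=False):
        bins: list[list[Marker]] = []
        for bin_index, bin_rows in sub.groupby("bin", sort=True):
            if bin_index != len(bins):
                raise ValueError(
                    f"{path}: chromosome {chrom} has a gap in bin indices "
                    f"(found bin {bin_index}, expected {len(bins)})")
            bins.append([
                Marker(chrom, int(bin_index), str(r.contig), int(r.position))
                for r in bin_rows.itertuples()
            ])
        bins_per_chromosome[chrom] = bins
    return LinkageMap(chromosomes, bins_per_chromosome)


def _count_comment_rows(path: str | Path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n += 1
            else:
                break
    return n
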