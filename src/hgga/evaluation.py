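"""Assembly metrics against a known truth genome.

Implements the standard evaluation vocabulary — contig counts, N50/NG50,
genome fraction, misjoin counts — directly from the metric definitions, for
fixture-scale assemblies where contigs locate on the truth by exact
substring search.  External evaluators (QUAST-style aligners, ortholog
search) are out of scope; the reads-mapped figure in fixture mode uses
truth-coordinate containment rather than a read mapper and is labelled as
such.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .formats_io import ReadRecord, revcomp, log


@dataclass
class LocatedSegment:
    """A piece of a contig placed on the truth: contig-local [q_start,q_end)
    maps to truth [t_start, t_start + (q_end - q_start)) on ``chromosome``
    with the given strand."""

    q_start: int
    q_end: int
    chromosome: str
    t_start: int
    strand: str


@dataclass
class AssemblyMetrics:
    n_contigs: int
    total_length: int
    n50: int
    ng50: int
    genome_fraction: float  # percent
    misjoins: int
    unaligned_contigs: int = 0
    reads_mapped: float | None = None  # percent, fixture mode


def n50(lengths: Sequence[int]) -> int:
    """Shortest length such that contigs at least that long cover half the
    assembly (reaching exactly half counts)."""
    return _nx50(lengths, sum(lengths))


def ng50(lengths: Sequence[int], genome_size: int) -> int:
    """Shortest length such that contigs at least that long cover half the
    *genome*; 0 when the assembly cannot reach half the genome."""
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    if sum(lengths) * 2 < genome_size:
        return 0
    return _nx50(lengths, genome_size)


def _nx50(lengths: Sequence[int], denominator: int) -> int:
    if not lengths:
        raise ValueError("lengths must be non-empty")
    half = denominator / 2
    acc = 0
    for l in sorted(lengths, reverse=True):
        acc += l
        if acc >= half:
            return l
    return 0


def locate_contig(sequence: str, truth: Mapping[str, str],
                  min_segment: int = 50) -> list[LocatedSegment]:
    """Place a contig on the truth by greedy exact matching.

    Repeatedly takes the longest prefix of the remaining contig suffix that
    occurs somewhere in the truth (forward or reverse complement, longest
    found by bisection), records it, and continues after it — so an
    error-free contig yields one segment and a chimeric or mismatched one
    splits at the breakpoints.  Stretches with no match >= ``min_segment``
    are skipped and reported as gaps (no segment emitted).
    """
    segments: list[LocatedSegment] = []
    pos = 0
    n = len(sequence)
    while pos < n:
        remaining = n - pos
        hit = _find_anywhere(sequence[pos:], truth)
        if hit is not None:
            L = remaining
        else:
            lo, hi = 1, remaining  # longest L with a hit is in [lo, hi)
            while hi - lo > 1:
                mid = (lo + hi) // 2
                if _find_anywhere(sequence[pos:pos + mid], truth) is not None:
                    lo = mid
                else:
                    hi = mid
            L = lo
            hit = _find_anywhere(sequence[pos:pos + L], truth)
        if hit is None or L < min_segment:
            pos += max(L, 1)
            continue
        chrom, t_start, strand = hit
        segments.append(LocatedSegment(pos, pos + L, chrom, t_start, strand))
        pos += L
    return segments


def _find_anywhere(segment: str, truth: Mapping[str, str],
                   ) -> tuple[str, int, str] | None:
    for chrom, seq in truth.items():
        i = seq.find(segment)
        if i != -1:
            return chrom, i, "+"
    rc = revcomp(segment)
    for chrom, seq in truth.items():
        i = seq.find(rc)
        if i != -1:
            return chrom, i, "-"
    return None


def _all_occurrences(segment: str, truth: Mapping[str, str],
                     ) -> list[tuple[str, int, int]]:
    """(chromosome, start, end) of every forward or reverse-complement
    occurrence; contigs from repeat regions may cover several places."""
    occ: list[tuple[str, int, int]] = []
    for probe in (segment, revcomp(segment)):
        for chrom, seq in truth.items():
            i = seq.find(probe)
            while i != -1:
                occ.append((chrom, i, i + len(probe)))
                i = seq.find(probe, i + 1)
    return occ


def count_misjoins(segments: Sequence[LocatedSegment], gap_bp: int) -> int:
    """A misjoin is a junction between consecutive located segments whose
    flanks land more than ``gap_bp`` apart, overlap by more than ``gap_bp``,
    or land on different strands or chromosomes."""
    misjoins = 0
    for s1, s2 in zip(segments, segments[1:]):
        if s1.chromosome != s2.chromosome or s1.strand != s2.strand:
            misjoins += 1
            continue
        len1 = s1.q_end - s1.q_start
        len2 = s2.q_end - s2.q_start
        if s1.strand == "+":
            gap = s2.t_start - (s1.t_start + len1)
        else:
            gap = s1.t_start - (s2.t_start + len2)
        if abs(gap) > gap_bp:
            misjoins += 1
    return misjoins


def genome_fraction(covered: dict[str, list[tuple[int, int]]],
                    truth: Mapping[str, str]) -> float:
    total = sum(len(s) for s in truth.values())
    cov = 0
    for chrom, ivals in covered.items():
        ivals = sorted(ivals)
        cur_s, cur_e = None, None
        for s, e in ivals:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    cov += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            cov += cur_e - cur_s
    return 100.0 * cov / total


def truth_metrics(contigs: Sequence[ReadRecord], truth: Mapping[str, str],
                  misjoin_gap_bp: int = 1000,
                  reads: Sequence[ReadRecord] | None = None,
                  ) -> AssemblyMetrics:
    """Locate every contig on the truth and compute the full metric set.

    Intended for error-free fixture assemblies; a contig with unlocatable
    stretches is counted in ``unaligned_contigs`` and logged loudly.  When
    ``reads`` are given, ``reads_mapped`` is the percentage of reads whose
    sequence (or reverse complement) is contained in some contig.
    """
    lengths = [len(c.sequence) for c in contigs]
    covered: dict[str, list[tuple[int, int]]] = {c: [] for c in truth}
    misjoins = 0
    unaligned = 0
    for contig in contigs:
        segments = locate_contig(contig.sequence, truth)
        located_bp = sum(s.q_end - s.q_start for s in segments)
        if located_bp < len(contig.sequence):
            unaligned += 1
            log.warning("contig %s: %d of %d bp not locatable on the truth",
                        contig.read_id, len(contig.sequence) - located_bp,
                        len(contig.sequence))
        misjoins += count_misjoins(segments, misjoin_gap_bp)
        for seg in segments:
            for chrom, s, e in _all_occurrences(
                    contig.sequence[seg.q_start:seg.q_end], truth):
                covered[chrom].append((s, e))
    reads_mapped = None
    if reads is not None:
        n_mapped = sum(
            1 for r in reads
            if any(r.sequence in c.sequence or revcomp(r.sequence) in c.sequence
                   for c in contigs))
        reads_mapped = 100.0 * n_mapped / len(reads) if reads else 0.0
    return AssemblyMetrics(
        n_contigs=len(contigs),
        total_length=sum(lengths),
        n50=n50(lengths) if lengths else 0,
        ng50=ng50(lengths, sum(len(s) for s in truth.values())) if lengths else 0,
        genome_fraction=genome_fraction(covered, truth),
        misjoins=misjoins,
        unaligned_contigs=unaligned,
        reads_mapped=reads_mapped,
    )
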