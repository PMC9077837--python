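"""Synthetic genomes, reads, draft assemblies and linkage maps with known
truth, so every pipeline stage is testable without downloads or external
aligners.

The generator emulates the simulated-organism setting used to study
map-guided assembly: a small multi-chromosome genome of i.i.d. bases
(optionally with planted repeats), uniformly sampled long reads with exact
truth coordinates, a draft assembly produced by fragmenting the truth, and
a linkage map simulated by random marker placement with gap pruning and
distance binning.  Error-free reads are the default: they exercise the
clustering and graph algorithms exactly; a substitution-noise mode exists
for adapter smoke tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .formats_io import PafAlignment, ReadRecord, RunConfig, revcomp, write_fasta
from .linkage_map import LinkageMap, Marker, simulate_map, save_map

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class RepeatSpec:
    """Copy ``length`` bp from (src_chrom, src_start) to (dst_chrom,
    dst_pos), overwriting, at the given sequence identity."""

    src_chrom: str
    src_start: int
    length: int
    dst_chrom: str
    dst_pos: int
    identity: float = 1.0


@dataclass
class TruthGenome:
    chromosomes: dict[str, str]
    planted_repeats: list[RepeatSpec] = field(default_factory=list)

    @property
    def size(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())


@dataclass(frozen=True)
class TruthRead:
    record: ReadRecord
    chromosome: str
    truth_start: int
    truth_end: int  # 0-based half-open
    strand: str


@dataclass
class DraftAssembly:
    """Truth chromosomes cut into contigs; ``segments`` maps each chromosome
    to its ordered (contig_id, truth_start, truth_end) pieces."""

    contigs: dict[str, str]
    segments: dict[str, list[tuple[str, int, int]]]

    def liftover(self, chromosome: str, position: int) -> tuple[str, int]:
        """Truth coordinate -> (draft contig, contig-local position)."""
        for contig_id, start, end in self.segments[chromosome]:
            if start <= position < end:
                return contig_id, position - start
        raise ValueError(f"position {chromosome}:{position} outside the genome")


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=n, p=p).tobytes().decode()


def simulate_genome(n_chrom: int, lengths: Sequence[int],
                    repeat_spec: Sequence[RepeatSpec] = (),
                    gc: float = 0.5, seed: int = 0) -> TruthGenome:
    """I.i.d.-base chromosomes at the given GC, with repeats copied in
    afterwards; deterministic by seed."""
    if len(lengths) != n_chrom:
        raise ValueError("need one length per chromosome")
    if any(l < 1000 for l in lengths):
        raise ValueError("chromosome lengths must be >= 1 kbp")
    rng = np.random.default_rng(seed)
    chroms = {f"chr{i + 1}": _random_dna(rng, l, gc)
              for i, l in enumerate(lengths)}
    for rep in repeat_spec:
        src = chroms[rep.src_chrom]
        if rep.src_start + rep.length > len(src):
            raise ValueError(f"repeat source exceeds {rep.src_chrom}")
        copy = list(src[rep.src_start:rep.src_start + rep.length])
        if rep.identity < 1.0:
            n_mut = rng.binomial(rep.length, 1 - rep.identity)
            for pos in rng.choice(rep.length, size=n_mut, replace=False):
                old = copy[pos]
                copy[pos] = chr(rng.choice([b for b in b"ACGT" if chr(b) != old]))
        dst = chroms[rep.dst_chrom]
        if rep.dst_pos + rep.length > len(dst):
            raise ValueError(f"repeat copy exceeds {rep.dst_chrom}")
        chroms[rep.dst_chrom] = (dst[:rep.dst_pos] + "".join(copy)
                                 + dst[rep.dst_pos + rep.length:])
    return TruthGenome(chroms, list(repeat_spec))


def simulate_reads(genome: TruthGenome, coverage: float, mean_len: int,
                   len_sd: float = 0.0, error_rate: float = 0.0,
                   seed: int = 0, min_len: int = 500) -> list[TruthRead]:
    """Uniformly sampled reads until total bases reach coverage x genome
    size.

    Lengths are truncated-normal around ``mean_len``; strand is a fair
    coin; errors (if any) are uniform substitutions.  Reads overhanging a
    chromosome end are clipped, which keeps coverage even right up to the
    ends.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if mean_len < 100:
        raise ValueError("mean_len must be >= 100")
    shortest = min(len(s) for s in genome.chromosomes.values())
    if mean_len > shortest:
        raise ValueError(f"mean read length {mean_len} exceeds the shortest "
                         f"chromosome ({shortest} bp)")
    rng = np.random.default_rng(seed)
    chrom_ids = list(genome.chromosomes)
    lengths = np.array([len(genome.chromosomes[c]) for c in chrom_ids], float)
    probs = lengths / lengths.sum()
    target = coverage * genome.size

    reads: list[TruthRead] = []
    total = 0
    i = 0
    while total < target:
        chrom = chrom_ids[rng.choice(len(chrom_ids), p=probs)]
        chrom_seq = genome.chromosomes[chrom]
        L = len(chrom_seq)
        rlen = int(np.clip(rng.normal(mean_len, len_sd), min_len, L)) \
            if len_sd > 0 else min(mean_len, L)
        # raw start may overhang either end; clip to the chromosome
        raw = int(rng.integers(-(rlen - min_len), L - min_len + 1))
        start, end = max(raw, 0), min(raw + rlen, L)
        seq = chrom_seq[start:end]
        if error_rate > 0:
            seq = _mutate(seq, error_rate, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = revcomp(seq)
        reads.append(TruthRead(ReadRecord(f"read{i:06d}", seq),
                               chrom, start, end, strand))
        total += end - start
        i += 1
    return reads


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for pos in hits:
        choices = BASES[BASES != arr[pos]]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode()


def make_draft(genome: TruthGenome, n_breaks: int, seed: int = 0,
               ) -> DraftAssembly:
    """Cut the truth chromosomes at ``n_breaks`` random positions into draft
    contigs.  Marker liftover is exact: :meth:`DraftAssembly.liftover`
    round-trips truth coordinates to contig-local ones."""
    if n_breaks < 0:
        raise ValueError("n_breaks must be >= 0")
    rng = np.random.default_rng(seed)
    chrom_ids = list(genome.chromosomes)
    lengths = np.array([len(genome.chromosomes[c]) for c in chrom_ids], float)
    cuts: dict[str, set[int]] = {c: set() for c in chrom_ids}
    for _ in range(n_breaks):
        c = chrom_ids[rng.choice(len(chrom_ids), p=lengths / lengths.sum())]
        pos = int(rng.integers(1, len(genome.chromosomes[c])))
        cuts[c].add(pos)
    contigs: dict[str, str] = {}
    segments: dict[str, list[tuple[str, int, int]]] = {}
    for c in chrom_ids:
        bounds = [0] + sorted(cuts[c]) + [len(genome.chromosomes[c])]
        segs = []
        for j, (s, e) in enumerate(zip(bounds, bounds[1:])):
            cid = f"{c}_ctg{j}"
            contigs[cid] = genome.chromosomes[c][s:e]
            segs.append((cid, s, e))
        segments[c] = segs
    return DraftAssembly(contigs, segments)


def lift_map_to_draft(lmap: LinkageMap, draft: DraftAssembly) -> LinkageMap:
    """Re-anchor a truth-coordinate map onto draft contigs (the map TSV a
    real workflow consumes is always draft-relative)."""
    out: dict[str, list[list[Marker]]] = {}
    for chrom in lmap.chromosomes:
        out[chrom] = [
            [Marker(m.chromosome, m.bin_index, *draft.liftover(m.chromosome,
                                                               m.position))
             for m in markers]
            for markers in lmap.bins_per_chromosome[chrom]
        ]
    return LinkageMap(list(lmap.chromosomes), out)


def reads_to_draft_paf(reads: Sequence[TruthRead],
                       draft: DraftAssembly) -> list[PafAlignment]:
    """Emit the true read-to-draft alignments as PAF directly from truth
    coordinates (no aligner involved); a read spanning a draft break yields
    one line per overlapped contig."""
    out: list[PafAlignment] = []
    for read in reads:
        qlen = len(read.record.sequence)
        ts, te = read.truth_start, read.truth_end
        for contig_id, seg_start, seg_end in draft.segments[read.chromosome]:
            s, e = max(ts, seg_start), min(te, seg_end)
            if s >= e:
                continue
            if read.strand == "+":
                q_start, q_end = s - ts, e - ts
            else:
                q_start, q_end = te - e, te - s
            out.append(PafAlignment(
                read.record.read_id, qlen, q_start, q_end, read.strand,
                contig_id, seg_end - seg_start, s - seg_start, e - seg_start,
                e - s, e - s))
    return out


@dataclass
class Fixture:
    genome: TruthGenome
    reads: list[TruthRead]
    draft: DraftAssembly
    linkage_map: LinkageMap  # draft-anchored
    alignments: list[PafAlignment]
    config: RunConfig


PRESETS = {
    # (chrom lengths, coverage, mean_len, len_sd, n_markers, n_breaks, repeats)
    "tiny": ([20_000], 20, 2_000, 200.0, 100, 1, ()),
    "standard": ([100_000, 100_000], 30, 8_000, 500.0, 400, 4, ()),
    "repeat-rich": ([100_000, 100_000], 30, 8_000, 500.0, 400, 4,
                    (RepeatSpec("chr1", 20_000, 5_000, "chr2", 60_000),)),
}


def make_fixture(preset: str = "standard", seed: int = 0,
                 n_markers: int | None = None,
                 out_dir: str | Path | None = None) -> Fixture:
    """Build a complete input bundle for one of the named presets.

    ``standard``: 2 x 100 kb chromosomes, 30x error-free ~8 kb reads, a
    marker about every 500 bp binned with the 200 bp rule, and length
    thresholds scaled to the genome (internal overlaps >= 500 bp).  All
    randomness flows from ``seed``.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    lengths, coverage, mean_len, len_sd, preset_markers, n_breaks, repeats = \
        PRESETS[preset]
    n_markers = n_markers if n_markers is not None else preset_markers
    genome = simulate_genome(len(lengths), lengths, repeats, seed=seed)
    reads = simulate_reads(genome, coverage, mean_len, len_sd,
                           seed=seed + 1)
    draft = make_draft(genome, n_breaks, seed=seed + 2)
    truth_map = simulate_map(genome, n_markers, seed=seed + 3)
    lmap = lift_map_to_draft(truth_map, draft)
    alignments = reads_to_draft_paf(reads, draft)
    scale = 1 if preset != "tiny" else 2
    config = RunConfig(
        min_internal_overlap=500 // scale,
        root_min_overlap=1000 // scale,
        root_min_contig_len=5000 // scale,
        min_read_overlap=500 // scale,
        coloring_mode="overlap",
        seed=seed,
    )
    fixture = Fixture(genome, reads, draft, lmap, alignments, config)
    if out_dir is not None:
        write_fixture(fixture, Path(out_dir))
    return fixture


def write_fixture(fx: Fixture, out_dir: Path) -> None:
    """Write all inputs plus truth TSVs (read coordinates, draft segments)."""
    from .formats_io import write_paf
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta([ReadRecord(c, s) for c, s in fx.genome.chromosomes.items()],
                out_dir / "truth.fa")
    write_fasta([r.record for r in fx.reads], out_dir / "reads.fa")
    write_fasta([ReadRecord(c, s) for c, s in fx.draft.contigs.items()],
                out_dir / "draft.fa")
    save_map(fx.linkage_map, out_dir / "map.tsv")
    write_paf(fx.alignments, out_dir / "reads_vs_draft.paf")
    fx.config.to_yaml(out_dir / "config.yaml")
    with open(out_dir / "truth_reads.tsv", "w") as fh:
        fh.write("#read_id\tchromosome\tstart\tend\tstrand\n")
        for r in fx.reads:
            fh.write(f"{r.record.read_id}\t{r.chromosome}\t{r.truth_start}"
                     f"\t{r.truth_end}\t{r.strand}\n")
    with open(out_dir / "truth_draft.tsv", "w") as fh:
        fh.write("#contig\tchromosome\tstart\tend\n")
        for chrom, segs in fx.draft.segments.items():
            for cid, s, e in segs:
                fh.write(f"{cid}\t{chrom}\t{s}\t{e}\n")
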