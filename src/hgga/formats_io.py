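"""Readers and writers for the sequence and alignment formats the pipeline
touches, plus run configuration and logging.

Coordinates everywhere are 0-based, half-open, matching the PAF convention.
FASTQ qualities are discarded on read: no stage of the method consumes them.
"""

from __future__ import annotations

import gzip
import io
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import IO, Iterable, Iterator

import yaml

log = logging.getLogger("hgga")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement over the alphabet {A,C,G,T,N} (case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def setup_logging(level: int = logging.INFO) -> None:
    """Structured progress lines to stderr; idempotent."""
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[hgga] %(levelname)s %(message)s"))
        log.addHandler(handler)
    log.setLevel(level)


class FormatError(ValueError):
    """Malformed input file; message names the file and line number."""


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read or contig: an id and a DNA sequence."""

    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.read_id or any(c.isspace() for c in self.read_id):
            raise ValueError(f"invalid sequence id {self.read_id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PafAlignment:
    """One line of a minimap2-style PAF file (first 12 columns)."""

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    n_matches: int
    block_len: int

    def __post_init__(self) -> None:
        if not (0 <= self.query_start < self.query_end <= self.query_len):
            raise ValueError(f"bad query interval in {self}")
        if not (0 <= self.target_start < self.target_end <= self.target_len):
            raise ValueError(f"bad target interval in {self}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class RunConfig:
    """Tunable parameters of a run.

    Length thresholds are in bp and may be scaled down for small test
    genomes; the defaults suit real long-read data (multi-kbp overlaps).
    """

    min_leaf_fraction: float = 0.015
    min_internal_overlap: int = 10000
    root_min_overlap: int = 20000
    root_min_contig_len: int = 50000
    min_read_overlap: int = 2000
    min_output_contig_len: int = 0
    coloring_mode: str = "overlap"
    closest_tolerance_bp: int = 100
    bin_gap_from_first: bool = True
    merge_small_tail_leaf: bool = True
    emit_unplaced: bool = False
    seed: int = 0
    leaf_assembler: str = "builtin"
    external_cmd_template: str = ""
    jobs: int = 1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.min_leaf_fraction < 1:
            raise ValueError("min_leaf_fraction must be in (0, 1)")
        for name in ("min_internal_overlap", "root_min_overlap",
                     "root_min_contig_len", "min_read_overlap",
                     "min_output_contig_len", "closest_tolerance_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.root_min_overlap < self.min_internal_overlap:
            raise ValueError("root_min_overlap must be >= min_internal_overlap")
        if self.coloring_mode not in ("overlap", "closest"):
            raise ValueError(f"unknown coloring_mode {self.coloring_mode!r}")
        if self.leaf_assembler not in ("builtin", "external"):
            raise ValueError(f"unknown leaf_assembler {self.leaf_assembler!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    raw = open(path, "rb")
    if raw.read(2) == b"\x1f\x8b":
        raw.seek(0)
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    raw.seek(0)
    return io.TextIOWrapper(raw)


def read_fasta(path: str | Path) -> Iterator[ReadRecord]:
    """Yield records from a FASTA or FASTQ file (gzip allowed), in file order.

    The format is detected from the first character (``>`` or ``@``).
    Multi-line sequences are concatenated, lowercase is uppercased and FASTQ
    qualities are discarded.  Malformed input raises :class:`FormatError`
    naming the offending line.
    """
    path = Path(path)
    with _open_text(path) as fh:
        first = fh.read(1)
        if first == "":
            return
        fh.seek(0)
        if first == ">":
            yield from _parse_fasta(fh, path)
        elif first == "@":
            yield from _parse_fastq(fh, path)
        else:
            raise FormatError(f"{path}:1: not FASTA or FASTQ (starts with {first!r})")


def _parse_fasta(fh: IO[str], path: Path) -> Iterator[ReadRecord]:
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                yield _make_record(header, chunks, path, header_line)
            header = line[1:].split()[0] if line[1:].split() else ""
            if not header:
                raise FormatError(f"{path}:{lineno}: empty FASTA header")
            header_line = lineno
            chunks = []
        else:
            if header is None:
                raise FormatError(f"{path}:{lineno}: sequence line before header")
            chunks.append(line)
    if header is not None:
        yield _make_record(header, chunks, path, header_line)


def _parse_fastq(fh: IO[str], path: Path) -> Iterator[ReadRecord]:
    lineno = 0
    while True:
        header = fh.readline()
        if not header:
            return
        lineno += 1
        header = header.rstrip("\n")
        if not header.startswith("@"):
            raise FormatError(f"{path}:{lineno}: expected '@' header, got {header[:20]!r}")
        seq = fh.readline().rstrip("\n")
        plus = fh.readline()
        qual = fh.readline()
        if not qual:
            raise FormatError(f"{path}:{lineno}: truncated FASTQ record")
        lineno += 3
        if not plus.startswith("+"):
            raise FormatError(f"{path}:{lineno - 1}: expected '+' separator")
        name = header[1:].split()[0] if header[1:].split() else ""
        if not name:
            raise FormatError(f"{path}:{lineno - 3}: empty FASTQ header")
        yield ReadRecord(name, seq.upper())


def _make_record(header: str, chunks: list[str], path: Path, lineno: int) -> ReadRecord:
    seq = "".join(chunks).upper()
    if not seq:
        raise FormatError(f"{path}:{lineno}: record {header!r} has no sequence")
    return ReadRecord(header, seq)


def write_fasta(records: Iterable[ReadRecord], path: str | Path, line_width: int = 80) -> None:
    """Write records as FASTA; round-trips exactly through :func:`read_fasta`.

    Duplicate ids are an error: downstream overlap-graph keys would collide.
    """
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    seen: set[str] = set()
    with open(path, "w") as fh:
        for rec in records:
            if rec.read_id in seen:
                raise ValueError(f"duplicate sequence id {rec.read_id!r}")
            seen.add(rec.read_id)
            fh.write(f">{rec.read_id}\n")
            for i in range(0, len(rec.sequence), line_width):
                fh.write(rec.sequence[i:i + line_width] + "\n")


def read_paf(path: str | Path) -> Iterator[PafAlignment]:
    """Yield alignments from a PAF file in file order; columns beyond the
    twelfth are ignored."""
    path = Path(path)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: expected >= 12 columns, got {len(fields)}")
            try:
                aln = PafAlignment(
                    query_id=fields[0],
                    query_len=int(fields[1]),
                    query_start=int(fields[2]),
                    query_end=int(fields[3]),
                    strand=fields[4],
                    target_id=fields[5],
                    target_len=int(fields[6]),
                    target_start=int(fields[7]),
                    target_end=int(fields[8]),
                    n_matches=int(fields[9]),
                    block_len=int(fields[10]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            yield aln


def write_paf(alignments: Iterable[PafAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            fh.write("\t".join(str(x) for x in (
                a.query_id, a.query_len, a.query_start, a.query_end, a.strand,
                a.target_id, a.target_len, a.target_start, a.target_end,
                a.n_matches, a.block_len, 255)) + "\n")
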