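"""Assemble the raw reads of one hierarchy leaf into contigs.

Leaves are independent by construction, so any assembler suited to the read
data can be plugged in.  The builtin mode runs the same overlap-layout
machinery as the internal nodes at read scale, which is exact on
error-corrected or error-free reads; the external mode shells out to a real
long-read assembler (e.g. a miniasm + polisher pipeline) through a simple
command template.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .formats_io import ReadRecord, read_fasta, write_fasta
from .overlap_core import assemble_node


@dataclass
class LeafAssemblyParams:
    min_read_overlap: int = 2000
    min_output_contig_len: int = 0
    max_mismatch_rate: float = 0.0
    mode: str = "builtin"  # {builtin, external}
    external_cmd_template: str = ""

    def __post_init__(self) -> None:
        if self.min_read_overlap < 1:
            raise ValueError("min_read_overlap must be >= 1")
        if self.mode not in ("builtin", "external"):
            raise ValueError(f"unknown leaf assembler mode {self.mode!r}")


class LeafAssemblyError(RuntimeError):
    """External leaf assembly failed; the message names the leaf."""


def assemble_leaf(reads: Sequence[ReadRecord], params: LeafAssemblyParams,
                  leaf_id: str = "leaf",
                  workdir: str | Path | None = None) -> list[ReadRecord]:
    """Assemble one leaf's reads into contigs.

    The result depends only on the reads and parameters, never on when or
    where the leaf is processed, so leaves can run in any order or in
    parallel.
    """
    if not reads:
        raise ValueError(f"{leaf_id}: empty read set")
    if params.mode == "external":
        if workdir is None:
            raise ValueError("external mode needs a workdir")
        contigs = external_adapter(reads, params.external_cmd_template,
                                   Path(workdir), leaf_id)
    else:
        contigs = assemble_node(reads, params.min_read_overlap,
                                params.max_mismatch_rate,
                                id_prefix=leaf_id)
    if params.min_output_contig_len > 0:
        contigs = [c for c in contigs
                   if len(c.sequence) >= params.min_output_contig_len]
    return contigs


def external_adapter(reads: Sequence[ReadRecord], cmd_template: str,
                     workdir: Path, leaf_id: str = "leaf") -> list[ReadRecord]:
    """Run an external assembler: write the reads as FASTA, substitute
    ``{reads}`` and ``{out}`` in the template, run it through the shell, and
    parse the output FASTA.  Intermediate files the tool writes are its own
    business; only ``{out}`` is consumed."""
    if "{reads}" not in cmd_template or "{out}" not in cmd_template:
        raise ValueError("command template must contain {reads} and {out}")
    workdir.mkdir(parents=True, exist_ok=True)
    reads_path = workdir / "reads.fa"
    out_path = workdir / "contigs.fa"
    write_fasta(reads, reads_path)
    cmd = cmd_template.format(reads=str(reads_path), out=str(out_path))
    proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
    if proc.returncode != 0:
        raise LeafAssemblyError(
            f"leaf {leaf_id}: external assembler exited "
            f"{proc.returncode}: {proc.stderr.strip()[:500]}")
    if not out_path.exists():
        raise LeafAssemblyError(
            f"leaf {leaf_id}: external assembler produced no output file "
            f"({out_path}); stderr: {proc.stderr.strip()[:500]}")
    return [ReadRecord(f"{leaf_id}.{r.read_id}", r.sequence)
            for r in read_fasta(out_path)]
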