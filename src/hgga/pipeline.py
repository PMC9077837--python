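"""End-to-end orchestration: color reads, build the hierarchy, assemble
leaves, merge up the trees, and finish with the root step.

Every node's inputs and outputs live in files under the output directory and
a JSON manifest tracks per-node status, so an interrupted run resumes from
the last finished node.  Nodes whose children are done are independent: the
leaf processing order is a parameter (and changing it must not change any
output), and leaves can be assembled in parallel.
"""

from __future__ import annotations

import json
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .formats_io import (PafAlignment, ReadRecord, RunConfig, log,
                         read_fasta, write_fasta)
from .hierarchy_builder import HierarchyTree, TreeNode, build_hierarchy, tree_manifest
from .leaf_assembler import LeafAssemblyParams, assemble_leaf
from .linkage_map import LinkageMap
from .overlap_core import assemble_node, assemble_root
from .read_coloring import color_reads, save_colors
from .evaluation import locate_contig


@dataclass
class RunResult:
    final_contigs: list[ReadRecord]
    out_dir: Path
    trees: list[HierarchyTree]
    manifest: dict


def align_reads_to_draft(reads: Sequence[ReadRecord],
                         draft_contigs: Sequence[ReadRecord],
                         min_segment: int = 50) -> list[PafAlignment]:
    """Built-in exact read-to-draft aligner.

    Places each read on the draft by greedy exact matching (forward or
    reverse complement), emitting one PAF line per matched segment; a read
    spanning a draft gap or contig junction yields several lines.  Exact
    matching suits error-free reads; noisy reads should be aligned with an
    external mapper and passed in as PAF.
    """
    draft = {c.read_id: c.sequence for c in draft_contigs}
    out: list[PafAlignment] = []
    for read in reads:
        for seg in locate_contig(read.sequence, draft, min_segment):
            L = seg.q_end - seg.q_start
            out.append(PafAlignment(
                read.read_id, len(read.sequence), seg.q_start, seg.q_end,
                seg.strand, seg.chromosome, len(draft[seg.chromosome]),
                seg.t_start, seg.t_start + L, L, L))
    return out


def _node_path(out_dir: Path, node_id: str) -> Path:
    return out_dir / "nodes" / node_id / "contigs.fa"


def _safe_prefix(node_id: str) -> str:
    return node_id.replace("/", "_").replace(".", "_")


def _assemble_leaf_job(args) -> tuple[str, list[ReadRecord]]:
    node_id, reads, params = args
    return node_id, assemble_leaf(reads, params, leaf_id=_safe_prefix(node_id))


class Pipeline:
    """Checkpointed run driver; all state is in ``out_dir``."""

    def __init__(self, out_dir: str | Path, config: RunConfig | None = None):
        self.out_dir = Path(out_dir)
        self.config = config or RunConfig()
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out_dir / "manifest.json"
        self.manifest: dict = {"config": vars(self.config).copy(), "nodes": {}}
        if self.manifest_path.exists():
            prev = json.loads(self.manifest_path.read_text())
            if prev.get("config") == self.manifest["config"]:
                self.manifest = prev
            else:
                log.warning("config changed; ignoring previous manifest")

    # -- node bookkeeping ---------------------------------------------------

    def _save_manifest(self) -> None:
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1))

    def _node_done(self, node_id: str) -> bool:
        entry = self.manifest["nodes"].get(node_id)
        return (entry is not None and entry.get("status") == "done"
                and _node_path(self.out_dir, node_id).exists())

    def _store(self, node_id: str, contigs: list[ReadRecord]) -> None:
        path = _node_path(self.out_dir, node_id)
        path.parent.mkdir(parents=True, exist_ok=True)
        write_fasta(contigs, path)
        self.manifest["nodes"][node_id] = {"status": "done",
                                           "path": str(path)}
        self._save_manifest()

    def _load(self, node_id: str) -> list[ReadRecord]:
        return list(read_fasta(_node_path(self.out_dir, node_id)))

    # -- stages -------------------------------------------------------------

    def run(self, reads: Sequence[ReadRecord],
            alignments: Iterable[PafAlignment], lmap: LinkageMap,
            leaf_order: Sequence[int] | None = None) -> RunResult:
        """Execute all stages in dependency order and return the final
        contig set (also written to ``final.fa``).

        ``leaf_order`` permutes the order leaves are processed in; outputs
        are identical for every permutation.
        """
        cfg = self.config
        reads_by_id = {r.read_id: r for r in reads}

        colors = color_reads(reads, alignments, lmap, cfg)
        save_colors(colors, self.out_dir / "colors.tsv")
        if cfg.emit_unplaced:
            write_fasta([reads_by_id[c.read_id] for c in colors if not c.placed],
                        self.out_dir / "unplaced.fa")

        min_leaf_size = max(1, round(cfg.min_leaf_fraction * len(reads)))
        trees = build_hierarchy(colors, min_leaf_size, cfg.merge_small_tail_leaf)
        self.manifest["trees"] = tree_manifest(trees)
        self._save_manifest()

        leaf_params = LeafAssemblyParams(
            min_read_overlap=cfg.min_read_overlap,
            min_output_contig_len=cfg.min_output_contig_len,
            mode=cfg.leaf_assembler,
            external_cmd_template=cfg.external_cmd_template)

        # leaves, in any order
        all_leaves = [leaf for tree in trees for leaf in tree.leaves]
        order = list(leaf_order) if leaf_order is not None \
            else list(range(len(all_leaves)))
        if sorted(order) != list(range(len(all_leaves))):
            raise ValueError("leaf_order must be a permutation of the leaves")
        pending = [all_leaves[i] for i in order
                   if not self._node_done(all_leaves[i].node_id)]
        jobs = [(leaf.node_id,
                 [reads_by_id[rid] for rid in leaf.read_ids], leaf_params)
                for leaf in pending]
        if cfg.jobs > 1 and jobs:
            with ProcessPoolExecutor(max_workers=cfg.jobs) as pool:
                results = list(pool.map(_assemble_leaf_job, jobs))
        else:
            results = [_assemble_leaf_job(j) for j in jobs]
        for node_id, contigs in results:
            self._store(node_id, contigs)
            log.info("leaf %s: %d contigs", node_id, len(contigs))

        # internal nodes, bottom-up
        for tree in trees:
            for level in tree.nodes_by_level()[1:]:
                for node in level:
                    if node.is_leaf or self._node_done(node.node_id):
                        continue
                    children = [c for child in node.children
                                for c in self._load(child.node_id)]
                    contigs = assemble_node(
                        children, cfg.min_internal_overlap,
                        id_prefix=_safe_prefix(node.node_id))
                    self._store(node.node_id, contigs)
                    log.info("node %s: %d -> %d contigs", node.node_id,
                             len(children), len(contigs))

        # root step over all trees, with stronger parameters
        root_id = "root"
        if not self._node_done(root_id):
            roots = [self._load(t.root.node_id) for t in trees]
            final = assemble_root(roots, cfg.root_min_overlap,
                                  cfg.root_min_contig_len)
            self._store(root_id, final)
        final = self._load(root_id)
        write_fasta(final, self.out_dir / "final.fa")
        log.info("final assembly: %d contigs, %d bp", len(final),
                 sum(len(c.sequence) for c in final))
        return RunResult(final, self.out_dir, trees, self.manifest)


def run(reads: Sequence[ReadRecord], alignments: Iterable[PafAlignment],
        lmap: LinkageMap, out_dir: str | Path,
        config: RunConfig | None = None,
        leaf_order: Sequence[int] | None = None) -> RunResult:
    """Convenience wrapper: one call from inputs to final assembly."""
    return Pipeline(out_dir, config).run(reads, alignments, lmap,
                                         leaf_order=leaf_order)
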