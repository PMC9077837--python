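"""Build per-chromosome binary hierarchy trees from colored reads.

Reads are sorted by their associated bins with a counting sort, packed into
preliminary leaves by adding whole bins until a minimum leaf size is
reached, and then overlapped with their neighbors: every preliminary leaf is
split in half and each final leaf is the union of four consecutive
half-blocks.  The overlap guarantees that adjacent leaf assemblies share
sequence, so their contigs can be merged on the way up the tree; it also
makes leaf coverage higher and more even.  The tree height is never a
parameter — it follows from the number of leaves.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .formats_io import log
from .read_coloring import ReadColor


@dataclass
class PreliminaryLeaf:
    """A bin-contiguous block of reads, split in half for neighbor overlap."""

    chromosome: str
    bin_range: tuple[int, int]  # inclusive [first_bin, last_bin]
    read_ids: list[str]

    @property
    def left_half(self) -> list[str]:
        return self.read_ids[:math.ceil(len(self.read_ids) / 2)]

    @property
    def right_half(self) -> list[str]:
        return self.read_ids[math.ceil(len(self.read_ids) / 2):]


@dataclass
class TreeNode:
    node_id: str
    children: list["TreeNode"] = field(default_factory=list)
    read_ids: list[str] | None = None  # leaves only

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class HierarchyTree:
    chromosome: str
    root: TreeNode
    leaves: list[TreeNode]

    @property
    def height(self) -> int:
        def h(node: TreeNode) -> int:
            return 0 if node.is_leaf else 1 + max(h(c) for c in node.children)
        return h(self.root)

    def nodes_by_level(self) -> list[list[TreeNode]]:
        """Bottom-up levels: index 0 is the leaves, last is [root]."""
        levels: dict[int, list[TreeNode]] = {}

        def visit(node: TreeNode) -> int:
            lvl = 0 if node.is_leaf else 1 + max(visit(c) for c in node.children)
            levels.setdefault(lvl, []).append(node)
            return lvl

        top = visit(self.root)
        return [levels.get(i, []) for i in range(top + 1)]


def sort_colored_reads(colors: Iterable[ReadColor]) -> dict[str, list[ReadColor]]:
    """Per-chromosome read lists ordered by (min associated bin, read_id).

    The bin sort is a counting sort over bin indices (the bins are small
    integers), so the whole pass is linear in reads + bins; ties within a
    bin are broken by read id for determinism.
    """
    per_chrom: dict[str, list[ReadColor]] = {}
    for c in colors:
        if not c.placed:
            raise ValueError(f"unplaced read {c.read_id} cannot be sorted")
        per_chrom.setdefault(c.chromosome, []).append(c)
    out: dict[str, list[ReadColor]] = {}
    for chrom, cs in per_chrom.items():
        n_bins = max(c.key_bin for c in cs) + 1
        buckets: list[list[ReadColor]] = [[] for _ in range(n_bins)]
        for c in cs:
            buckets[c.key_bin].append(c)
        ordered: list[ReadColor] = []
        for bucket in buckets:
            bucket.sort(key=lambda c: c.read_id)
            ordered.extend(bucket)
        out[chrom] = ordered
    return out


def build_preliminary_leaves(ordered: Sequence[ReadColor], min_leaf_size: int,
                             merge_small_tail: bool = True,
                             ) -> list[PreliminaryLeaf]:
    """Pack whole bins into preliminary leaves of at least ``min_leaf_size``
    reads.

    A bin's reads are never split across leaves (each read is attributed to
    its minimum associated bin).  The trailing remainder becomes the last
    leaf; if it holds fewer than ``min_leaf_size / 2`` reads and
    ``merge_small_tail`` is set, it is merged into its predecessor.
    """
    if min_leaf_size < 1:
        raise ValueError("min_leaf_size must be >= 1")
    if not ordered:
        return []
    chrom = ordered[0].chromosome

    leaves: list[PreliminaryLeaf] = []
    current: list[str] = []
    first_bin = last_bin = ordered[0].key_bin
    i = 0
    while i < len(ordered):
        # consume one whole bin
        b = ordered[i].key_bin
        j = i
        while j < len(ordered) and ordered[j].key_bin == b:
            j += 1
        if not current:
            first_bin = b
        current.extend(c.read_id for c in ordered[i:j])
        last_bin = b
        i = j
        if len(current) >= min_leaf_size:
            leaves.append(PreliminaryLeaf(chrom, (first_bin, last_bin), current))
            current = []
    if current:
        if leaves and merge_small_tail and len(current) < min_leaf_size / 2:
            prev = leaves[-1]
            leaves[-1] = PreliminaryLeaf(
                chrom, (prev.bin_range[0], last_bin), prev.read_ids + current)
        else:
            leaves.append(PreliminaryLeaf(chrom, (first_bin, last_bin), current))
    if len(leaves) == 1 and len(leaves[0].read_ids) < min_leaf_size:
        log.warning("chromosome %s has only %d reads (< min leaf size %d): "
                    "single leaf", chrom, len(leaves[0].read_ids), min_leaf_size)
    return leaves


def overlap_leaves(prelim: Sequence[PreliminaryLeaf]) -> list[list[str]]:
    """Final leaf i = R(i-1) + L(i) + R(i) + L(i+1): the preliminary leaf
    plus the right half of its left neighbor and the left half of its right
    neighbor (missing neighbors at chromosome ends omitted)."""
    if not prelim:
        raise ValueError("need at least one preliminary leaf")
    final: list[list[str]] = []
    for i, leaf in enumerate(prelim):
        reads: list[str] = []
        if i > 0:
            reads.extend(prelim[i - 1].right_half)
        reads.extend(leaf.read_ids)
        if i + 1 < len(prelim):
            reads.extend(prelim[i + 1].left_half)
        final.append(reads)
    return final


def build_tree(chromosome: str, final_leaves: Sequence[list[str]]) -> HierarchyTree:
    """Pair final leaves bottom-up in leaf order into a binary tree.

    Level k+1 pairs nodes (2i, 2i+1); an odd node out is promoted unchanged,
    which keeps the tree order-preserving.  With 2^k leaves this is a perfect
    binary tree of height k.
    """
    if not final_leaves:
        raise ValueError("need at least one final leaf")
    level: list[TreeNode] = [
        TreeNode(f"{chromosome}/leaf{i}", read_ids=list(reads))
        for i, reads in enumerate(final_leaves)
    ]
    leaves = list(level)
    depth = 0
    while len(level) > 1:
        depth += 1
        nxt: list[TreeNode] = []
        for i in range(0, len(level) - 1, 2):
            nxt.append(TreeNode(f"{chromosome}/n{depth}.{i // 2}",
                                children=[level[i], level[i + 1]]))
        if len(level) % 2:
            nxt.append(level[-1])
        level = nxt
    return HierarchyTree(chromosome, level[0], leaves)


def build_hierarchy(colors: Iterable[ReadColor], min_leaf_size: int,
                    merge_small_tail: bool = True) -> list[HierarchyTree]:
    """Colored reads -> one hierarchy tree per chromosome (chromosomes in
    first-appearance order of the colors)."""
    per_chrom = sort_colored_reads(c for c in colors if c.placed)
    trees = []
    for chrom, ordered in per_chrom.items():
        prelim = build_preliminary_leaves(ordered, min_leaf_size, merge_small_tail)
        final = overlap_leaves(prelim)
        tree = build_tree(chrom, final)
        log.info("chromosome %s: %d reads -> %d leaves, height %d",
                 chrom, len(ordered), len(final), tree.height)
        trees.append(tree)
    return trees


def tree_manifest(trees: Sequence[HierarchyTree]) -> dict:
    """JSON-serializable description of the trees (ids, children, leaf read
    ids), used by the pipeline manifest."""
    def node_dict(node: TreeNode) -> dict:
        d: dict = {"id": node.node_id}
        if node.is_leaf:
            d["read_ids"] = node.read_ids
        else:
            d["children"] = [node_dict(c) for c in node.children]
        return d

    return {"trees": [
        {"chromosome": t.chromosome, "root": node_dict(t.root),
         "n_leaves": len(t.leaves)}
        for t in trees
    ]}


def save_manifest(trees: Sequence[HierarchyTree], path: str | Path) -> None:
    Path(path).write_text(json.dumps(tree_manifest(trees), indent=1))
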