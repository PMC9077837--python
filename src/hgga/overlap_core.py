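"""Overlap detection, the bidirected overlap graph, greedy alternating-path
traversal, stitching and containment removal.

This is the merge engine used at every internal node of the hierarchy and at
the final root step.  Double-strandedness is handled with an undirected
simulation of a bidirected graph: each contig *u* contributes two vertices
``u_s`` / ``u_e`` joined by a *contig edge*, and each dovetail overlap
contributes an *overlap edge* whose endpoints encode the relative
orientation of the two contigs:

=========================================  =============
suffix of u overlaps prefix of v           (u_e, v_s)
suffix of u overlaps prefix of rc(v)       (u_e, v_e)
suffix of rc(u) overlaps prefix of v       (u_s, v_s)
suffix of rc(u) overlaps prefix of rc(v)   (u_s, v_e)
=========================================  =============

Super-contigs are read off as paths alternating contig and overlap edges;
traversing a contig edge s->e emits the contig forward, e->s emits its
reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .formats_io import PafAlignment, ReadRecord, revcomp

DOVETAIL_KINDS = (
    "a_suffix_b_prefix",
    "a_suffix_brc_prefix",
    "arc_suffix_b_prefix",
    "arc_suffix_brc_prefix",
)
CONTAINMENT_KINDS = ("a_contained", "b_contained")

#: overlap kind -> (side on a, side on b) of the overlap edge
EDGE_ENDPOINTS = {
    "a_suffix_b_prefix": ("e", "s"),
    "a_suffix_brc_prefix": ("e", "e"),
    "arc_suffix_b_prefix": ("s", "s"),
    "arc_suffix_brc_prefix": ("s", "e"),
}

_SIDE_ORDER = {"s": 0, "e": 1}

Vertex = tuple[str, str]  # (contig_id, "s" | "e")


@dataclass(frozen=True)
class Overlap:
    """A pairwise overlap between contigs a and b.

    Coordinates are 0-based half-open on the *forward* strand of each
    contig; ``strand`` is the orientation of b relative to a; ``length`` is
    the bp length of the aligned block; ``kind`` classifies the overlap as
    one of the four dovetail cases, a containment, or an internal match.
    """

    a_id: str
    b_id: str
    strand: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    a_len: int
    b_len: int
    length: int
    kind: str

    def span_on(self, contig_id: str) -> int:
        """bp covered by the overlap on the given contig's own coordinates."""
        if contig_id == self.a_id:
            return self.a_end - self.a_start
        if contig_id == self.b_id:
            return self.b_end - self.b_start
        raise ValueError(f"{contig_id} is not part of this overlap")


@dataclass
class AssemblyPath:
    """A maximal alternating contig-edge / overlap-edge path.

    ``vertices`` starts and ends on a contig edge; ``members`` is the
    per-contig orientation implied by the traversal direction of each contig
    edge; ``overlaps`` are the junctions, one fewer than members.
    """

    vertices: list[Vertex]
    members: list[tuple[str, str]]  # (contig_id, "+" | "-")
    overlaps: list[Overlap]


@dataclass
class SuperContig:
    contig_id: str
    sequence: str
    path: AssemblyPath

    @property
    def members(self) -> list[tuple[str, str]]:
        return self.path.members


# ---------------------------------------------------------------------------
# overlap detection

def _matches(x: str, y: str, max_mismatch_rate: float) -> bool:
    if max_mismatch_rate <= 0:
        return x == y
    if len(x) != len(y):
        return False
    mism = sum(a != b for a, b in zip(x, y))
    return mism <= max_mismatch_rate * len(x)


def find_overlaps_builtin(contigs: Sequence[ReadRecord], min_overlap: int,
                          max_mismatch_rate: float = 0.0) -> list[Overlap]:
    """All pairwise suffix-prefix overlaps of length >= ``min_overlap`` and
    all containments, between every oriented pair of distinct contigs.

    Detection seeds on an exact prefix k-mer of the (oriented) second contig
    and verifies the full candidate region, with an optional Hamming
    mismatch allowance for noisy input (substitutions only; the exact mode
    is the one exercised by the hierarchical pipeline on corrected contigs).
    Every overlap is reported from both sides; the mirrored duplicates
    collapse onto the same undirected edge in :func:`build_graph`.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    k = min(21, min_overlap)
    oriented: list[tuple[str, str, str]] = []  # (b_id, strand, oriented seq)
    for rec in contigs:
        oriented.append((rec.read_id, "+", rec.sequence))
        oriented.append((rec.read_id, "-", revcomp(rec.sequence)))

    out: list[Overlap] = []
    for a in contigs:
        for a_orient, A in (("+", a.sequence), ("-", revcomp(a.sequence))):
            for b_id, b_orient, B in oriented:
                if b_id == a.read_id:
                    continue
                out.extend(_scan_pair(a.read_id, a_orient, A, b_id, b_orient,
                                      B, k, min_overlap, max_mismatch_rate))
    return out


def _scan_pair(a_id: str, a_orient: str, A: str, b_id: str, b_orient: str,
               B: str, k: int, min_overlap: int, mmr: float) -> list[Overlap]:
    """Occurrences of B's prefix seed inside the oriented A: containment of
    B when the hit fits inside A, a dovetail (suffix of oriented A = prefix
    of oriented B) when it runs off A's end.

    Scanning A in both orientations covers all four dovetail cases
    (tail-to-head, tail-to-tail, head-to-head); containments are only
    reported from the forward scan to avoid mirrored duplicates.
    """
    b_len = len(B)
    seed = B[:k] if b_len >= k else B
    found: list[Overlap] = []
    have_containment = False
    i = A.find(seed)
    while i != -1:
        if i + b_len <= len(A):
            if (a_orient == "+" and not have_containment
                    and _matches(A[i:i + b_len], B, mmr)):
                found.append(_containment(a_id, A, b_id, b_orient, b_len, i))
                have_containment = True
        else:
            L = len(A) - i
            if i > 0 and L >= min_overlap and _matches(A[i:], B[:L], mmr):
                found.append(_dovetail(a_id, a_orient, len(A), b_id,
                                       b_orient, b_len, L))
                break  # first valid dovetail is the longest
        i = A.find(seed, i + 1)
    return found


def _dovetail(a_id: str, a_orient: str, a_len: int, b_id: str, b_orient: str,
              b_len: int, L: int) -> Overlap:
    kind = {("+", "+"): "a_suffix_b_prefix",
            ("+", "-"): "a_suffix_brc_prefix",
            ("-", "+"): "arc_suffix_b_prefix",
            ("-", "-"): "arc_suffix_brc_prefix"}[(a_orient, b_orient)]
    # coordinates on the forward strand of each contig
    a_start, a_end = (a_len - L, a_len) if a_orient == "+" else (0, L)
    b_start, b_end = (0, L) if b_orient == "+" else (b_len - L, b_len)
    strand = "+" if a_orient == b_orient else "-"
    return Overlap(a_id, b_id, strand, a_start, a_end, b_start, b_end,
                   a_len, b_len, L, kind)


def _containment(a_id: str, A: str, b_id: str, strand: str, b_len: int,
                 i: int) -> Overlap:
    return Overlap(a_id, b_id, strand, i, i + b_len, 0, b_len,
                   len(A), b_len, b_len, "b_contained")


def overlaps_from_paf(alignments: Iterable[PafAlignment],
                      max_overhang_bp: int = 1000,
                      max_overhang_ratio: float = 0.8) -> list[Overlap]:
    """Turn externally computed all-vs-all PAF alignments into classified
    overlaps (a = query, b = target)."""
    out = []
    for aln in alignments:
        kind = classify_overlap(aln, max_overhang_bp, max_overhang_ratio)
        out.append(Overlap(
            aln.query_id, aln.target_id, aln.strand,
            aln.query_start, aln.query_end, aln.target_start, aln.target_end,
            aln.query_len, aln.target_len, aln.block_len, kind))
    return out


def classify_overlap(aln: PafAlignment, max_overhang_bp: int = 1000,
                     max_overhang_ratio: float = 0.8) -> str:
    """Classify an alignment with the standard string-graph overhang rule.

    Flank lengths outside the aligned block decide the call: both flanks of
    one sequence small -> that sequence is contained; large unaligned
    overhang on both relevant flanks -> internal match (repeat-induced,
    unusable for layout); otherwise one of the four dovetail kinds follows
    from the strand and which ends are flush.
    """
    if aln.strand == "+":
        t_left, t_right = aln.target_start, aln.target_len - aln.target_end
    else:  # express target flanks in reverse-complement orientation
        t_left = aln.target_len - aln.target_end
        t_right = aln.target_start
    q_left, q_right = aln.query_start, aln.query_len - aln.query_end
    overhang = min(q_left, t_left) + min(q_right, t_right)
    allowance = min(max_overhang_bp, max_overhang_ratio * aln.block_len)
    if overhang > allowance:
        return "internal"
    if q_left <= t_left and q_right <= t_right:
        return "a_contained"
    if q_left >= t_left and q_right >= t_right:
        return "b_contained"
    if q_left > t_left:  # overlap sits on a's suffix
        return "a_suffix_b_prefix" if aln.strand == "+" else "a_suffix_brc_prefix"
    # overlap sits on a's prefix, i.e. the suffix of rc(a)
    return "arc_suffix_brc_prefix" if aln.strand == "+" else "arc_suffix_b_prefix"


def filter_overlaps(overlaps: Iterable[Overlap], min_internal_overlap: int,
                    ) -> tuple[list[Overlap], list[Overlap]]:
    """Drop self-loops, short overlaps (< ``min_internal_overlap``) and
    internal matches; dovetails and containments are returned separately
    (containments feed containment removal, not the graph)."""
    dovetails: list[Overlap] = []
    containments: list[Overlap] = []
    for ov in overlaps:
        if ov.a_id == ov.b_id:
            continue
        if ov.kind in CONTAINMENT_KINDS:
            containments.append(ov)
            continue
        if ov.length < min_internal_overlap or ov.kind == "internal":
            continue
        dovetails.append(ov)
    return dovetails, containments


# ---------------------------------------------------------------------------
# graph

class BidirectedOverlapGraph:
    """Two vertices per contig, a contig edge between them, and overlap
    edges typed by the four dovetail kinds.  Parallel overlap edges between
    the same vertex pair collapse to the largest overlap."""

    def __init__(self, contigs: Sequence[ReadRecord]):
        self.contigs: dict[str, ReadRecord] = {}
        for rec in contigs:
            if rec.read_id in self.contigs:
                raise ValueError(f"duplicate contig id {rec.read_id!r}")
            self.contigs[rec.read_id] = rec
        # overlap edges: canonical (sorted) vertex pair -> Overlap
        self.edges: dict[tuple[Vertex, Vertex], Overlap] = {}
        self.adj: dict[Vertex, set[Vertex]] = {
            (cid, side): set() for cid in self.contigs for side in "se"}

    @staticmethod
    def endpoints(ov: Overlap) -> tuple[Vertex, Vertex]:
        side_a, side_b = EDGE_ENDPOINTS[ov.kind]
        return (ov.a_id, side_a), (ov.b_id, side_b)

    def add_overlap(self, ov: Overlap) -> None:
        if ov.kind not in DOVETAIL_KINDS:
            raise ValueError(f"only dovetail overlaps enter the graph, got {ov.kind}")
        for cid in (ov.a_id, ov.b_id):
            if cid not in self.contigs:
                raise ValueError(f"overlap references unknown contig {cid!r}")
        if ov.a_id == ov.b_id:
            raise ValueError("self-loop overlap edges are not allowed")
        u, v = self.endpoints(ov)
        key = (u, v) if u <= v else (v, u)
        old = self.edges.get(key)
        if old is None or ov.length > old.length:
            self.edges[key] = ov
        self.adj[u].add(v)
        self.adj[v].add(u)

    def edge(self, u: Vertex, v: Vertex) -> Overlap:
        return self.edges[(u, v) if u <= v else (v, u)]


def build_graph(contigs: Sequence[ReadRecord],
                dovetail_overlaps: Iterable[Overlap]) -> BidirectedOverlapGraph:
    graph = BidirectedOverlapGraph(contigs)
    for ov in dovetail_overlaps:
        graph.add_overlap(ov)
    return graph


# ---------------------------------------------------------------------------
# traversal

def greedy_traverse(graph: BidirectedOverlapGraph) -> list[AssemblyPath]:
    """Read maximal super-contig paths off the graph greedily.

    Repeatedly: start from the vertex with the lowest number of edges
    (counting its contig edge and overlap edges to not-yet-consumed
    contigs; ties go to the longest contig, then lexicographic id, then the
    start vertex), traverse the contig edge first, then alternately follow
    the largest-overlap edge to an unconsumed contig and that contig's
    edge, until no overlap edge can be followed.  A contig is consumed by
    traversing its contig edge and excluded from all later paths, so every
    contig ends up in exactly one path (possibly a singleton).
    """
    consumed: set[str] = set()
    paths: list[AssemblyPath] = []

    def degree(v: Vertex) -> int:
        return 1 + sum(u[0] not in consumed for u in graph.adj[v])

    def start_key(v: Vertex) -> tuple:
        cid = v[0]
        return (degree(v), -len(graph.contigs[cid].sequence), cid,
                _SIDE_ORDER[v[1]])

    while len(consumed) < len(graph.contigs):
        candidates = [(cid, side) for cid in graph.contigs
                      if cid not in consumed for side in "se"]
        start = min(candidates, key=start_key)
        vertices: list[Vertex] = [start]
        members: list[tuple[str, str]] = []
        overlaps: list[Overlap] = []

        cur = start
        while True:
            cid, side = cur
            other = (cid, "e" if side == "s" else "s")
            members.append((cid, "+" if side == "s" else "-"))
            consumed.add(cid)
            vertices.append(other)
            cur = other
            nxt = _pick_edge(graph, cur, consumed)
            if nxt is None:
                break
            overlaps.append(graph.edge(cur, nxt))
            vertices.append(nxt)
            cur = nxt
        paths.append(AssemblyPath(vertices, members, overlaps))
    return paths


def _pick_edge(graph: BidirectedOverlapGraph, cur: Vertex,
               consumed: set[str]) -> Vertex | None:
    """Largest-overlap edge from ``cur`` to an unconsumed contig; ties by
    partner id, then partner side (start before end)."""
    best: Vertex | None = None
    best_key: tuple | None = None
    for v in graph.adj[cur]:
        if v[0] in consumed:
            continue
        key = (-graph.edge(cur, v).length, v[0], _SIDE_ORDER[v[1]])
        if best_key is None or key < best_key:
            best, best_key = v, key
    return best


# ---------------------------------------------------------------------------
# stitching and containment removal

def stitch(path: AssemblyPath, contigs: Mapping[str, ReadRecord],
           contig_id: str = "supercontig") -> SuperContig:
    """Spell the super-contig of a path.

    The first oriented contig is emitted whole; each subsequent oriented
    contig contributes its sequence from the end of the junction overlap
    (measured on its own coordinates) to its end, so every overlap region
    is kept exactly once, from the upstream contig.
    """
    if len(path.members) != len(path.overlaps) + 1:
        raise ValueError("path must alternate contig and overlap edges")
    parts: list[str] = []
    for idx, (cid, orient) in enumerate(path.members):
        seq = contigs[cid].sequence
        oriented = seq if orient == "+" else revcomp(seq)
        if idx == 0:
            parts.append(oriented)
            continue
        ov = path.overlaps[idx - 1]
        if cid not in (ov.a_id, ov.b_id):
            raise ValueError(f"junction overlap does not involve contig {cid}")
        used = ov.span_on(cid)
        if used > len(oriented):
            raise ValueError(
                f"overlap span {used} exceeds contig {cid} length {len(oriented)}")
        parts.append(oriented[used:])
    return SuperContig(contig_id, "".join(parts), path)


def remove_contained(contigs: Sequence[ReadRecord]) -> list[ReadRecord]:
    """Drop every contig whose sequence (or reverse complement) is an exact
    substring of a longer surviving contig; among identical sequences the
    lexicographically smallest id survives.  Deterministic."""
    survivors: list[ReadRecord] = []
    for rec in sorted(contigs, key=lambda r: (-len(r.sequence), r.read_id)):
        rc = revcomp(rec.sequence)
        if any(rec.sequence in s.sequence or rc in s.sequence for s in survivors):
            continue
        survivors.append(rec)
    # restore input order
    order = {r.read_id: i for i, r in enumerate(contigs)}
    return sorted(survivors, key=lambda r: order[r.read_id])


# ---------------------------------------------------------------------------
# node pipelines

def _contained_ids(containments: Iterable[Overlap],
                   contigs: Mapping[str, ReadRecord]) -> set[str]:
    """Contigs called contained in a strictly 'larger' partner (longer, or
    equal length with smaller id), so mutually contained identical contigs
    drop all but one."""
    dropped: set[str] = set()
    for ov in containments:
        inner, outer = ((ov.a_id, ov.b_id) if ov.kind == "a_contained"
                        else (ov.b_id, ov.a_id))
        li, lo = len(contigs[inner].sequence), len(contigs[outer].sequence)
        if lo > li or (lo == li and outer < inner):
            dropped.add(inner)
    return dropped


def assemble_node(child_contigs: Sequence[ReadRecord],
                  min_overlap: int,
                  max_mismatch_rate: float = 0.0,
                  min_output_len: int = 0,
                  id_prefix: str = "node") -> list[ReadRecord]:
    """One internal-node merge: overlap the (up to two) children's contigs,
    build the bidirected graph, traverse greedily, stitch, and remove
    contained sequences.  Empty input yields empty output."""
    if not child_contigs:
        return []
    by_id = {c.read_id: c for c in child_contigs}
    if len(by_id) != len(child_contigs):
        raise ValueError("duplicate contig ids across children")
    overlaps = find_overlaps_builtin(child_contigs, min_overlap,
                                     max_mismatch_rate)
    dovetails, containments = filter_overlaps(overlaps, min_overlap)
    dropped = _contained_ids(containments, by_id)
    kept = [c for c in child_contigs if c.read_id not in dropped]
    dovetails = [ov for ov in dovetails
                 if ov.a_id not in dropped and ov.b_id not in dropped]
    graph = build_graph(kept, dovetails)
    paths = greedy_traverse(graph)
    merged = [
        ReadRecord(f"{id_prefix}c{i}",
                   stitch(p, graph.contigs, f"{id_prefix}c{i}").sequence)
        for i, p in enumerate(paths)
    ]
    merged = remove_contained(merged)
    if min_output_len > 0:
        merged = [c for c in merged if len(c.sequence) >= min_output_len]
    return merged


def assemble_root(per_tree_roots: Sequence[Sequence[ReadRecord]],
                  root_min_overlap: int,
                  root_min_contig_len: int,
                  max_mismatch_rate: float = 0.0,
                  id_prefix: str = "final") -> list[ReadRecord]:
    """Final assembly step over the union of all tree roots with stronger
    parameters (longer overlaps, longer sequences), catching joins between
    reads mistakenly split across chromosomes by map errors.  Contigs
    shorter than ``root_min_contig_len`` are passed through unmerged but
    retained."""
    pool = [c for roots in per_tree_roots for c in roots]
    long_enough = [c for c in pool if len(c.sequence) >= root_min_contig_len]
    short = [c for c in pool if len(c.sequence) < root_min_contig_len]
    merged = assemble_node(long_enough, root_min_overlap, max_mismatch_rate,
                           id_prefix=id_prefix)
    out = merged + [ReadRecord(f"{id_prefix}_short_{c.read_id}", c.sequence)
                    for c in short]
    return out
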