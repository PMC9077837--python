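import itertools

import numpy as np
import pytest

from hgga.formats_io import PafAlignment, ReadRecord, revcomp
from hgga.overlap_core import (DOVETAIL_KINDS, EDGE_ENDPOINTS, Overlap,
                               assemble_node, assemble_root, build_graph,
                               classify_overlap, filter_overlaps,
                               find_overlaps_builtin, greedy_traverse,
                               remove_contained, stitch)
from conftest import random_dna


def rec(i, seq):
    return ReadRecord(i, seq)


KIND_OF = {("+", "+"): "a_suffix_b_prefix", ("+", "-"): "a_suffix_brc_prefix",
           ("-", "+"): "arc_suffix_b_prefix",
           ("-", "-"): "arc_suffix_brc_prefix"}


def brute_force_overlaps(contigs, min_overlap):
    """O(n^2 L^2) all-pairs, all-orientations suffix/prefix + containment
    scan by direct string comparison (independent of the seeded scanner).

    Dovetails are reported as (graph edge, length) since mirrored
    discoveries of one overlap collapse onto the same undirected edge;
    containments as (inner, outer, strand).
    """
    edges = {}
    containments = set()
    for a, b in itertools.permutations(contigs, 2):
        for ao in "+-":
            A = a.sequence if ao == "+" else revcomp(a.sequence)
            for bo in "+-":
                bseq = b.sequence if bo == "+" else revcomp(b.sequence)
                if ao == "+" and len(bseq) <= len(A):
                    if any(A[i:i + len(bseq)] == bseq
                           for i in range(len(A) - len(bseq) + 1)):
                        containments.add((b.read_id, a.read_id, bo))
                # longest proper suffix of oriented a == prefix of oriented b
                for L in range(min(len(A), len(bseq)) - 1,
                               min_overlap - 1, -1):
                    if A[len(A) - L:] == bseq[:L]:
                        sa, sb = EDGE_ENDPOINTS[KIND_OF[(ao, bo)]]
                        edge = frozenset([(a.read_id, sa), (b.read_id, sb)])
                        edges[edge] = max(edges.get(edge, 0), L)
                        break
    return edges, containments


def as_edges(overlaps):
    edges = {}
    containments = set()
    for o in overlaps:
        if o.kind == "b_contained":
            containments.add((o.b_id, o.a_id, o.strand))
        else:
            u, v = (o.a_id, EDGE_ENDPOINTS[o.kind][0]), \
                (o.b_id, EDGE_ENDPOINTS[o.kind][1])
            edge = frozenset([u, v])
            edges[edge] = max(edges.get(edge, 0), o.length)
    return edges, containments


def test_exact_dovetail_and_containment_examples():
    a = rec("a", "AAACCCGGGTTT")
    b = rec("b", "GGGTTTACGTAC")   # suffix of a == prefix of b, |Y| = 6
    c = rec("c", "CCGGG")          # substring of a
    ovs = find_overlaps_builtin([a, b, c], min_overlap=4)
    dove = [o for o in ovs if o.kind in DOVETAIL_KINDS
            and {o.a_id, o.b_id} == {"a", "b"}]
    assert any(o.a_id == "a" and o.kind == "a_suffix_b_prefix"
               and o.length == 6 for o in dove)
    cont = [o for o in ovs if o.kind == "b_contained" and o.b_id == "c"]
    assert cont and cont[0].a_id == "a"


def test_builtin_overlaps_match_brute_force():
    rng = np.random.default_rng(6)
    contigs = []
    for i in range(5):
        contigs.append(rec(f"c{i}", random_dna(rng, int(rng.integers(20, 60)))))
    # plant one known suffix-prefix overlap and one containment
    contigs[1] = rec("c1", contigs[0].sequence[-15:] + random_dna(rng, 30))
    contigs[3] = rec("c3", contigs[2].sequence[5:20])
    min_overlap = 8
    got = as_edges(find_overlaps_builtin(contigs, min_overlap))
    expected = brute_force_overlaps(contigs, min_overlap)
    assert got == expected


def paf(qlen, qs, qe, strand, tlen, ts, te, block=None):
    block = block if block is not None else max(qe - qs, te - ts)
    return PafAlignment("a", qlen, qs, qe, strand, "b", tlen, ts, te,
                        block, block)


@pytest.mark.parametrize("aln,kind", [
    # flush ends
    (paf(100, 50, 100, "+", 200, 0, 50), "a_suffix_b_prefix"),
    (paf(100, 50, 100, "-", 200, 150, 200), "a_suffix_brc_prefix"),
    (paf(100, 0, 50, "-", 200, 0, 50), "arc_suffix_b_prefix"),
    (paf(100, 0, 50, "+", 200, 150, 200), "arc_suffix_brc_prefix"),
    # containments
    (paf(100, 0, 100, "+", 300, 100, 200), "a_contained"),
    (paf(300, 100, 200, "+", 100, 0, 100), "b_contained"),
    # mid-to-mid with large overhangs on both sides
    (paf(10_000, 4000, 6000, "+", 10_000, 4000, 6000), "internal"),
])
def test_classify_overlap_cases(aln, kind):
    assert classify_overlap(aln) == kind


def test_classify_overhang_allowance_arithmetic():
    # overhang = min(50, 40) + min(30, 60) = 70 <= min(1000, 0.8*2000)
    aln = paf(2080, 50, 2050, "+", 2100, 40, 2040, block=2000)
    assert classify_overlap(aln) == "a_suffix_b_prefix"
    # tiny allowance forces internal
    assert classify_overlap(aln, max_overhang_bp=10) == "internal"


def ov(a, b, kind, length=50, a_len=1000, b_len=1000):
    return Overlap(a, b, "+", 0, length, 0, length, a_len, b_len, length, kind)


def test_filter_short_overlap_strict_threshold():
    ovs = [ov("a", "b", "a_suffix_b_prefix", length=9999),
           ov("a", "c", "a_suffix_b_prefix", length=10_000),
           ov("a", "a", "a_suffix_b_prefix", length=20_000),
           ov("a", "d", "b_contained", length=500),
           ov("a", "e", "internal", length=20_000)]
    dove, cont = filter_overlaps(ovs, 10_000)
    assert [(o.a_id, o.b_id) for o in dove] == [("a", "c")]
    assert [(o.a_id, o.b_id) for o in cont] == [("a", "d")]


def test_filter_matches_predicate_oracle():
    rng = np.random.default_rng(7)
    kinds = list(DOVETAIL_KINDS) + ["a_contained", "b_contained", "internal"]
    ovs = [ov(f"x{rng.integers(5)}", f"x{rng.integers(5)}",
              kinds[rng.integers(len(kinds))], length=int(rng.integers(1, 200)))
           for _ in range(200)]
    dove, cont = filter_overlaps(ovs, 100)
    assert dove == [o for o in ovs if o.a_id != o.b_id
                    and o.kind in DOVETAIL_KINDS and o.length >= 100]
    assert cont == [o for o in ovs if o.a_id != o.b_id
                    and o.kind in ("a_contained", "b_contained")]


def test_graph_unknown_contig_rejected():
    with pytest.raises(ValueError, match="unknown contig"):
        build_graph([rec("a", "ACGT")], [ov("a", "zz", "a_suffix_b_prefix")])


def test_graph_parallel_edges_collapse_to_longest():
    contigs = [rec("a", "A" * 100), rec("b", "C" * 100)]
    g = build_graph(contigs, [ov("a", "b", "a_suffix_b_prefix", length=10),
                              ov("a", "b", "a_suffix_b_prefix", length=30)])
    assert len(g.edges) == 1
    assert next(iter(g.edges.values())).length == 30


def test_endpoint_mapping_involution():
    """(u,v) and the mirrored (v,u) call give the same undirected edge."""
    mirror = {"a_suffix_b_prefix": "arc_suffix_brc_prefix",
              "a_suffix_brc_prefix": "a_suffix_brc_prefix",
              "arc_suffix_b_prefix": "arc_suffix_b_prefix",
              "arc_suffix_brc_prefix": "a_suffix_b_prefix"}
    for kind, dual in mirror.items():
        sa, sb = EDGE_ENDPOINTS[kind]
        da, db = EDGE_ENDPOINTS[dual]
        assert {("u", sa), ("v", sb)} == {("v", da), ("u", db)}


def fig3_graph(len_c=80):
    """Overlaps as in the worked three-contig example: a-b forward dovetail,
    b's suffix against the reversed c."""
    rng = np.random.default_rng(8)
    a_seq = random_dna(rng, 100)
    b_seq = a_seq[-30:] + random_dna(rng, 70)
    c_seq = revcomp(b_seq[-25:] + random_dna(rng, len_c - 25))
    contigs = [rec("a", a_seq), rec("b", b_seq), rec("c", c_seq)]
    overlaps = find_overlaps_builtin(contigs, min_overlap=20)
    dove, _ = filter_overlaps(overlaps, 20)
    return build_graph(contigs, dove), contigs


def test_three_contig_alternating_path():
    g, contigs = fig3_graph()
    paths = greedy_traverse(g)
    assert len(paths) == 1
    assert paths[0].vertices == [("a", "s"), ("a", "e"), ("b", "s"),
                                 ("b", "e"), ("c", "e"), ("c", "s")]
    assert paths[0].members == [("a", "+"), ("b", "+"), ("c", "-")]
    sc = stitch(paths[0], {c.read_id: c for c in contigs})
    total = sum(len(c.sequence) for c in contigs)
    assert len(sc.sequence) == total - 30 - 25


def test_isolated_contig_singleton_path():
    g = build_graph([rec("u", "ACGTACGT")], [])
    (path,) = greedy_traverse(g)
    assert path.vertices == [("u", "s"), ("u", "e")]
    assert path.members == [("u", "+")]


def test_paths_partition_contigs():
    rng = np.random.default_rng(9)
    for _ in range(30):
        n = int(rng.integers(1, 7))
        contigs = [rec(f"c{i}", "A" * int(rng.integers(50, 150)))
                   for i in range(n)]
        ovs = []
        for _ in range(int(rng.integers(0, 10))):
            i, j = rng.choice(n, 2, replace=False) if n > 1 else (0, 0)
            if i == j:
                continue
            ovs.append(ov(f"c{i}", f"c{j}",
                          DOVETAIL_KINDS[rng.integers(4)],
                          length=int(rng.integers(10, 60)),
                          a_len=len(contigs[i].sequence),
                          b_len=len(contigs[j].sequence)))
        g = build_graph(contigs, ovs)
        paths = greedy_traverse(g)
        seen = [m[0] for p in paths for m in p.members]
        assert sorted(seen) == sorted(c.read_id for c in contigs)
        for p in paths:
            assert len(p.members) == len(p.overlaps) + 1


def test_stitch_exact_concatenation():
    a = rec("a", "AAAACCCC")
    b = rec("b", "CCCCGGGG")
    ovs = find_overlaps_builtin([a, b], 4)
    dove, _ = filter_overlaps(ovs, 4)
    g = build_graph([a, b], dove)
    (path,) = greedy_traverse(g)
    sc = stitch(path, g.contigs)
    assert sc.sequence in ("AAAACCCCGGGG", revcomp("AAAACCCCGGGG"))
    assert len(sc.sequence) == 8 + 8 - 4


def test_stitch_singleton_unchanged():
    g = build_graph([rec("u", "ACGTAC")], [])
    (path,) = greedy_traverse(g)
    assert stitch(path, g.contigs).sequence == "ACGTAC"


def test_remove_contained():
    rng = np.random.default_rng(10)
    big = random_dna(rng, 200)
    contigs = [rec("a", big), rec("b", big[50:120]),
               rec("c", revcomp(big[10:90])), rec("d", random_dna(rng, 60)),
               rec("e", big)]
    out = remove_contained(contigs)
    assert [c.read_id for c in out] == ["a", "d"]
    assert remove_contained([rec("x", "ACGT")]) == [rec("x", "ACGT")]


def test_assemble_node_merges_two_tiling_children():
    rng = np.random.default_rng(11)
    segment = random_dna(rng, 500)
    left = rec("L", segment[:300])
    right = rec("R", segment[250:])
    out = assemble_node([left, right], min_overlap=30, id_prefix="n")
    assert len(out) == 1
    assert out[0].sequence in (segment, revcomp(segment))


def test_assemble_node_no_cross_overlap_passthrough():
    rng = np.random.default_rng(12)
    a, b = rec("a", random_dna(rng, 200)), rec("b", random_dna(rng, 200))
    out = assemble_node([a, b], min_overlap=30)
    assert sorted(c.sequence for c in out) == sorted([a.sequence, b.sequence])


def test_assemble_node_single_child_dedups_containment():
    rng = np.random.default_rng(13)
    big = random_dna(rng, 400)
    out = assemble_node([rec("a", big), rec("b", big[100:200])],
                        min_overlap=30)
    assert [c.sequence for c in out] == [big]
    assert assemble_node([], 30) == []


def test_assemble_root_threshold_and_passthrough():
    rng = np.random.default_rng(14)
    segment = random_dna(rng, 2000)
    a = rec("a", segment[:1200])
    b = rec("b", segment[1100:])   # overlap 100
    tiny = rec("t", random_dna(rng, 80))
    # overlap 100 < root_min_overlap 150: not merged
    out = assemble_root([[a], [b, tiny]], root_min_overlap=150,
                        root_min_contig_len=500)
    assert sorted(len(c.sequence) for c in out) == sorted(
        [1200, 900, 80])
    # relaxed threshold: merged, tiny passed through
    out = assemble_root([[a], [b, tiny]], root_min_overlap=50,
                        root_min_contig_len=500)
    assert sorted(len(c.sequence) for c in out) == [80, 2000]


def test_supercontigs_are_truth_substrings(tiny_fixture):
    """Error-free leaf reads stitch into exact substrings of the truth."""
    fx = tiny_fixture
    chrom_seqs = list(fx.genome.chromosomes.values())
    reads = [r.record for r in fx.reads[:40]]
    out = assemble_node(reads, fx.config.min_read_overlap, id_prefix="t")
    assert out
    for contig in out:
        assert any(contig.sequence in s or revcomp(contig.sequence) in s
                   for s in chrom_seqs)
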