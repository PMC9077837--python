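# Methods

This note documents the model behind `hgga`, the parameters that matter,
the numerical conventions, and what the synthetic test data does and does
not demonstrate.

## Model and assumptions

The guiding idea is that any long-range data source inducing an approximate
linear order on reads can drive a divide-and-conquer assembly.  For genetic
linkage maps the order comes for free: markers are grouped into chromosomes
and ordered bins, and a read inherits the bins of the markers its
draft-assembly alignment overlaps.  The method assumes:

- the map's bin order within each chromosome is correct (intra-bin marker
  order is not used);
- the draft assembly is good enough to place reads locally — it is used
  *only* to anchor markers and localize reads, never as an assembly
  backbone;
- reads are long relative to marker spacing, so most alignments overlap at
  least one marker (where they do not, closest-marker coloring takes over);
- the per-leaf read sets are small enough that a simple
  overlap-layout assembler handles them, and leaves overlap enough
  (half a preliminary leaf on each side) that adjacent leaf assemblies
  share sequence to merge on.

Reads whose best alignment overlaps markers from more than one chromosome
(chimeric draft contigs, misalignments) are demoted to unplaced and
counted in the log rather than guessed at.  Unplaced reads are excluded
from the hierarchy; `emit_unplaced` writes them to a side FASTA.

## Parameters

| parameter | default | unit | why |
|---|---|---|---|
| `min_leaf_fraction` | 0.015 | fraction of all reads | minimum leaf size; around 1.5 % of the reads balances per-leaf coverage against cluster granularity, denser maps/higher coverage tolerate smaller leaves |
| `min_internal_overlap` | 10 000 | bp | overlaps shorter than this (strict `<`) are discarded at internal nodes; corrected multi-kbp contigs support demanding long overlaps |
| `root_min_overlap` | 2 × internal | bp | the root step joins across trees, where spurious overlaps are likelier; "stronger parameters" quantified as doubling |
| `root_min_contig_len` | 50 000 | bp | contigs shorter than this skip the root merge but are retained |
| `min_read_overlap` | 2 000 | bp | leaf-scale overlap floor for the builtin read assembler |
| `coloring_mode` | `overlap` | — | `overlap` falls back to closest-marker for marker-free alignments; `closest` always uses nearest markers |
| `closest_tolerance_bp` | 100 | bp | "roughly equidistant": markers within d* + tolerance of the alignment join the color |
| `bin_gap_from_first` | true | — | map simulation: the 200 bp bin gap is measured from the bin's first marker (bounded bin span); the previous-marker convention is the alternative reading and stays available |
| `merge_small_tail_leaf` | true | — | a trailing leaf under half the minimum merges into its predecessor |

All length thresholds scale down together for small test genomes; the
shipped fixture presets set internal overlaps to 500 bp on 100 kb
chromosomes.

## Numerical and tie-breaking conventions

- Coordinates are 0-based half-open everywhere (PAF convention), including
  the map TSV.
- Marker-to-alignment distance is `max(0, start − pos, pos − (end − 1))` on
  the draft contig.
- A read with several bins is *owned* by its minimum bin for packing; the
  four-block leaf overlap covers junction reads.  Sorting is a counting
  sort over bins, ties broken by read id.
- Preliminary leaves split as first ⌈n/2⌉ / rest; an odd node out during
  tree pairing is promoted unchanged, keeping leaf order.
- Overlap classification uses the standard string-graph overhang rule with
  allowance `min(1000 bp, 0.8 × block length)`; both knobs are
  configurable.
- Traversal start vertex: lowest degree, then longest contig, then
  lexicographic id, then the start-side vertex.  Edge choice: largest
  overlap, then partner id, then partner start side.  These rules also
  break pure cycles (all degrees equal) deterministically.  Paths extend in
  one direction from the start vertex, per the greedy rule's literal
  statement; a path started mid-component may therefore be non-maximal,
  and the leftovers become their own paths.
- Parallel overlap edges between one vertex pair collapse to the largest
  overlap; mirrored discoveries of the same overlap collapse onto the same
  undirected edge.
- Among mutually contained (identical) contigs the lexicographically
  smallest id survives.
- N50/NG50 use ≥: reaching exactly half counts.  NG50 is reported 0 when
  the assembly is shorter than half the genome.
- Degenerate inputs: empty overlap sets yield isolated contig-edge paths;
  an empty child set yields an empty node; a chromosome with fewer reads
  than the minimum leaf size becomes a single leaf with a warning.

## The synthetic data generator

`synthetic_data` emulates the whole input side: i.i.d.-base multi-chromosome
genomes with optionally planted repeats, uniformly sampled reads with exact
truth coordinates (lengths truncated-normal; reads overhanging chromosome
ends are clipped, no shorter than 500 bp, which keeps coverage even at the
ends), a draft made by cutting the truth at random positions with exact
marker liftover, and a map simulated by uniform marker placement, 20 bp
predecessor pruning, and 200 bp binning.  Read-to-draft alignments are
emitted as PAF directly from truth coordinates, so no aligner is needed.

Error-free reads are the deliberate default: the package's contribution is
the clustering and merge machinery, which exact data exercises exactly.
What passing fixtures do **not** show: behavior under real PacBio error
profiles (indel-dominated), haplotype divergence, coverage biases, or map
genotyping errors.  Noisy substitution reads exist for smoke-testing the
external-assembler adapter; indel noise and consensus polishing are
delegated to external leaf assemblers via the command template.

Fixture presets: `tiny` (1 × 20 kb, ~200 reads) for fast tests, `standard`
(2 × 100 kb, 30×, ~800 reads, marker per ~500 bp) for end-to-end checks,
`repeat-rich` (standard plus a 5 kb cross-chromosome repeat).  These sizes
were chosen as the smallest scale at which every stage — multi-chromosome
trees of height ≥ 5, draft breaks, bin packing — is non-trivially
exercised.

## Design choices where the design was open

- **One best alignment per read** (most matching bases) drives coloring;
  secondary alignments are ignored.
- **Built-in overlapper**: exact prefix-seed scanning with full
  verification and an optional Hamming mismatch allowance.  It is the
  engine for error-free and corrected sequence, not a general noisy-read
  aligner; external PAF is the escape hatch.
- **Leaf assembler**: the builtin mode reuses the internal-node engine at
  read scale rather than reimplementing a production string-graph cleaner
  (transitive reduction, tips, bubbles are out of scope); real read data
  should use the external adapter (e.g. miniasm + Racon).
- **Containment removal** is exact-substring based, matching the
  error-free contract of the builtin engine.
- **Root passthrough**: sub-threshold contigs are retained verbatim rather
  than containment-checked against the merged set, reading "passed through
  unmerged" literally.

## Limitations

- Exact-match machinery (builtin overlapper, evaluation locator) does not
  tolerate indels; noisy pipelines must bring an external aligner and
  assembler.
- Coloring trusts the map: systematically misplaced markers translate into
  misclustered reads; only cross-chromosome conflicts are detected.
- The greedy traversal is not globally optimal; an adversarial overlap
  graph can make it take a locally largest overlap that a global layout
  would avoid.  Containment removal after stitching recovers most such
  cases on clean data.
- Evaluation metrics are fixture-mode re-implementations of the standard
  definitions (N50/NG50, genome fraction, misjoins, reads mapped by
  containment); they are not a substitute for full external evaluators on
  real data.
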