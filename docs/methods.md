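# Methods

## Problem and approach

`ppibridge` implements a guilt-by-association candidate-gene discovery
protocol for monogenic diseases with many causal genes. The premise is that
genes converging on one disease phenotype form a disease module: a connected
neighborhood of the protein-interaction network (PIN). Given a curated list of
known causal genes and a confidence-scored undirected PPI edge table, the
pipeline

1. builds a thresholded PPI graph,
2. classifies input genes by connectivity — **Group A** (directly interacting
   with another input gene), **Group B** (connectable to the module through a
   single intermediate), **Group C** (unbridgeable),
3. selects exactly one **Group D** intermediate (bridge) per Group B gene by a
   confidence-based score; these intermediates are the proposed novel
   candidate genes,
4. propagates cellular-localization group labels (in the retinal preset:
   1 = RPE, 2 = photoreceptor outer segment, 3 = connecting cilium,
   4 = nucleus) from a seed assignment by iterated PPI-count majority, and
5. summarizes inter/intragroup connectivity as a symmetric 4×4 edge-count
   matrix.

## Network model

The graph is simple and undirected. Each edge carries one combined confidence
in [0, 1]; STRING-style integer scores (0–999) are divided by 1000 on read.
Duplicate edge rows — including the reversed orientation that STRING flat
files always list — are merged keeping the **maximum** confidence, a
conservative, deterministic union of evidence channels. Self-loops are dropped
at parse time. Edges below the retention threshold are removed at
construction; their endpoints are kept as isolated declared nodes.

**Threshold.** Default 0.400, STRING's "medium confidence" convention. It is
exposed on every command (`--threshold`) and recorded in the run manifest;
raising it can only delete edges (monotonicity is property-tested).

**Identifiers.** Gene symbols are uppercased and stripped before any
comparison (symbols are case-insensitive in practice and curated lists mix
cases). STRING protein IDs are handled through an explicit alias map
(2-column TSV, chains flattened, cycles rejected) rather than hard-coded ID
syntax; the alias step reports renamed and unrecognized genes separately, and
recognized + unrecognized always partition the input.

## Bridge selection

The *main component* is the largest connected component of the subgraph
induced on Group A (size ties go to the component containing the
lexicographically smallest symbol). For a disconnected gene *b*, valid bridge
candidates are exactly its one-hop neighbors outside the input list that also
have at least one edge into the main component. Each candidate is scored; the
default strategy is the additive two-leg score

```
score(c) = conf(c, b) + max over m in main of conf(c, m)
```

the simplest monotone combination of the two legs every bridge must have.
Alternatives are pluggable (`--score-strategy`): `all_links_sum` (rewards
many anchors in the core) and `min_leg` (a bridge is only as good as its
weaker leg). Ties break by more links into the main component, then the
lexicographically smaller symbol — selection is fully deterministic.
Candidates are one-hop only (no multi-hop Steiner bridging), the anchor must
be in the *main* component (the goal is one network, not enlarging minor
fragments), and distinct B genes may share an intermediate, which keeps the
augmented map minimal. Genes with no valid candidate go to Group C. On graphs
of ≤ 50 nodes the selection is verified against exhaustive enumeration over
all nodes.

## Localization label propagation

Rounds are **batch-synchronous**: every unassigned gene is evaluated against
the assignment frozen at round start, so the result is independent of gene
enumeration order (property-tested). A gene with at least one edge to an
assigned gene joins the group with the most such edges; a count tie is broken
by the larger sum of edge confidences; a residual tie defers the gene one
round and, if it persists, forces the lowest tied group index with a logged
warning. Edges count toward a group for *all* its assigned members (seeds and
previously assigned genes alike), so groups expand round by round. Seeds are
never reassigned. Genes that never acquire an edge into any assigned group
terminate the iteration as reported `unassigned` — they are not forced into a
group.

In the full protocol the propagation universe includes the selected
intermediates: an isolated gene's only route to an assigned neighbor can run
through its bridge, so labels must flow across bridges for every gene to be
sorted. After propagation, each intermediate's label is overridden by
inheritance: it is placed with the group of its paired disconnected gene
(lexicographically smallest partner if shared, with a warning). Its recorded
assignment round is its partner's, since placement is inheritance, not a
propagation step.

## Connectivity matrix

Each undirected edge whose endpoints are both assigned contributes exactly
once: to the diagonal cell of its group if intragroup, otherwise to the
symmetric pair of off-diagonal cells. The lower-triangular total (diagonal
included) therefore equals the number of edges among assigned genes — a
conservation identity checked against a raw edge scan on every fixture.
Because it is ambiguous whether edges incident to intermediates belong in the
group totals, both are reported: intermediates contribute to `counts` through
their inherited group, and `intermediate_links` separately counts, per group,
the gene-side incidences of edges touching an intermediate.

## Synthetic scenarios

The generator emulates the structure the method assumes: localization groups
are dense interaction blocks (planted-partition topology, `p_intra` ≫
`p_inter`), a subset of block genes are disease genes, and a few disease genes
are isolated — zero edges to any other disease gene — each wired to planted
bridge genes that also anchor into the disease-gene core.

Default scenario (chosen once to mirror the retinitis pigmentosa study
conditions structurally): 4 blocks of 60/55/55/55 genes holding 38/37/37/37
disease genes (149 connected), 10 isolated disease genes with one bridge each
(159 input genes total), `p_intra = 0.30`, `p_inter = 0.02`, confidences
uniform on [0.40, 0.95], seed fraction 0.20 (≈ the 30-of-149 seed ratio of
the retinal preset). Planted confidences are drawn at or above the default
threshold so planted structure survives thresholding. A deterministic
confidence-scored chain over each block's disease genes guarantees each
block's disease genes form one connected component regardless of random
draws; bridges anchor into the block with the most disease genes, which is
the main component under the classifier's tie-break. With one bridge per
isolated gene the planted bridge is the unique valid candidate, so recovery
must be exact — the basis of the recovery tests.

What the generator does **not** emulate: scale-free degree distributions,
STRING's evidence-channel structure, hub proteins shared across blocks, and
annotation errors in the seed file. Passing tests therefore demonstrate
correctness of the algorithmic contract, not biological performance on real
interactomes.

Problem sizes in the test suite and acceptance script (200 random graphs of
≤ 50 nodes, 100 noise-free recovery replicates, 10 replicates per noise level
for the monotonicity check, 20 replicates for label recovery) were chosen as
the package's own desk-scale battery; the whole suite runs in seconds.

## Numerical and degenerate-input choices

* Component ordering, candidate ordering and all tie-breaks are
  deterministic, so reruns on identical inputs produce byte-identical
  artifacts (the run manifest's timestamp is the only non-input field).
* Confidence-sum ties in propagation use `numpy.isclose` to avoid splitting
  on floating-point dust.
* Empty gene lists, malformed scores (rejected with line numbers), scores
  outside the declared scale, self-loops, alias cycles, conflicting seed
  assignments, and unknown genes all fail fast with messages naming the
  offending line or gene.
* An input gene recognized by the edge table but with no retained edges is
  classified like any disconnected gene and will land in Group C if no
  candidate exists.

## Reproducing the published RP run (external data)

The published instance of this protocol used the STRING v11 human network and
the RetNet retinitis pigmentosa gene list, which are external downloads and
are not shipped. To reproduce it: (1) obtain the RetNet RP gene list
(161 symbols) and the STRING v11 `9606.protein.links.txt` plus
`9606.protein.aliases.txt`; (2) derive a symbol-level alias map (including
the two renamed symbols, SC5DL→SC5D and C5orf4→FAXDC2); (3) run

```
ppibridge classify --genes retnet_rp.txt --edges 9606.protein.links.txt \
    --dialect string_links --aliases aliases.tsv --threshold 0.4 \
    --out-prefix rp_run
```

Expected headline counts at that pinned version: 159 recognized genes, 149
directly connected, 10 disconnected, 10 intermediates. The seed localization
file for the grouping step (30 genes in four compartment groups) must be
assembled from its literature source — it is not reprinted here; a template
ships in `examples/`.

## Limitations

* The bridge score is a design choice; the original protocol's scoring rule
  is underdetermined beyond "confidence levels drive the pairing", so three
  strategies are exposed and the default is the simplest two-leg sum.
* One-hop bridging only: a gene two hops from the module is Group C here.
* Localization propagation treats the seed assignment as ground truth and has
  no confidence or stability measure; labels from low-degree genes rest on
  very few edges.
* Connectivity-matrix semantics for intermediate-incident edges are reported
  both ways (see above) because the convention is ambiguous.
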