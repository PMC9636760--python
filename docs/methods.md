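# Methods

This note records the models, parameter choices and numerical decisions
behind `chemotax`, and what the synthetic benchmarks do and do not
demonstrate.

## Similarity model

Compounds are set-valued fingerprints: finite sets of integer feature IDs.
When structures are supplied (MOL/SDF V2000), features are topological
atom pairs — atom-type pairs keyed by their bond-path separation — computed
with RDKit's atom-pair generator at its defaults; the pipeline is equally
defined over any deterministic set-valued fingerprint supplied as a table,
because the Tanimoto coefficient only sees sets. Different toolkits
enumerate atom-pair features differently, so feature-level parity across
backends is deliberately not a goal; all downstream results depend on the
fingerprints only through pairwise Tanimoto values.

The network keeps edges with Tanimoto **strictly greater** than the
cut-off (default 0.85). The comparison is exact: with threshold p/q as a
rational from its decimal string, a pair enters iff
`|A∩B| * q > p * |A∪B|` in integer arithmetic. A pair whose coefficient
equals the cut-off (e.g. 17/20 at 0.85) is therefore excluded on every
platform, and edge sets are bit-stable. A secondary "reporting floor"
(default 0.7) controls the pair table written alongside the network.

All C(n, 2) pairs are evaluated densely. The intended scale is hundreds of
compounds, where the quadratic loop costs milliseconds; no similarity
index is used.

The degree distribution's power-law slope is ordinary least squares of
log10(count) on log10(degree) over degrees ≥ 1 — the simple fit network
analysis tools report — not a maximum-likelihood exponent. It is reported
as absent when fewer than two distinct positive degrees exist (e.g. when
the network is a union of equal-size cliques).

## Density clustering

Definitions, for cluster k with node set N_k and internal edge count |E_k|:

- density `d_k = |E_k| / (|N_k|(|N_k|-1)/2)`;
- cluster property of candidate n: `cp_nk = |E_nk| / (d_k * |N_k|)`, with
  |E_nk| the number of edges between n and cluster members.

Defaults: `cp_in = 0.5`, `d_in = 0.7`, minimum cluster size 2, overlapping
mode on.

The published description of this family of algorithms fixes the scoring
formulas and thresholds but leaves growth details open; the following
reconstruction is fixed here and pinned by tests:

- **Seeding.** The unclustered node of highest degree; ties break to the
  lexicographically smallest ID.
- **Bootstrap.** cp is undefined for a single edgeless node, so a new
  cluster starts as the seed plus its highest-degree neighbour (density 1
  for any connected pair).
- **Growth.** Candidates are the cluster's outside neighbours, ranked by
  descending |E_nk|, then degree, then ID. The best candidate with
  `cp_nk >= cp_in` *and* post-admission density `>= d_in` is added; the
  scan restarts after each admission and growth stops when no candidate
  qualifies. cp is evaluated against the cluster *before* insertion.
- **Overlap.** Emitted-cluster nodes are barred from future seeding but
  stay in the graph and may be absorbed into later clusters; non-overlap
  mode removes them outright. Termination holds because every iteration
  retires at least the seed.
- **Floors.** Clusters that stall below the minimum size are discarded and
  their seed retired as a single node. Nodes in no cluster are returned as
  singletons, so clusters plus singletons always cover the node set.

An independent verifier (`dpcluso.verify_clusters`) recounts |E_k| and
d_k from the input graph for every emitted cluster; the test suite runs it
on random graphs so the emission contract holds regardless of growth
details.

## Species classification

`build_matrix` supports two readings of "species contains group k":
`member` (≥ 1 compound of the group; default) and `pair` (≥ 2 compounds,
the strictly literal reading, under which single-representative species
drop out). The column universe is the emitted clusters plus one column per
unclustered network compound by default, or clusters only; both choices
are explicit because collapsing compounds into groups is lossy and the
right universe depends on how much signal the singletons carry.

Distances between binary rows are Euclidean, i.e. the square root of the
Hamming distance. Linkage is UPGMA (`average`) by default, with
`complete` and `ward` available. Species are sorted by ID before linkage,
which makes the merge order — including tie resolution inside scipy —
deterministic and invariant to input order; labels from a k-cut are
renumbered in first-seen order. Cuts use the merge-count definition (the
state after n − k merges), so exactly k non-empty clusters result even
with tied heights. Clades are the 3-cut by default.

Newick export places an internal node merging at height h at elevation
h/2, so leaf-to-leaf path lengths equal cophenetic heights exactly
(round-tripped through an independent parser to 1e-9 in tests).

## Pathway co-localization

The co-localization fraction is compound-denominated: among clustered
compounds that appear in the mapping, the fraction that share at least one
pathway with at least one *other* mapped compound of the same cluster.
A variant divides by all clustered compounds (`denominator="all"`), and a
cluster-denominated variant reports the fraction of clusters (with any
mapped member) in which some pathway holds ≥ 2 members. The statistic is
undefined (returned as `None`) when no compound is mapped. ID conversion
against external services is out of scope: the mapping table is an input.

## Synthetic benchmark

The generator emulates the statistical structure the analysis assumes:
structurally coherent compound groups and clade-specific metabolite
content.

- **Fingerprints.** Group g owns a base set B_g of size F
  (`fingerprint_size`, default 64): s features shared by all groups plus
  F − s group-private ones. Each member compound copies B_g and swaps m
  features for fresh compound-private IDs, keeping |fingerprint| = F.
  Closed forms drive the design: within-group Tanimoto
  ≥ (F − 2m)/(F + 2m) and between-group Tanimoto ≤ s/(2F − s). m is the
  largest swap count meeting the within-group target (default 0.90 → m=1,
  realised similarity ≈ 0.94) and s the largest shared pool under the
  between-group cap (default 0.30 → s=29, realised ≈ 0.29). Both bounds
  are deterministic, not merely expected, which is why planted groups are
  exact cliques at the 0.85 cut-off and recovery can be required exactly.
- **Relations.** Clade c's profile is `groups_per_clade` groups
  (consecutive blocks, disjoint at the defaults). Each species draws
  `metabolites_per_species` (default 6) distinct compounds from its
  profile and, with probability `noise_rate` (default 0.05), one
  off-profile compound. Every species has ≥ 2 compounds by construction
  unless `allow_filter_victims` plants single-compound species for
  testing the filter.
- Defaults: 4 groups × 10 compounds, 2 clades × 20 species. All
  randomness flows from one integer seed through separate named streams,
  so outputs are byte-identical per seed.

What passing these benchmarks does *not* show: real fingerprints are not
constant-cardinality, real structural families are not equidistant
near-cliques, similarity does not separate this cleanly around the
cut-off, and real species content is not an i.i.d. draw from a clade
profile. The benchmarks validate the algorithms' correctness and the
pipeline's contracts, not the taxonomic signal of any real dataset.
Dataset-level counts from real species–metabolite databases depend on the
database export and curation and are supported as pipeline outputs, not as
test expectations.

## Problem sizes

Tests and the acceptance script run at desk scale: 40–80 compounds,
40–60 species, 10–20 seeds per recovery experiment — sizes at which the
exact O(n²) pair evaluation and O(n³) linkage are instantaneous while
still exercising every code path.

## Known limitations

- Hashed/folded bit-vector fingerprints and similarity measures other than
  Tanimoto are out of scope.
- The clustering reconstruction above is one defensible reading of the
  published parameterisation; byte-parity with any particular historical
  implementation's tie-breaking is not claimed.
- Edges are unweighted once thresholded; weighted-density clustering is
  not implemented.
- No statistical enrichment (p-values) for pathways — only descriptive
  co-localization.
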