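# Methods

## Model and procedure

`hicenclave` treats one chromosome's Hi-C contact map as a dense
symmetric weighted graph over equally sized genomic bins and extracts a
hierarchy of preferentially self-interacting clusters ("enclaves") by
recursive spectral bisection.  The assumptions are minimal: contacts
are non-negative, symmetric, and meaningful after per-locus coverage
correction; cluster structure expresses itself as blocks of elevated
contact frequency, which need not be contiguous along the genome.

### Normalization

* **Balancing.**  Row sums are equalized by symmetric diagonal scaling
  `diag(x) W diag(x)`, found by a Sinkhorn–Knopp-style fixed-point
  iteration (tolerance 1e-8 on the relative row-sum spread, at most
  1000 iterations; total matrix weight preserved).  This has the same
  fixed point as Newton-type Knight–Ruiz solvers on strictly positive
  matrices and is simpler at the matrix sizes the package targets.
  Bins with zero total raw weight are unmappable and dropped before
  balancing.
* **Box–Cox.**  A chromosome-specific exponent λ is chosen by maximum
  profile log-likelihood over the grid [−2, 2] in steps of 0.05,
  fitted on the strictly positive upper-triangle entries (each
  symmetric pair counted once).  Zeros encode absent contacts and are
  left at zero — Box–Cox is undefined there and a pseudo-count would
  invent contacts.  For λ ≤ 0 the transform can be negative; all
  transformed entries are then shifted by `−min + ε`
  (ε ≈ √machine-epsilon scaled) so downstream graph weights stay
  non-negative.  The shift preserves order; spectral bisection is
  invariant to the overall scale.

### Bisection and classification

The random-walk normalized Laplacian `L = I − D⁻¹W` is used throughout;
degrees include the diagonal (self-contact) weight.  Eigenpairs are
computed via the similar symmetric form `I − D^(−1/2) W D^(−1/2)`
(dense below 500 loci, sparse shift-invert above; tolerance 1e-10), and
the eigenvector sign is canonicalized on its first nonzero coordinate
so runs are platform-stable.  The Fiedler coordinates are clustered by
2-means with five distinct seeds derived from one master seed
(default 1234); run labels are aligned by centroid order and each locus
takes its majority label, ties going to the nearer mean centroid.  In
1-D each k-means cluster is an interval containing an extreme
coordinate, so both consensus parts are always non-empty.

The expansion metric follows the ordered-pair convention literally: the
numerator sums `w(x, y)` over C₁ × C₂ (each cross edge once), the
denominator over C₁ × C₁ (each internal edge twice, the diagonal once).
Insulated means expansion < 1 under this convention.  A consequence
worth knowing: for a uniform-weight cluster the larger part of *any*
bisection scores `n_small / n_large < 1`, so featureless regions shed
loci through strip branchings rather than stopping outright — which is
also why real trees show long strip streaks toward the leaves.

Recursion enters every insulated part with more than two loci.  For a
strip, only the insulated part is recursed; the loose partner is stored
on the node as auxiliary loci without a branch of its own.  Branches
end on a stop classification (no insulated part), on parts with at most
two loci, and on degenerate spectra.  Expansion is always evaluated on
the full-chromosome normalized weights restricted to the loci involved
(for the parts of one bisection this coincides with the subgraph view).
Node ids are deterministic path strings (`R`, `R.0`, `R.0.1`, ...), so
identical inputs and seeds give byte-identical serialized trees.

### Landmarks

* **Leaves** — childless nodes.
* **Bottom enclaves** — non-leaf children of a split whose subtree
  (themselves included) contains no further split.
* **Top enclaves** — strip-branching nodes all of whose ancestors
  branch as splits, excluding bottom enclaves.

A node can satisfy both the "first strip" and the "last split child"
descriptions when no split occurs below the first strip; it is then
classified as a bottom enclave.  This keeps the three sets disjoint and
matches the role such nodes play: they are the terminal self-interacting
clusters of their branch.  In deep trees with a mixed split/strip
mid-region (the shape real chromosomes produce) the two landmark kinds
separate naturally.

### Nestedness

Anchors: NS = 0 at top enclaves, 0.5 at bottom enclaves, 1 at leaves.
With `D` the root distance, a node between a top and a bottom enclave
scores `0.5 (D − Dmin) / ((Dmax − Dmin) + 1)` where `Dmin` is the
nearest top enclave above and `Dmax` the furthest bottom enclave below;
the +1 keeps these values strictly under 0.5.  A node between a bottom
enclave and a leaf scores `0.5 (D − Dmin) / (Dmax − Dmin) + 0.5`
anchored on the nearest bottom enclave above and the furthest leaf
below.  Nodes in the pure-split region above all top enclaves carry no
NS of their own; nodes on side branches with no bottom enclave below
are reported NS-undefined and excluded from trends.  Per locus, the NS
of the deepest scored containing node is used; a locus confined to the
pure-split region scores 0.  These formulas make NS monotone
non-decreasing along every root-to-leaf path below a top enclave.

### Validation and annotation

Variation of information is computed in nats from empirical cluster and
joint frequencies (0·log 0 = 0).  The null model replays the real
tree's topology with memberships drawn uniformly without replacement at
every bisection, so node sizes are preserved exactly; the flat
clustering is extracted from the random tree's bottom enclaves the same
way as for the real tree.  Loci outside every bottom enclave form a
single catch-all cluster (not singletons), keeping cluster counts
comparable with reference clusterings.  The empirical P-value is
`(r+1)/(n+1)` with `r` the number of null draws *strictly* below the
observed VI and `n` the number of clusterings considered (draws + 1;
500 draws give a floor of 1/502).

Track overlaps follow the three per-site summary statistics (coverage
fraction of the cluster, intensity-weighted coverage per bp, overlap
count).  Sites are never merged: a self-overlapping track can legally
push the coverage fraction above 1.  Intervals are 0-based half-open;
strand is ignored.  Feature enrichment divides each locus's overlap
statistic by the mean over all loci of its top enclave; loci without a
top-enclave ancestor, or in a top enclave with zero mean, are reported
FE-undefined.  The Poisson ratio test is the exact one-sample test of
an observed count against the genome-wide rate, two-sided by the
minimum-likelihood convention (all outcomes no likelier than the
observed one, with the customary 1+1e-7 slack) — the same convention
as R's `poisson.test`.  Tests across nestedness bins are
Benjamini–Hochberg corrected at 0.05.  The enrichment significance
cutoff on a null FE sample is its 75th percentile plus twice its IQR.
Loop anchors overlapping several enclaves are assigned to the enclave
with the largest bp overlap (ties to the earlier-starting enclave).

## Synthetic data

The generator produces the expected contact surface
`background · max(|i−j|, 1)^(−α)` plus, for every planted cluster
containing both bins, that cluster's within weight; realized counts are
independent Poisson draws on the upper triangle, mirrored (a
negative-binomial switch adds over-dispersion).  Defaults: background
1 count, decay exponent α = 1 (the fractal-globule-like decay of
mammalian Hi-C), Poisson noise.

Three presets cover the shapes the analyses need:

* `nested_two_level` — two superblocks of two additive uniform blocks;
  the classic "plaid" compartment look, used for I/O and shape tests.
* `nested_binary` — a balanced binary hierarchy whose levels multiply
  contact intensity geometrically (default level weights 3/6/12 over
  background 1, leaf blocks of 3 loci at weight 30; within/background
  ratio ≈ 50).  This is the recovery-grade preset: the planted leaf
  blocks are exactly identifiable as bottom enclaves.  Two features
  make it so.  Balanced splits compare within- versus cross-weight at
  equal part sizes, and the Box–Cox transform preserves that order no
  matter how strongly it compresses contrast.  And 3-loci leaf blocks
  terminate branches deterministically, because a 1|2 bisection of a
  cohesive triplet is always a strip.  Additive flat blocks, by
  contrast, sit exactly at the insulation knife-edge: a balanced
  bisection of a featureless block is marginally "insulated" whenever
  the spectral relaxation overfits counting noise (which it does at
  even part sizes at a 10–30% rate), so their interiors occasionally
  split and the bottom enclaves land below the planted blocks.  That is
  a property of the split rule on structureless data, not a failure of
  the implementation, and it is why recovery claims are made on the
  multiplicative preset.
* `core_shell` — structures whose dense core is wrapped in a loose
  shell; bisection insulates only the core, so these trees contain
  genuine top enclaves (first strips) and populate the full nestedness
  range, which the enrichment analyses need.

Synthetic tracks place Poisson site counts per bin (rate multiplied by
an enrichment factor on target loci), uniform positions, exponential
lengths (min 50 bp, clipped to the bin), log-normal intensities.

What the synthetic data does *not* emulate: trans contacts,
resolution-dependent coverage gradients, structural variants, copy
number, and the irregular block sizes and partial-overlap hierarchy of
real chromatin.  Passing the recovery suite therefore shows the
algorithm does what its definition promises on data matching its
assumptions — not that real chromosomes decompose this cleanly.

## Problem sizes and numerics

The suites run per-chromosome matrices of 48–200 bins and trees of up
to ~100 nodes; matrices are held dense (numpy), which is comfortable up
to a few thousand bins per chromosome.  Balancing tolerance 1e-8;
eigensolver tolerance 1e-10 with a dense path below 500 loci;
2-means consensus over 5 seeds derived from the master seed; VI nulls
default to 500 draws.  Degenerate inputs are handled explicitly:
sub-2-loci sets are never bisected, zero-internal-weight parts count as
not insulated, constant Fiedler coordinates terminate a branch, and a
zero expected rate with a positive observed count reports P = 0 with an
infinite rate ratio, flagged as degenerate.

## Known limitations

* Per-chromosome (cis) analysis only; no trans matrices, no `.hic` or
  `.cool` parsing (export to sparse triples first).
* The literal ordered-pair expansion convention makes insulation twice
  as permissive as a symmetric convention would be; thresholds are not
  configurable because the split/strip semantics depend on them.
* Strip auxiliary loci leave the recursion at the node where they are
  shed; their nestedness is that of the shedding node, which is the
  natural reading but not the only possible one.
* KR balancing assumes every retained bin is connected enough to
  balance; pathological near-disconnected matrices can hit the
  iteration cap (reported as a convergence error with the residual).
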