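# Methods

`arborcode` infers *potential connectivity* of single neurons from geometry
alone: two neurons can be wired only where the axonal arbor of one overlaps
the dendritic arbors of others. Given reconstructions registered to a common
annotation volume, the pipeline derives spatial arbor domains, summarizes
each neuron's outgoing reach as a connectivity barcode, and classifies and
subtypes neurons from those barcodes. This note documents the model, its
parameters, the numerical choices, and what the synthetic test world does
and does not establish.

## Reference space and mirroring

The annotation volume is a 3-D grid of isotropic voxels (default 25 μm)
with integer region labels and a declared mirror axis whose grid midplane
acts as the mid-sagittal plane. Points map to voxels by
`floor((p − origin)/voxel_size)` (0-based, half-open voxels); mirroring
reflects a single coordinate about the midplane and is an involution.
Hemisphere handling is asymmetric by design: *neurons are never flipped*;
instead every dendritic domain is duplicated into both hemispheres, so a
neuron's contralateral projections meet the mirrored copy of the target
domain. Somas are mirrored (to the canonical hemisphere) only inside the
anatomy-aware distance map, where left/right position is a nuisance.

## Morphology handling and QC

SWC trees are validated strictly (single root, no dangling parents, no
cycles) and resampled so no edge exceeds 10 μm, preserving the root, branch
points and tips exactly; total cable length is invariant under resampling.
Morphometric features follow the L-Measure conventions: tips, total length,
maximal path distance from the soma, bifurcation count, maximal branch
order (root order 0, +1 per bifurcation on the root path), maximal
Euclidean distance, bounding box, and the average remote bifurcation angle
— at each bifurcation, the angle subtended by the next remote points
(following each child branch to its next bifurcation or tip), averaged over
child pairs.

Automated dendrite tracings are filtered by five-feature realism intervals
(tips [7, 143], length [700, 13615] μm, max path distance [108, 1382] μm,
average remote bifurcation angle [35, 129]°, max branch order [3, 32]): a
candidate is kept when at least 4 of 5 features fall inside their closed
intervals, and among passing candidates for one soma the greatest total
length wins. The keep-direction of this rule is the only reading under
which the intervals describe realistic arbors; the 4-of-5 threshold is
configurable.

## Arbor domains

Per soma-region cohort (s-type), all resampled node coordinates are pooled
and clustered with Gaussian mixtures. Model selection maximizes
BIC = 2·lnL − p·ln n over component counts k = 1..9 and the four covariance
structures EM supports here (spherical, diagonal, tied, full); EM restarts
are seeded, so selection is deterministic. Degenerate clouds fall back to a
regularized diagonal fit. Dendrite-only cohorts (the survey-style dendrite
datasets) are *not* GMM-clustered: their coordinates are pooled into a
single per-hemisphere set, because sub-clustering a dendrite-only cloud
manufactures spurious sub-domains that encode nothing but sampling
position.

Each cluster is enclosed in a 3-D α-shape: the union of Delaunay tetrahedra
with circumradius ≤ α (α → ∞ recovers the convex hull). α is expressed in
voxel units of the atlas (default 0.4, i.e. 10 μm at 25 μm voxels, matching
the resampling scale); the synthetic world uses α = 4 voxel units because
its arbors are far sparser than real reconstructions and fragment at small
α. Fewer than 5 points or a coplanar cloud falls back to the convex hull of
the points dilated by one voxel. Membership tests use the Delaunay
point-location walk plus a bounded barycentric re-test near kept/discarded
facet boundaries, so generator points always test inside.

A domain's voxel mask contains every voxel whose center passes the inside
test, unioned with the voxels of the member nodes themselves (a pure center
test can drop a boundary node's voxel; the union keeps the mask an honest
cover of the cluster). A domain is *dendritic* when strictly more than 50%
of its member nodes belong to neurons whose soma lies inside the α-shape;
ties go to axonal. Domain volume is voxel count × voxel volume, reported in
mm³.

The whole-brain panel concatenates, in persisted order, the pooled
dendrite-cohort domains and the per-s-type GMM dendritic domains of one
hemisphere followed by their mirrored twins; the barcode dimension is
2 × (n_pooled + n_stype). A per-voxel index of covering domains makes
barcode computation one pass over a neuron's mask.

## Connectivity barcodes

A neuron's mask is the voxelization of the α-shape of its axonal nodes
(whole-neuron masks are available by flag; axon is the default because the
barcode models *outgoing* connectivity). Fewer than 5 axonal nodes use a
dilated-polyline fallback; the mask always contains every axonal node's
voxel. The barcode entry for domain d is the voxel count of mask ∩ domain
mask — raw counts, convertible to mm³ by the voxel volume. On a symmetric
atlas, mirroring a neuron permutes its barcode by the panel's
hemisphere-swap permutation exactly.

## Scores and distances

The cluster-pair similarity used for both morphology (m-score) and
connectivity (c-score) is

    score(A, B) = exp(−2 · D_inter / ((D_intra(A) + D_intra(B)) / 2)),

with Manhattan center distance and mean sample-to-others Manhattan
intra-distances; identical clusters score 1. Features are z-scored over the
pooled comparison set first (they span orders of magnitude; unscaled
Manhattan sums would be dominated by cable length), singleton clusters have
intra-distance 0, and when both intra-distances vanish the score is 1 for
coincident centers and 0 otherwise. The c/m ratio matrix flags entries with
m-score 0 as undefined rather than dividing.

Within an s-type, soma separation is measured by the squared Mahalanobis
form (s₁−s₂)ᵀ Cov⁻¹ (s₁−s₂), with Cov the covariance of the host region's
ipsilateral voxel-center coordinates and all somas mirrored to the
canonical hemisphere first; a rooted variant exists behind a flag. The
d-map is correlated (Pearson, strict upper triangle) against neuron-level
similarity matrices: cosine on raw barcodes for connectivity, cosine on
z-scored morphometric features for morphology; all-zero barcode rows get
similarity 0 to everything.

Class separability is quantified as the resubstitution error of a linear
soft-margin SVM (C = 1000) on z-scored features, in percent; the
connectivity contribution is assessed by appending the top-3 principal
component scores of the (column-centered) connectivity matrix to the
morphology features and re-measuring.

## Spatially tuned subtyping

For one s-type: MC is the cosine similarity of barcodes and MD the soma
distance map, both min-max normalized over off-diagonal entries (the
self-similarity diagonal would otherwise compress the range); the Gaussian
distance affinity is MDA = exp(−MD ⊙ MD) and the combined affinity
A = MC ⊙ MDA (elementwise — both matrices are pairwise affinities over the
same index set, so a matrix product would be meaningless), with the
diagonal forced to the matrix maximum. Ward linkage runs on the condensed
dissimilarity 1 − A; every candidate k in 2..min(10, n−1) cuts the same
tree, and the Calinski-Harabasz index, computed with rows of A as feature
vectors, selects k by argmax. All-zero barcode rows are excluded before
normalization.

A caution established during development: argmax-CH over Ward cuts
over-partitions when the within-cluster residual is an effectively
one-dimensional continuum (CH increases monotonically with k on 1-D data).
The criterion is reliable in the regime the method targets — many neurons,
barcodes with several independently varying components — and the synthetic
study conditions are set in that regime (below). On data with a single
dominant nuisance axis, the selected k should be read as an upper bound and
the dendrogram inspected.

## The synthetic world

The generator emulates the inputs the pipeline needs, not biology: a
mirrored toy atlas (64³ voxels at 25 μm; box/ellipsoid region pairs) and
neurons grown as random trees. Arbors grow by a directed random walk
(momentum 0.7, Gaussian angular noise, bifurcation probability per step,
hard node cap) and are then radially rescaled about their center so the
realized RMS spread equals the requested spread parameter exactly — the
spread is a knob, not an emergent property. Axons are a low-tortuosity
path from the soma toward each planted target's centroid plus a terminal
arbor there. Somas are drawn without replacement from region voxels (soma
= voxel center, so the s-type label is exact by construction), and
everything derives from `numpy.random.SeedSequence`, so cohorts are
byte-reproducible.

Default study conditions: two connectivity subtypes share one soma region
with identical dendrite generators (spread 75 μm, ~120 nodes) and differ
only in disjoint three-target combinations (ipsi- and contralateral),
planted at compact, well-separated soma sites; target regions host dense
dendrite-only populations (spread 140 μm) so their pooled dendritic
domains cover the regions without holes. Three targets per subtype give
each neuron several independently varying barcode components — the regime
in which CH model selection is well conditioned; single-target plants
reduce the within-group residual to one arbor-volume scalar and CH
over-splits (see above). Dense target domains matter for the same reason:
patchy domains turn overlap counts into landing-position noise.

What passing tests show: the implementation recovers exactly the structure
it plants, under generator assumptions (isotropic Gaussian-like arbors,
noise-free coordinates, a symmetric atlas, targets that host dendrites).
They do not show robustness to registration error, tracing errors,
non-Gaussian arbor geometry, partial reconstructions, or unbalanced
cohorts — all properties of real data this world does not emulate.

## Numerical choices and degenerate inputs

- BIC sign follows the maximize convention; ties resolve to the first
  maximum in (family, k) scan order.
- Circumradii are computed by solving the 3×3 circumcenter system per
  tetrahedron; near-singular tetrahedra get radius ∞ (kept only at α = ∞).
- Overlapping atlas primitives: later wins, with a warning for
  same-hemisphere overlaps.
- Projection matrices attribute each edge's length to the region of the
  child node's voxel; the error is bounded by the resampling step. Nodes
  outside the volume count in a dedicated column 0.
- Singular region covariances are ridge-regularized
  (ε = 1e-6 × trace/3) before inversion.
- Stage seeds derive from the run seed via
  `SeedSequence(entropy=seed, spawn_key=(stage_index,))`, so each stage is
  individually reproducible and all derived seeds stay below 2³¹.

## Problem sizes

The default toy run uses a 64³ atlas, 40 fully traced neurons in two
planted subtypes plus 30 dendrite-only neurons, ~120–200 nodes per arbor
before resampling. These sizes keep a full pipeline run under a minute on
one CPU while leaving every stage with enough data to be statistically
meaningful (e.g. 780 soma pairs per s-type for the d-map correlations).

## Known limitations

- The morphometric panel is a compact six-feature stand-in; it is declared
  in every output manifest rather than hidden, and swapping in a larger
  panel only changes the m-feature matrix builder.
- α-shape voxelization tests voxel centers only; sub-voxel slivers of a
  shape can be missed (bounded by one voxel).
- The GMM domain decomposition inherits BIC's preference for more
  components on non-Gaussian point unions; domain *counts* are data
  outcomes, not contracts (domain coverage is the tested property).
- `hyperoverlap`-style SVM stopping heuristics are not reproduced; overlap
  is plain resubstitution error at C = 1000.
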