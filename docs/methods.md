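# Methods

This note documents the models and procedures implemented in `fisseg`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Problem setting

Pulmonary fissures — the boundaries between lung lobes — occupy a fraction
of a percent of a thoracic CT volume, which makes dense voxel-wise 3D
segmentation computationally wasteful.  The pipeline here replaces the
dense representation with a sparse one: (1) abstract the volume into at
most K = 20 000 candidate keypoints inside the lung mask, (2) classify
each point as background or one of three fissures (left oblique, right
oblique, right horizontal) with a geometric deep-learning model operating
on point coordinates and local intensity features, and (3) reconstruct a
dense open triangle mesh per fissure from its labeled points.

## Keypoint extraction

**Förstner keypoints** (fissure-agnostic).  The structure tensor
S = G_{σ_t} ∗ (∇I ∇Iᵀ) is computed from Gaussian-derivative gradients
(σ_g = 1 voxel) and tensor smoothing σ_t = 1.5 voxels (defaults,
configurable; the scales trade localization against noise robustness).
The distinctiveness D = 1 / trace((S + εI)⁻¹) (ε = 1e−6) is evaluated in
closed form via the 3×3 adjugate; D is large only where gradient energy is
spread over all three directions (blobs/corners), which makes the operator
generic rather than fissure-specific.  Candidates are local maxima of D in
5×5×5 neighborhoods inside the lung mask.  The plateau rule admits ties
with the window maximum, so a non-empty mask always yields a non-empty
cloud — a robustness property of the detector that the test suite checks
over twenty random cases.  Over-budget clouds keep the top-K by
distinctiveness.

**CNN keypoints** (fissure-specific).  A MobileNetV3-Large backbone with
all 2D convolutions inflated to 3D (kernel sizes and channel widths kept)
and an FPN-style decoder proposes fissure voxels; K points are sampled
uniformly at random from the proposals.  An empty proposal set is a valid
outcome that propagates as a non-assigned (n.a.) fissure instead of an
error.  The head width is 44 channels, chosen so the total trainable
parameter count lands on the published 3.6 M budget, which is the only
surviving architectural constraint for this network.  The CNN is
implemented inference-only (plain numpy convolutions); the recall-oriented
loss — cross-entropy weighted per class by the batch false-negative rate
FN/(FN+TP), zero for absent classes — is implemented and differentiable at
the logits level.  Sliding-window inference tiles the volume with at least
50 % overlapping 128³ patches and averages softmax maps uniformly
(uniform rather than Gaussian fusion: simpler and directly testable).

**Patch features.**  Every keypoint carries its flattened 5×5×5
neighborhood of windowed intensity (lung window −1000…600 HU mapped to
[0, 1]) as a 125-dim feature vector; out-of-volume voxels are filled by
edge replication (avoids an artificial intensity step at the border).
Flattening is x-fastest — any fixed order works, but it must be frozen for
model reproducibility.  Coordinates are normalized per axis from the index
lattice to [−1, 1]; physical spacing is kept only for reporting distances
in millimetres.

## Point cloud segmentation

All models map (N×3 coordinates, N×125 features) to N×4 class logits and
are permutation-equivariant by construction.

* **PointNet**: shared per-point MLPs, global max-pool, concatenation of
  local and global features, per-point head; no spatial transformer
  (structures are roughly aligned in CT).
* **DGCNN**: three EdgeConv layers (max over neighbors of an MLP on
  [x_i, x_j − x_i]) over one kNN graph with k = 40 built from coordinates
  only and reused by every layer; the dynamic graph rebuild of the original
  architecture is deliberately disabled.
* **PointTransformer**: five-stage U-Net with vector self-attention in
  k = 16 neighborhoods.  Attention weights are produced per channel group
  (share factor 8) from q_i − k_j plus a learned position encoding that is
  also added to the values; downsampling is farthest-point sampling (4×)
  with local max-pooling, upsampling is 3-NN inverse-distance
  interpolation with skip connections.  The farthest-point start index is
  the lexicographically smallest point so that the whole network stays
  permutation-equivariant.

Channel widths were tuned so the trainable-parameter counts reproduce the
published budgets to the printed precision: PointNet 0.48 M, DGCNN 0.65 M,
PointTransformer 7.77 M.  The budgets act as the architecture oracle; the
acceptance suite asserts them.

**Training.**  Per step, N = 2048 points (desk-scale configurations use
smaller N, see below) are drawn uniformly without replacement from one
case's cloud, a random rigid transform (rotations ±15° per axis,
translation ±0.1, scale 0.9–1.1 — configurable) is applied to the
coordinates, and one Adam step (lr 1e−3, weight decay 1e−5) minimizes
cross-entropy plus mean soft-Dice complement over all four classes
(smoothing δ = 1e−5 in numerator and denominator).  The learning rate
follows cosine annealing from η at epoch 0 to 0.05·η at the last epoch.
Training is bit-reproducible given the seed (single-threaded numpy).

**Inference.**  The forward pass runs 50 times on random N-point subsets;
softmax scores are accumulated per point.  Subsets are drawn
coverage-first — uncovered points are exhausted before covered ones are
resampled — which guarantees every point is segmented (extra rounds are
appended in the rare case the configured rounds cannot cover the cloud).
Labels are the argmax of accumulated scores; exact ties resolve to the
lowest class index, so background wins ties (conservative).  Scores are
softmax probabilities rather than raw logits: accumulation then has a
bounded per-round contribution.

## Mesh reconstruction

**Poisson route.**  Normals are estimated per point by PCA over k_n = 30
neighbors (smallest-eigenvalue eigenvector) and given globally consistent
signs by flip propagation along a minimum spanning tree of the kNN graph
weighted by 1 − |n_i·n_j|.  The screened-Poisson indicator problem is
solved on a regular grid of resolution 2^depth (depth 6 by default, the
analogue of the octree depth of adaptive solvers): normals are splatted
trilinearly into a vector field, lightly smoothed (σ = 1.3 cells, playing
the role of the B-spline kernel of octree solvers), and the Poisson
equation ∇²χ = ∇·V is solved with homogeneous Neumann conditions by DCT.
The iso-level is the mean of χ at the input samples; marching cubes
extracts a watertight mesh.  The solver is validated by accuracy
contracts: 5 000 oriented sphere samples reconstruct to ASSD < 0.05·radius
(measured ≈ 0.0006·radius), and a flat sheet to < 0.05 edge lengths.
Inputs below 50 points or of rank < 2 (collinear) fail explicitly and feed
the n.a. pathway.

Fissure topology is produced by post-processing: every triangle with at
least one vertex outside the lung mask is dropped (the strict variant —
"any vertex outside" — keeps meshes inside the lungs), then the largest
face-connected component is kept (ties: lowest component index) and
unreferenced vertices pruned.  Clipping a closed surface this way yields
an open surface with a boundary, which the tests verify by counting
boundary edges.

**Ground truth from label maps.**  Per class, the voxel mask is reduced to
a one-voxel-thick medial surface by topology-preserving thinning and the
remaining voxel centers enter the same normals → Poisson → clip chain.
The thinning iterates over the six face directions and deletes border
voxels sequentially (lexicographic order) when they are 26/6 simple points
(Malandain–Bertrand characterization) and not surface points (a voxel
whose two 6-neighbors along some axis are both background is part of a
thin sheet and is protected).  The procedure is idempotent, returns a
subset of its input, and preserves the 26-connected component count; slabs
reduce to sheets of thickness ≤ 2 (staircase transitions can retain
two-voxel columns).  A faster ablation mode skips thinning and samples up
to 10 000 class voxels uniformly instead.

**Learned route (PC-AE).**  The autoencoder encodes exactly N = 2048
points (EdgeConv stack on coordinates, k = 20, global max-pool, linear map
to z ∈ R⁵¹²) and decodes by deforming a fissure-homeomorphic template — a
45×45 vertex grid (M = 2025, the closest square to N; 3 872 triangles)
over [−0.3, 0.3]² at z = 0 — in two residual steps V¹ = V⁰ + f₁([z, V⁰]),
V² = V¹ + f₂([z, V¹]) with shared per-vertex MLPs (hidden width 416).
Vertex order and connectivity are template-fixed, so decoded meshes are in
correspondence across shapes.  Widths are tuned to the published 1.42 M
parameter budget.

The training loss is w_CD·CD + w_NC·NC + w_EL·EL + w_LS·LS with weights
1 / 0.1 / 1 / 0.1.  Frozen conventions (the source leaves them open):
chamfer uses squared distances, mean-reduced per direction and summed, and
compares decoded *vertices* against the input points without surface
resampling; NC is the mean over adjacent-face pairs of 1 − cos of the face
normals; EL the mean squared edge length; LS the mean squared norm of the
uniform (row-normalized) graph Laplacian.  Means rather than sums keep the
terms scale-comparable across template sizes.  Setting w_NC = 0 is the
documented ablation hook for fold-over behavior.  At inference, one
forward pass runs per fissure; clouds above N are reduced by farthest
point sampling (deterministic start), clouds below N are padded with
duplicated points plus isotropic Gaussian offsets (σ_pad = 0.05 normalized
units, configurable) — padding, not resampling, because sparse clouds are
a domain shift the encoder must see in the same density regime as
training.

## Evaluation metrics

Both meshes are sampled uniformly by area (10 000 points each by default,
seeded, barycentric within faces); each sample is measured by its exact
point-to-triangle distance to the other mesh (Ericson's region
classification, with a nearest-vertex upper bound pruning candidate
triangles through a centroid KD-tree without losing exactness).  The two
directed distance sets are pooled: ASSD is the pooled mean, SDSD the
pooled standard deviation, HD the pooled maximum — so ASSD ≤ HD always and
the report is symmetric in its arguments.  A missing prediction yields an
n.a. report; case aggregates average the non-n.a. fissures and carry the
n.a. count, mirroring how missing fissures are accounted rather than
silently dropped.

## Synthetic benchmark

`fisseg.synthetic` generates toy cases so every stage is testable without
clinical data: two ellipsoidal "lungs" in a 64³ volume (128³ available for
demos), each fissure an analytic quadratic height field z = a + bx + cy +
dx² + ey² + fxy clipped to the inner 40 % (squared fractional radius) of
its lung footprint — one oblique sheet on the left, a steeper oblique and
a flatter horizontal sheet on the right, kept ≥ 3 voxels apart.  The image
is parenchyma at −850 HU with Gaussian noise (σ = 40 HU), a bright ridge
of Gaussian cross-profile (amplitude 300 HU, width 1 voxel) along each
sheet, a soft-tissue exterior and a few ellipsoidal distractor blobs.
Label maps mark voxels within half a voxel (vertically) of a sheet;
ground-truth meshes are triangulated directly from the analytic height
fields, so the geometric reference is exact rather than derived from the
voxelization (labels and meshes agree to sub-voxel ASSD, which is itself
tested).  The labeled fraction stays below 2 % of the lung — the
thin-structure regime that motivates the sparse representation.

Desk-scale choices, stated once: at 64³ the Förstner operator returns on
the order of 10² NMS maxima (its non-emptiness and mask containment are
tested at exactly this scale), far fewer than the 20 000 points available
at clinical resolution.  The dataset helper therefore samples K = 8192
lung voxels uniformly as the keypoint abstraction for
training/evaluation, and the learning-sanity experiments use N = 512
points per forward pass, 16 accumulation rounds and 2 000 metric samples.
The synthetic benchmark shows that the pipeline's stages compose correctly
and that training moves held-out surface distance from chance to sub-voxel
accuracy; it does not emulate vasculature, airway walls, incomplete
fissures, scanner-dependent noise or anatomical lobe shapes, so passing it
says nothing quantitative about clinical accuracy.

## Numerical and engineering choices

All networks run on a compact in-package reverse-mode autodiff engine
(`fisseg.nn`, channels-last float32 numpy): broadcasting arithmetic,
batched matmul, reductions with first-index tie routing, sparse-backed
gather/scatter, BatchNorm with batch statistics inside the graph, Adam and
the cosine schedule.  Gradients are verified against finite differences in
the test suite.  The pre-segmentation CNN is forward-only.  Determinism:
all randomness flows through explicit `numpy.random.Generator` seeds;
repeated runs are bit-identical on the same single-threaded setup.

Known limitations: the grid Poisson solver has uniform resolution (no
octree adaptivity), so very large depth values are memory-hungry; the
thinning is sequential and sized for sparse structures; BatchNorm running
statistics are updated but training uses batch statistics only; the
PointTransformer follows the published description (vector attention,
k = 16, U-Net) with widths set by the parameter budget rather than by the
original implementation's exact layer table, which is not public.
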