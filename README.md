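# fisseg — keypoint-based lung fissure segmentation

`fisseg` segments the pulmonary fissures — the thin boundary surfaces
between lung lobes (left oblique, right oblique, right horizontal) — from
3D CT-like volumes using a *sparse* representation.  Fissures occupy well
under a percent of a thorax scan, so instead of dense voxel-wise 3D
segmentation the pipeline:

1. **abstracts** the volume into a keypoint cloud P ∈ [−1, 1]^{K×3}
   (K ≤ 20 000) inside the lung mask, either with the fissure-agnostic
   Förstner operator (local maxima of the structure-tensor
   distinctiveness D = 1/tr((S+εI)⁻¹)) or with a lightweight 3D
   MobileNetV3 pre-segmentation, each point carrying a 5×5×5 patch of
   windowed intensity as a 125-dim feature;
2. **segments** the cloud into {background, LO, RO, RH} with a geometric
   deep-learning model — PointNet, DGCNN (EdgeConv on a static kNN graph,
   k = 40) or PointTransformer (vector attention, k = 16) — trained with a
   combined cross-entropy + soft-Dice loss and evaluated by accumulating
   softmax scores over 50 random-subset passes so that all K points are
   labeled;
3. **reconstructs** a dense open triangle mesh per fissure, either by
   Poisson surface reconstruction (PCA normals with MST-consistent
   orientation, indicator solve at depth 6, lung-mask clipping + largest
   component) or by a point-cloud-to-mesh autoencoder (PC-AE) that
   encodes N = 2048 points to z ∈ R⁵¹² and decodes it as two residual
   deformations V¹ = V⁰ + f₁([z, V⁰]), V² = V¹ + f₂([z, V¹]) of a flat
   template grid;
4. **evaluates** predictions against reference meshes with pooled
   symmetric surface distances (ASSD / SDSD / HD, in mm) and explicit
   non-assigned (n.a.) accounting for fissures without segmented points.

It is aimed at researchers in medical image analysis who want a fully
testable, CPU-only reference implementation of this pipeline.  A synthetic
data module generates toy "lungs" — ellipsoids containing thin curved
intensity sheets with exact analytic ground-truth meshes — so every stage
runs and is verified without any clinical data.  The neural networks run
on a compact in-package numpy autodiff engine; model widths reproduce the
published parameter budgets (PointNet 0.48 M, DGCNN 0.65 M,
PointTransformer 7.77 M, PC-AE 1.42 M, pre-segmentation CNN 3.6 M).

## Worked example

```python
import numpy as np
from fisseg import synthetic, pointseg, meshrec, metrics

# 10 toy cases with labeled keypoint clouds; train on 8, hold out 2
data = synthetic.make_dataset(10, seed=42)
train, test = synthetic.train_test_split(data, 8)

model = pointseg.build_seg_model("dgcnn", seed=0)
cfg = pointseg.SegTrainConfig(epochs=50, n_points=512, seed=0)
model, history = pointseg.train_seg(
    model, [(cloud, y) for _, cloud, y in train], cfg)
print(f"loss {history[0]:.2f} -> {history[-1]:.3f}")

case, cloud, _ = test[0]
scores = pointseg.infer_full_cloud(model, cloud, rounds=16, n_points=512,
                                   seed=0)
sets, _ = pointseg.split_by_label(cloud, scores)
meshes, na = meshrec.reconstruct_from_segmentation(sets, case.lung_mask)
reports, na_count, agg = metrics.evaluate_case(meshes, case.gt_meshes,
                                               n=2000)
for name, r in zip(("LO", "RO", "RH"), reports):
    print(f"{name}: ASSD {r.assd:.4f}  HD {r.hd:.4f}  (normalized units)")
print("non-assigned fissures:", na_count)
```

Typical output (seeds as above):

```
loss 2.58 -> 0.031
LO: ASSD 0.0283  HD 0.2080  (normalized units)
RO: ASSD 0.0228  HD 0.1837  (normalized units)
RH: ASSD 0.0214  HD 0.1910  (normalized units)
non-assigned fissures: 0
```

On the 64³ toy cases one normalized unit is 31.5 voxels, so these ASSDs
are below one voxel: training took the held-out surface distance from
"no reconstructable fissures at all" (the random-weight twin) to
sub-voxel agreement with the analytic sheets.  The same stages are
available from the shell via the `fisseg` command
(`synth`, `keypoints`, `train-seg`, `segment`, `train-pcae`,
`reconstruct`, `evaluate`, and the composite `run`).

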