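# kernelseg

Segmentation of adhered (touching) corn kernels in 2-D images and per-kernel
mechanical-damage detection — a classical, small-sample computer-vision
pipeline for grain quality control in breeding labs and small processing
plants, where the ≥1000 annotated images a deep segmentation model needs are
simply not available.

Kernels scattered on a dark matte background binarize into blobs that fuse
wherever kernels touch; counting and per-kernel assessment both fail unless
the blobs are split. `kernelseg` separates them with a coarse-to-fine chain
and then classifies every kernel:

1. **Preprocess** — luminance grayscale (0.299 R + 0.587 G + 0.114 B), Otsu
   threshold *t* = argmax of the between-class variance σ²_B(t), binary
   opening + closing;
2. **Coarse split (watershed)** — exact Euclidean distance transform
   D(x, y) = min over background pixels of the distance to (x, y); markers
   from its per-component cores; flooding of −D with watershed lines across
   adhesion necks;
3. **Fine split (convexity defects)** — for hull edge AB and contour point
   C, depth = |AB × AC| / ‖AB‖; defects ≥ 8 px are adhesion points and the
   blob is cut between paired defect points;
4. **Shape features** — area, perimeter, major/minor axis (rotating
   calipers), elongation, rectangularity, eccentricity
   √(1 − minor²/major²), compactness 4πA/P²;
5. **SVM** — intact vs damaged on the standardized 8-vector (linear, RBF
   γ = 0.1, or polynomial d = 3).

A seeded synthetic scene generator with exact per-kernel ground truth
stands in for laboratory acquisition, and an evaluation suite provides
counting accuracy, IoU/Dice and TN/TD/FN/FD confusion metrics. See
`docs/methods.md` for the full model description and design rationale.

## Worked example

Train and evaluate end-to-end on ten synthetic scenes (image-level 80/20
split; the classifier is fitted on segmented kernels of the training
images):

```python
from kernelseg import SceneSpec, PipelineConfig, train_and_evaluate

specs = [SceneSpec(image_width=1000, image_height=750, n_kernels=40,
                   adhesion_probability=0.5, damage_fraction=0.3, rng_seed=s)
         for s in range(10)]
report = train_and_evaluate(specs, PipelineConfig(seed=0))
print(f"counting accuracy : {report.counting_accuracy:.2f}%")
print(f"damage Acc/P/R/F1 : {report.acc:.1f} / {report.precision:.1f} / "
      f"{report.recall:.1f} / {report.f1:.1f} %")
print(f"mean matched IoU  : {report.iou:.3f}")
```

prints

```
counting accuracy : 100.00%
damage Acc/P/R/F1 : 90.8 / 84.0 / 87.5 / 85.7 %
mean matched IoU  : 0.898
```

— on the two held-out scenes every kernel was counted (100% = detected
count over true count), 90.8% of matched kernels got the right
intact/damaged label, and matched instance masks overlap their ground
truth at IoU ≈ 0.9.

The same flows are available from the shell:

```bash
kernelseg generate --seed 0 --n-scenes 3 --out scenes/
kernelseg segment scenes/scene_0000.png --out results/
kernelseg train --seed 0 --n-scenes 20 --out model.pkl
kernelseg ablate --seed 0 --n-scenes 10 --out ablation.csv
```

`segment` writes a 16-bit label TIFF, a contour overlay PNG and a feature
CSV (`id,area,perimeter,major_axis,minor_axis,elongation,rectangularity,
eccentricity,compactness,label`); `ablate` runs the four stage-ablation
variants (full pipeline, no preprocessing, no watershed, no defect cutting)
and tabulates their counting accuracies.

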