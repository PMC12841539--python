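# Methods

`kernelseg` implements a classical, small-sample computer-vision pipeline for
two coupled tasks on 2-D images of corn (maize) kernels scattered on a dark
matte background: (i) counting kernels when many of them touch or overlap
("adhesion"), and (ii) classifying every separated kernel as intact or
mechanically damaged. This note records the model, the parameter choices,
what the synthetic data does and does not emulate, and the numerical
conventions.

## Pipeline model

The method is a coarse-to-fine separation chain followed by shape-based
classification:

1. **Preprocessing.** RGB frames are reduced to luminance
   (`0.299 R + 0.587 G + 0.114 B`, rounded half-up to 8 bits) and binarized
   with Otsu's threshold — the gray level maximizing the between-class
   variance of the histogram, with the dark class `[0, t]` and bright class
   `[t+1, 255]`, ties broken toward the smallest `t` within a 1e-9 relative
   band (empty histogram levels make the criterion constant on plateaus, and
   floating-point noise must not decide the argmax). The binary mask is
   cleaned by one opening (removes bright speckles) and one closing (fills
   pinholes) with a 3×3 elliptical element. The element size is not
   prescribed by the method and is exposed in the configuration; 3×3 is the
   smallest element that removes single-pixel noise without eroding kernel
   geometry. Everything outside the frame counts as background.

2. **Coarse separation — marker-based watershed.** The exact Euclidean
   distance transform of the mask is high at kernel cores and dips at
   adhesion necks. Markers are the 8-connected components of
   `{D ≥ peak_fraction × max D of the enclosing component}` (default
   `peak_fraction = 0.4`), with components under `min_marker_area = 9` px
   dropped. This rule cannot fragment a convex kernel (the thresholded core
   of a convex blob is connected), so the watershed stage never
   over-segments; the price is that pairs overlapping more than a few
   percent of their area share one marker and are left for the next stage.
   Flooding runs over the negated distance field (4-connected frontier,
   deterministic tie-breaking; a Sobel-gradient height smoothed with a
   Gaussian of σ = 1.5 is available as an alternative). Watershed-line
   pixels are merged into the adjacent basin with the lowest label so that
   region boundaries stay closed; foreground components that earned no
   marker are labelled as their own objects and left to the area filter.

3. **Fine separation — convexity-defect cutting.** Each region's outer
   boundary is traced (Moore neighbor following; the trace equals the set of
   pixels 4-adjacent to background). For a hull edge AB and a contour point
   C on its arc, the defect depth is `|cross(AB, AC)| / ‖AB‖`. One hull edge
   may subtend several necks (a chain of kernels under one tangent edge), so
   every contiguous above-threshold run of the depth profile contributes its
   own defect. Defects at least `depth_threshold = 8` px deep are treated as
   adhesion points: true necks measure well above 8 px while surface
   wrinkles stay under 5 px, so the threshold separates the two populations.
   Cutting is iterative: the deepest defect is paired with the nearest other
   defect point of the same region whose connecting segment lies inside the
   foreground, and a 1-px cut is drawn between them; with no partner, the
   cut runs from the defect point along its depth direction to the opposite
   boundary. Cuts are rasterized 4-connected — an 8-connected line cannot
   disconnect an 8-connected region, because the two sides remain diagonally
   adjacent across it. The loop re-extracts regions after every cut and
   stops when no deep defect remains or after 10 cuts per region (logged).

4. **Area filter.** Surviving regions smaller than 15% of the scene's median
   region area are discarded (noise debris, cut slivers). An absolute
   `min_area` override exists; the ablation experiments set it to 0 to show
   the effect of skipping preprocessing.

5. **Shape features.** Eight descriptors per region: pixel area; boundary
   chain length (1 per axial step, √2 per diagonal); major axis (rotating-
   calipers diameter of the hull); minor axis (maximal extent perpendicular
   to the major-axis direction); elongation = major/minor; rectangularity =
   area / minimum-area rotated enclosing rectangle (calipers over hull-edge
   directions, spans widened by 1 px so a filled W×H rectangle scores
   exactly WH); eccentricity = √(1 − minor²/major²); compactness =
   4π·area/perimeter² together with its reciprocal ("roughness"). Calipers
   were chosen over ellipse-moment fitting because they realize the verbal
   geometric definitions ("largest axial dimension", "maximum dimension
   perpendicular to it") and reproduce the reference measurement table's
   normal-row eccentricities from its printed axes. The exact perimeter
   convention of that table is not recoverable; chain length is the standard
   choice.

6. **Classification.** A support vector machine on the 8-vector with three
   kernel options: linear `x₁·x₂`, RBF `exp(−γ‖x₁−x₂‖²)` with γ = 0.1
   (default), polynomial `(γ x₁·x₂ + r)^d` with d = 3 and r = 1 (the
   inhomogeneous form; r = 0 would discard all lower-order terms). `C = 1`
   (not prescribed; exposed). Features span four orders of magnitude (area
   ~8000 px² vs eccentricity ~0.5), so per-feature standardization — fitted
   on the training split only — is on by default. Damaged is the positive
   class. The margin optimizer is scikit-learn's SVC; kernels, feature
   protocol and label conventions are defined here.

   Training happens in the segmentation domain: training images are run
   through the same pipeline, segmented instances inherit the annotation
   label of the ground-truth kernel they match by IoU, and the classifier is
   fitted on those segmented-feature vectors. Training on annotation-mask
   features instead systematically mislabels at prediction time, because a
   kernel that loses pixels to a watershed line or an occluding neighbor
   looks "smaller and cut" in a way annotation masks never do.

## Evaluation conventions

The confusion matrix uses the crop-inspection labels TN/TD/FN/FD (true
normal, true damaged, false normal, false damaged), damaged positive;
Acc/P/R/F1 are percentages; any metric with a zero denominator is reported
as null, never coerced to 0 or 100. Counting accuracy is
100 × detected/actual and can exceed 100 when noise contours inflate the
count. Mask overlap uses IoU and Dice with empty∪empty defined as perfect
overlap. Predicted instances match ground-truth kernels greedily by
descending IoU, one-to-one, with a 0.5 floor (the standard instance-
segmentation rule; no rule is prescribed by the method itself); unmatched
ground-truth kernels are tallied as missed detections and kept out of the
classification metrics rather than being silently counted as errors of
either class.

## Synthetic scenes

The generator emulates the laboratory acquisition the method targets:
2000 × 1500 frames, ~80–150 bright elliptical kernels (default 120; uniform
gray level 140–200 per kernel over a background of 30, which guarantees a
bimodal histogram), random orientation, semi-axes drawn from 40–60 px so
kernel areas land near 8000 px². With probability `adhesion_probability`
(default 0.5) a kernel is placed overlapping a previously placed anchor by
at least one pixel; overlap is capped pairwise at `overlap_cap` (default
0.45) of the smaller kernel's area, and cumulatively so that no kernel is
ever mostly buried — rigid grains occlude each other only near contact.
Touching/overlapping kernels share an adhesion-cluster id (union-find over
realized masks). A linear illumination ramp (default 0.005 gray/px,
centered) and salt-and-pepper speckles (default density 5×10⁻⁴) are applied
last; all randomness flows from one integer-seeded generator, and identical
specs give byte-identical scenes.

**Damage model.** A damaged kernel is its ellipse minus a circular bite
whose center sits outside the body on a boundary normal. Penetration is
drawn as 0.5–0.9 of the minor semi-axis, so a broken kernel loses roughly a
quarter to a half of its area — matching the observed severity of real
mechanical damage, where damaged kernels measure near half the area of
intact ones with visibly higher elongation. The bite radius is then solved
by bisection so that the *realized* convexity-defect depth of the notch hits
a target drawn from `bite_depth_range` (default 3–6 px): a genuinely broken
kernel presents a near-chord cut edge, unlike the deep pinch of an adhesion
neck, and keeping the notch under the 8 px threshold reflects that physical
distinction (and keeps the defect cutter from slicing damaged kernels). The
cut edge is finally roughened with 4–8 small (1–2.5 px) dents, rejected if
they disconnect the kernel or push the notch depth above 7 px: fracture
edges are irregular, and the extra boundary length is precisely the
roughness signature that separates a damaged kernel from an intact one
truncated by a neighbor or a watershed line.

**What the generator does not emulate:** kernel surface texture and
specular gradients, perspective and depth stacking, soft shadows, debris
with kernel-like reflectance, and color variation (frames are replicated
grayscale; the luminance weights are still exercised end to end). Passing
benchmarks on these scenes therefore demonstrates the geometry of the
separation chain and the feature/classifier protocol, not robustness to
photometric nuisance on real imagery.

## Benchmark problem sizes

The end-to-end suite trains on 12 scenes (seeds 1000–1011) and evaluates 20
scenes (seeds 0–19) at 100 kernels per 2000 × 1500 frame, adhesion 0.5,
overlap cap 0.30, damage fraction 0.3 — about 2000 evaluated kernels. The
kernel-function comparison uses a 500-kernel feature dataset from 20 smaller
scenes (800 × 600, 25 kernels) with an image-level 80/20 split. These sizes
give stable percentages while keeping the whole suite inside a coffee
break.

## Known limitations

- The marker rule never over-segments but under-separates heavy overlaps;
  counting beyond ~5 mutually overlapping kernels per cluster degrades, as
  it does for the method this package implements.
- Watershed-alone separation (the W-SVM ablation) resolves only lightly
  overlapping pairs; the defect-cutting stage carries most of the
  separation load on strongly adhered scenes.
- The defect cutter's fallback (no partner defect) cuts through the body
  and would bisect a kernel whose damage notch exceeded the 8 px threshold;
  deep-notch damage types would need a shape prior the method does not
  have.
- Feature-space damage detection inherits the segmentation's failure modes:
  a kernel that loses a large occluded region to a neighbor is genuinely
  indistinguishable, in these 8 features, from a moderately damaged one.
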