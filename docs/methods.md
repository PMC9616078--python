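# Methods

## Problem setting

A digitized gastric biopsy slide must be assigned one of four WHO (5th ed.)
categories of increasing malignancy risk — NED, LGD, HGD, IIN — from pixels
alone.  Pathologists integrate evidence across all lesion areas of a slide
rather than any single field of view; the two-step design mirrors that: a
patch-level segmenter finds and characterizes candidate abnormal regions,
and a graph neural network aggregates the most suspicious patches into one
slide-level call.

## Synthetic slide model

Real WSIs are ~50k × 110k pixels and unavailable here; the generator
produces desk-scale stand-ins (default 1024 × 1024) that preserve the
*structure* of the problem, not its visual realism.

* **Background** is near-white (every channel ≥ 240), so automatic tissue
  thresholding is well-posed.
* **Tissue** is the top `tissue_fraction` (default 0.45) of a smoothed
  Gaussian random field, colored eosin-pink with per-pixel noise
  (sd 5 gray levels) and low-frequency mottling.
* **Lesions** (dysplastic categories only) are grown from `lesion_count`
  seed points by thresholding a bump-plus-noise potential *inside tissue*
  at exactly the requested `lesion_area_fraction` quantile, so the measured
  lesion fraction tracks the request tightly.  Default recipes draw 2–4
  blobs covering 15–35% of tissue.
* **Category signal**: lesion texture is monotone in severity through three
  knobs — base chroma (darker/more purple), nucleus-like spot density
  (0.004 → 0.020 per pixel), and spot radius (2 → 4 px) for LGD → IIN.
  Adjacent categories differ in mean lesion color by ≥ 3 noise standard
  deviations, so the "easy" default setting leaves recovery limited by the
  pipeline, not by class overlap.
* **Center styles** emulate stain/scanner variation as a per-channel affine
  gain/offset plus pixel noise applied after synthesis.

What this does *not* emulate: nuclear morphology, glandular architecture,
pyramidal formats, scan artifacts, or ambiguous borderline lesions.  A
passing recovery test therefore shows the pipeline's machinery works
end-to-end under a clean, learnable signal; it says nothing about
diagnostic performance on real tissue.

All generation is keyed by integer seeds (per-slide seeds spawned from a
cohort seed), and identical specs produce bit-identical images.

## Preprocessing

* **Tissue mask**: Otsu threshold on HSV saturation.  A pixel is background
  only if it is both below the saturation threshold *and* near-white (min
  channel ≥ 230); this guard keeps Otsu from splitting the tissue's own
  saturation spread on slides without background.  Components smaller than
  64 px are dropped.  Constant images yield an empty mask plus a warning.
* **Stain normalization**: per channel, `Z = (X − μ)/σ · σ_T + μ_T`; μ, σ
  are tissue-pixel statistics of the current slide, targets are the means
  of per-slide statistics over the training cohort.  Statistics come from
  tissue pixels but the map is applied to every pixel, then clipped to
  [0, 255].  A zero source standard deviation raises rather than divides.
* **Tiling**: non-overlapping `P × P` grid (default 128), right/bottom
  padded with white; patches under 5% tissue are dropped (contributing
  probability 0 to the stitched map).  Coordinates are 0-based, half-open,
  single resolution level.
* **Augmentation** (training only): flips, 90° rotations, random erasing,
  and brightness/saturation/contrast jitter, all seeded; spatial transforms
  are applied identically to the label crop.

## Patch segmenter

A 2-D V-Net-style encoder–decoder implemented directly in NumPy with
hand-written backpropagation (the environment targets plain CPUs):
3 resolution levels, base width 8, additive skip connections through 1 × 1
projections, sigmoid head.  The binary foreground is "abnormal"
(LGD ∪ HGD ∪ IIN); category discrimination is deferred to the GCN.  The
feature vector of a patch is the global-average-pooled bottleneck
activation (d = 32).

Training minimizes soft dice, `1 − 2Σpg / (Σp² + Σg² + ε)` with ε = 1e-6,
averaged over the foreground and background classes of each batch — the
background term keeps gradients informative on batches with no abnormal
pixel.  Optimizer is Adam at 1e-3.  The final-layer bias initializes at −1
so an untrained network starts from a background prior.  Training patches
are sampled balanced (≈ half lesion-bearing), capped at `max_seg_patches`
(default 256).  Two runs with one seed produce identical parameter blobs.

## Slide graph

Patch grade = mean of its probability map (the alternative, fraction of
pixels above a cut, would introduce a second threshold).  The top-n patches
by grade (default n = 64; ties broken row-major) become nodes; edges follow
the strict Chebyshev rule `E_mn = 1 iff ‖x_m − x_n‖_∞ < γ`.  γ can be a
fixed number (0 and +∞ give the edgeless and complete limits) or "auto":
the 20th percentile of the slide's pairwise node distances, which adapts to
per-slide feature scale.  Self-loops are on by default so isolated nodes
still propagate through the GCN.

## GCN classifier

Node inputs are the standardized patch features (training-cohort mean/std)
concatenated with the abnormality grade.  Two message-passing layers
(`H' = ReLU(Â H W)`, `Â = D^{−1/2} A D^{−1/2}`, hidden width 32) feed mean
pooling over nodes and a 4-way softmax, making predictions invariant to
node order.  Training uses focal loss
`−α_c (1 − p_t)^{γ_f} ln p_t` (γ_f = 2, `p_t` floored at 1e-12, α_c
inversely proportional to class frequency normalized to mean 1), Adam at
1e-3, one graph per step, seeded shuffling.

Four-tier calls are the argmax; exact ties resolve toward the more severe
category so malignancy is never under-called.

## NED screening

The screening score is `p_NED` from the four-tier head — no separate
binary model.  Calibration sets `t = max p_NED` over the positive slides of
a calibration set; a slide is screened out iff `p_NED > t` (strict).  On
the calibration set this makes 100% sensitivity and 100% NPV structural:
no positive slide exceeds `t`, and among thresholds with that property this
one screens out the most benign slides.  The threshold is calibrated once
(typically on a validation split) and applied unchanged to new data, where
the guarantee is reported, not asserted.  Calibration without any positive
slide is refused (`t` undefined).

## Evaluation battery

Confusion matrices (rows = truth), sensitivity/specificity/accuracy/NPV
with empty denominators reported as NaN rather than 0, trapezoidal ROC/AUC
(equivalent to the Mann–Whitney statistic with half-credit ties), and
Cohen's κ.  Quadratic κ weights are `w_ij = 1 − ((i−j)/(K−1))²` on the
severity ordering; bands use the 0.2/0.4/0.6/0.8 cut-points with each
boundary belonging to the upper band.  κ is undefined (raises) for
constant identical ratings.  Both weightings are always computed and
labeled, since agreement studies quote either.  Per-center reporting pools
rows by a `center` column; standard estimators are delegated to
scikit-learn behind this module's interface.

## Desk-scale study conditions

Acceptance-level runs use 1024 × 1024 slides with 128-px patches: 120
training and 40 held-out slides (30/10 per category) for end-to-end
recovery, and a 200-slide calibration cohort (50 per category, cohort seed
42) for the screening guarantee.  Segmenter training samples 192 balanced
patches for 6 epochs; the GCN trains 60 epochs.  These sizes are chosen so
a full run completes in minutes on one CPU while leaving the recovery
margins (held-out four-tier accuracy ≥ 0.8, abnormal-pixel AUC ≥ 0.9)
comfortably met on the easy synthetic signal.

## Numerical choices and edge cases

* Soft-dice ε = 1e-6; focal-loss probability floor 1e-12.
* Probability simplexes are validated to 1e-6 after an explicit
  renormalization of float round-off.
* Max-pooling backward routes gradient to the first maximal element of
  each 2 × 2 window, conserving gradient mass under ties.
* Degree-zero nodes get a zero row in `Â` (no propagation) instead of a
  division error.
* Slides where no patch clears the tissue cut are re-tiled with threshold
  0 so every slide yields at least one node.
* Stitching copies values exactly — no blending — and rejects overlapping
  or out-of-canvas patches.

## Known limitations

Hand-rolled NumPy networks are orders of magnitude slower than GPU stacks
and deliberately tiny; the binary (rather than four-class) segmentation
head is an assumption, with category discrimination resting entirely on
the GCN; the synthetic texture signal is far easier than real histology;
and γ in "auto" mode is per-slide, which mildly decouples edge density
from absolute feature scale across slides.
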