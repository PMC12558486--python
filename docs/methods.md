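# Methods

This note records the scientific and engineering design decisions behind
`respiro`, a pipeline for dye-free quantification of organoid swelling
from bright-field microscopy.

## Problem setting

Respiratory organoids (nasal or iPSC-derived lung) are grown in
extracellular-matrix droplets and imaged in transmitted light. In
bright-field they appear as bright-lumen structures with a dark rim.
The functional readout is forskolin-induced swelling (FIS): activating
the CFTR chloride channel drives fluid into the lumen, and the area
fold change over ~24 h reports channel activity. Healthy-donor
organoids swell strongly; organoids carrying disease variants such as
F508del swell weakly. The pipeline turns raw multi-field z-stacks into
per-organoid fold-change tables without any fluorescent dye.

## Extended-focus stitched image (EFSI)

Each well is imaged as a grid of fields (default 2 x 3), each field as a
z-stack (default 10 planes, 100 um apart, 1000 um total coverage).

*Focus stacking.* Per-pixel sharpness is the local variance of the
Laplacian (window 9 px). The per-pixel argmax plane index is smoothed
with a majority filter (window 11 px) before selection, which removes
salt-and-pepper plane switching in smooth regions while keeping plane
boundaries aligned with image structure. Fusion only ever selects
values from input planes; it never invents intensities, and the unit
tests assert this property directly.

*Stitching.* Fields are placed either at their nominal fixed overlap or
by phase correlation (`registration_mode: correlate`), and blended with
linear feathering across the overlap band. On synthetic tiles with
exactly known overlap the round trip reconstructs the canvas with RMSE
below one 16-bit quantization step.

*Crop.* The stitched image is centre-cropped to a square (default
2100 px at 2.0 um/px) so that all downstream geometry is isotropic.

## Preprocessing

The fixed sequence is: 1-99 percentile normalization to [0, 1], CLAHE
(clip limit 1.0, 32 px tiles), bilinear resize to the network input side
(default 512 px; 2100/512 rounds to a 4.1x downsample). Masks travel
the reverse path with nearest-neighbour interpolation so they stay
binary.

## Semantic segmentation

Two interchangeable backends produce the same `BinaryMask` contract.

*U-Net.* Encoder-decoder with skip connections: depth 5, 32 base
filters doubling per level, 3 x 3 kernels, ReLU, 2 x 2 max pooling,
nearest-neighbour upsampling followed by convolution, softmax over two
classes. The implementation is pure numpy (im2col convolutions,
hand-written backprop, verified against central finite differences), so
training is bit-reproducible on any machine for a fixed seed. The
desk-scale profile (depth 3, base 8, 128 px inputs) trains in about two
minutes on one CPU and is used throughout tests and demos; the
full-scale profile is constructible and trainable with the same code.

*Training loss.* We use a soft Dice loss on the foreground channel,

    L = 1 - 2 * sum(p1 * t1) / sum(p1 + t1),

optimized with SGD (momentum 0.9, stepped learning-rate schedule) with
**normalized gradient steps**: the whole-model gradient is rescaled to a
fixed L2 norm (1.0) before each update.

Two design decisions here deserve justification:

1. *Foreground-only Dice rather than volume-weighted multi-class Dice.*
   A popular variant weights each class by its inverse (squared) volume
   to counter class imbalance. At small batch sizes we found that
   weighting to be actively destabilizing: the scarce-class weight is so
   dominant that training oscillates between all-foreground and
   all-background predictions, and seeds collapse to IoU 0. Because the
   softmax couples the two channels (p0 = 1 - p1), the foreground Dice
   already supervises the background, and Dice itself is scale-free with
   respect to class imbalance. In a seed-controlled comparison on the
   desk-scale phantom task, foreground Dice reached IoU 0.92-0.96 on all
   tested seed pairs, inverse-volume weighting collapsed to 0.0 on all,
   and inverse-squared-volume weighting was seed-dependent (0.63-0.90).
2. *Normalized gradient steps rather than clipping.* The Dice gradient
   magnitude varies over orders of magnitude between the near-collapsed
   and well-fitted regimes, which makes a single learning rate either
   too timid early or unstable late. Rescaling the gradient to a fixed
   norm (a normalized-SGD scheme) removes that scale. Plain clipping
   (only shrinking large gradients) was not sufficient: some seeds still
   oscillated.

The classification head is zero-initialized so the softmax starts at
(0.5, 0.5); with a randomly initialized head the softmax can begin
saturated, making initial gradients vanish.

*Augmentation.* Geometric ops (reflection, rotation, shear, scale)
transform image and mask together, the mask with nearest-neighbour
interpolation; photometric ops (blur, noise, brightness, contrast)
touch the image only.

*Classical baseline.* Minimum cross-entropy (Li) global thresholding
with 1 px Gaussian pre-smoothing. Important: the baseline runs on
percentile-normalized input **without CLAHE**. CLAHE equalizes local
contrast and thereby destroys exactly the global foreground/background
intensity separation a single threshold needs; with CLAHE the baseline
IoU dropped from ~0.66 to ~0.14 on phantom scenes. Each backend is run
in the configuration that suits it, which makes the U-Net-vs-baseline
comparison a fair best-vs-best comparison.

*Known bias of the baseline.* The threshold captures the bright lumen
and excludes the dark rim. Measured areas are therefore smaller than
the full organoid footprint, and because the rim has roughly fixed
width, fold changes of growing organoids are biased slightly upward.
The pipeline tests assert against the rim-corrected (lumen) oracle, and
the end-to-end acceptance keeps organoids large relative to the rim so
group medians land within 10% of the generator truth.

## Instance separation and morphometrics

Touching organoids are split by marker-controlled watershed on the
smoothed Euclidean distance transform, with `peak_local_max` markers;
connected components that receive no marker get one seed so no
foreground is ever lost (asserted pixel-exact in tests). Per-object
measurements include area (px and um^2), Crofton perimeter (4
directions; keeps the digital-disc form factor near 1), form factor
4*pi*A/P^2, ellipse-fit axes and eccentricity, solidity, extent,
CellProfiler-style compactness, Euler number, distance-transform radii,
and min/max Feret diameters. The minimum Feret diameter uses rotating
calipers over the convex hull of pixel-corner points: treating each
pixel as a unit square keeps a 1 px line at width 1 and a digital disc
of radius r near 2r. (Running calipers over a marching-squares contour
instead underestimates the width, because that contour is slightly
non-convex and the edge-supported-width formula requires convexity.)

Artifact filtering removes objects failing area or form-factor bounds
and reports each removed id with the failed criterion; surviving labels
are relabeled contiguously.

## Tracking and FIS quantification

Matching runs in *reverse chronological order*, seeded from the final
frame. Rationale: organoids grow monotonically during the assay, so a
late, large footprint reliably covers the organoid's earlier position;
walking backward lets each late object claim exactly one antecedent
instead of an early small object being absorbed by the wrong, larger
neighbour, and objects that drift into focus mid-assay still receive
full tracks. A containment override accepts a match whose centroid
distance exceeds the gate when the earlier centroid falls inside the
later footprint. Matching is greedy nearest-centroid by default, with
an optimal-assignment (Hungarian) option for ambiguous scenes.

Fold change is area(t1)/area(t0) per track, with 0 h defined as 1. The
assay filter keeps tracks with baseline area >= 1500 px and fold change
>= 0.8 (both inclusive); the area bound removes debris and the fold
bound removes collapsing or mis-tracked objects. Summaries report
n / median / Q1 / Q3 per group with numpy's linear quantile
interpolation.

## Evaluation

Pixel metrics are IoU, F1 and accuracy from explicit confusion counts;
F1 = 2*IoU/(1+IoU) is asserted to 1e-12. Accuracy is reported but
documented as misleading under the extreme class imbalance of these
images (an all-background prediction already scores ~0.99). Consensus
ground truth is the pixel-wise AND of two annotations. Evaluation
subsets keep images with more than 5000 labeled foreground pixels,
because overlap metrics on near-empty truths are dominated by
degenerate cases. The dataset splitter reproduces an 85/10/5 split
(827 -> 703/83/41) with round-then-remainder arithmetic. Object-size
agreement matches instances by maximal overlap (>= 50% of the truth
object) and reports the OLS R^2 of predicted vs true areas.

## Synthetic phantom

The generator renders bright-lumen/dark-rim organoids (discs, ellipses,
lobed shapes), bubble rings that perturb the image but are excluded
from the truth, a polynomial illumination field, Gaussian noise, and
16-bit quantization. Ground truth is exact by construction and follows
the annotation rule that touching organoids form one instance
(8-connected components of the footprint union). Z-stacks assign each
organoid a focus plane and blur it by sigma proportional to plane
distance; the noise field is shared across planes and the all-in-focus
reference, so fusion and stitching have exact oracles. Growth scales
radius by sqrt(growth_factor) per full interval so that *area* scales
by the growth factor, which is the quantity the assay reports.

Known simplifications: no rim texture or internal debris, no
illumination flicker between timepoints, no organoid motion, rigid
growth without shape change. These keep oracles exact; the pipeline
makes no use of any of these simplifications.

## Determinism

Every randomized stage consumes an explicit seed; tables are written
with fixed column order, fixed row sort keys and fixed float formatting.
Two runs with identical config, seed and inputs produce byte-identical
CSVs, which the acceptance suite verifies.
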