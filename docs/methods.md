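# Methods

## Model and assumptions

The pipeline implements classical seeded region growing with automatic
seed initialization, targeted at 2-D brain MR slices on which the tumor
is the brightest intra-cranial structure (FLAIR-like contrast). Its
assumptions are explicit and each has a mechanism attached:

- **Tumor hyperintensity.** Seeds are the centers of the brightest
  image tiles; if the tumor is not among the brightest interior tissue
  (e.g. non-enhancing T1), seed selection fails by design.
- **Tumor homogeneity.** The growing criterion accepts a pixel when its
  intensity is within a fixed tolerance of the region's running mean;
  strongly heterogeneous lesions fragment. Ring-enhancing lesions with a
  dark core are handled by the dedicated hole-filling step, not by the
  growing criterion.
- **Skull/brain separability.** Skull stripping assumes the skull is a
  connected component separate from (and smaller than) the brain after
  Otsu thresholding and opening — true when a dark CSF gap separates
  them, as in typical axial slices.

## Procedure

One slice flows through: linear normalization to [0, 1] → bilinear
resampling to the 256×256 working grid → skull stripping (Otsu
threshold, disk opening, disk dilation, largest 8-connected component,
disk closing, hole fill, mask-out) → tile statistics (non-overlapping
8×8 blocks; the mean of each; 1024 blocks on the working grid) → top-5
tile centers inside the brain mask as seeds → per-seed breadth-first
region growing at tolerance 0.1 → hole filling per candidate →
eight-metric scoring against the reference on the working grid →
best-Dice candidate mapped back to the native resolution by
nearest-neighbor resampling.

## Parameters

| Parameter | Default | Units | Rationale |
| --- | --- | --- | --- |
| working size | 256×256 | px | fixed analysis grid; all internal metrics are computed here |
| `selem_radius` | 3 | px | disk radius shared by opening/dilation/closing; large enough to break thin skull bridges at 256×256, small enough not to erode the brain outline |
| `block_size` | 8 | px | tile edge; 1024 tiles give fine localization while averaging out noise over 64 pixels |
| `k_seeds` | 5 | – | number of candidate regions grown; redundancy against one or two bright non-tumor tiles |
| `tolerance` | 0.1 | intensity ([0,1] scale) | half-width of the acceptance band around the region mean |
| `connectivity` | 8 | – | matches the dilation-heavy preprocessing; 4 available |
| `criterion` | `running_mean` | – | classic seeded region growing; tolerant of a slightly off-peak seed. `fixed_seed` compares to the constant seed reference and is exactly a thresholded connected component — the testable variant |
| `max_region_fraction` | 0.5 | fraction of image | growth cap guarding against flooding a near-uniform slice |
| `restrict_to_brain` | on | – | tiles whose center falls outside the brain mask are excluded from seeding, so residual bright boundary artifacts cannot win |
| `selection_metric` | `dss` | – | Dice; `iou` and `acc` selectable |

The seed reference intensity is the originating tile's mean, not the
center pixel's value: the tile mean is what ranked the tile, and it is
robust to single-pixel noise.

## Numerical choices

- **Otsu** is computed on a 256-bin histogram of the normalized image; a
  constant image returns its constant (there are no two classes to
  separate). Foreground is `I > T`.
- **Connectivity pairing**: foreground components use 8-connectivity,
  hole filling treats background as 4-connected — the standard dual
  pairing that avoids topological paradoxes.
- **Ties**: equal-size largest components resolve to the one whose first
  pixel comes earliest in row-major order; equal tile means keep
  row-major tile order (the ranking sort is stable); equal candidate
  scores keep the lower index (higher-ranked seed). All choices make the
  pipeline bit-reproducible.
- **FIFO frontier**: breadth-first ordering makes the running-mean
  criterion deterministic; the mean is updated after every accepted
  pixel, starting from the seed reference.
- **Degenerate inputs**: a constant slice normalizes to all zeros and
  produces an empty brain mask with a warning and zero candidates; a
  seed whose own pixel violates the criterion yields an empty region
  flagged `degenerate`, kept in the per-seed accounting with score 0.
- **Reference-mask resampling**: references are resampled to the working
  grid by nearest neighbor for scoring; reported metrics therefore refer
  to the working grid, and only the final best mask is mapped back.

## Reference-free selection

Best-ROI selection against a ground-truth mask is the faithful
evaluation path but unusable at inference time. Without a reference the
pipeline ranks candidates by a contrast proxy — mean interior intensity
minus the mean of a 2-pixel dilated rim — and flags the output as
unsupervised selection. The proxy favors compact hyperintense regions
and agrees with the Dice-based choice on the phantom suite, but it is a
heuristic, not part of the evaluated method.

## Eight-metric panel

Acc, IoU, DSS, Sn, Sp, EF, OF and PSNR are all derived from the pixel
confusion counts. OF equals Sn by definition and DSS = 2·IoU/(1+IoU);
both identities are asserted in tests. EF = FP/(TP+FN) may exceed 1.
PSNR uses the standard 10·log10(255²/MSE) between 0/255-encoded masks
and is infinite for identical masks; it is reported for completeness but
carries no information beyond the error pixel count. Percent-style
metrics are stored as fractions and rendered as percentages only in
reports. Empty-vs-empty masks score Dice 1.0 (perfect agreement by
convention); ratios against an empty reference raise in the scalar API
and score 0 inside batch reports so degenerate candidates rank last
rather than aborting a run.

## Phantom generator

Phantoms emulate the gross radiological structure the method depends on:
dark background (0.0), bright elliptical skull ring (0.8) separated from
a mid-intensity brain ellipse (0.45) by a 10 px dark gap, and a
hyperintense tumor disk (0.9, radius 12–24 px) strictly inside the
brain, with optional dark core (0.1, half the tumor radius) and additive
Gaussian noise (σ = 0.02, clipped to [0, 1]). The ring is brighter than
brain tissue on purpose: thresholding alone cannot remove it, so the
largest-component step of the stripper is genuinely exercised. The suite
generator randomizes tumor position, radius, and intensity (0.78–0.95,
keeping contrast ≥ ~0.3 over brain) with all draws derived from one
master seed.

What the phantoms do **not** model: anatomy (gyri, ventricles, midline),
partial-volume effects, bias fields, Rician noise statistics, multifocal
or infiltrative lesion shapes, and inter-scanner intensity variation.
Passing the phantom suite therefore demonstrates algorithmic
correctness — each stage does what it claims on inputs satisfying the
method's assumptions — not clinical performance on scanner data.

## Problem sizes

The test suite and the reproduction script use 20-phantom noisy suites,
20 ringed stripping phantoms, 10 dark-core phantoms, 200 random 64×64
mask pairs for the metric oracle, and 100 random 16×16 grids for the
growing oracle; the whole suite runs in well under a minute on one CPU.
These sizes give stable averages while keeping every check cheap to
rerun.

## Known limitations

- Single-slice, single-modality: no 3-D growing, no multi-modal fusion.
- Selection of the best candidate requires a reference mask to mirror
  the evaluated method; the unsupervised fallback is a proxy.
- The tolerance is a global constant; slices with different tumor/brain
  contrast may need a different value (`--tolerance`, config YAML).
- PSNR between binary masks is reported but nearly redundant with the
  error count; comparisons across publications using other PSNR
  conventions are not meaningful.
- No DICOM input, bias-field correction, or intensity standardization;
  NIfTI volumes are sliced along the third axis only.
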