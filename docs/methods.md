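# Methods

## The detector

cytoblob implements multiscale blob detection with the scale-normalized
Laplacian of Gaussian. The working representation is a 2D float image in
[0, 1]; integer containers (8/16-bit PNG/TIFF/JPEG) are mapped linearly
from their dtype range and color is reduced with Rec.601 luma weights
(0.299, 0.587, 0.114). No other preprocessing is applied by default — the
detector is meant to cope with the raw staining and exposure variability of
cytology fields.

For each scale σ (the Gaussian **standard deviation**, in pixels — the
variance t = σ² appears only as the normalization factor), the image is
convolved with sampled analytic Gaussian and Gaussian-second-derivative
kernels and the normalized response σ²(L_xx + L_yy) is formed. Three
numerical choices matter here:

* **Kernels.** We sample the analytic derivative kernels directly (rather
  than finite-differencing the smoothed image) and de-mean the
  second-derivative kernel so its weights sum exactly to zero. Truncation
  at 4σ otherwise leaves a small DC residual (~1e-4 on a constant image)
  that would break the exact annihilation of flat regions; with the
  correction, a constant image produces a response volume that is zero to
  ~1e-16. Truncation is configurable via `truncate` (default 4σ, <0.01%
  kernel mass lost).
* **Borders.** All convolutions use reflection padding, which conserves the
  image mean and avoids the spurious edge responses a zero pad would
  create.
* **Sign convention.** A dark region of size ~σ yields a *positive*
  response. The default polarity is dark (hematoxylin-stained nuclei);
  `polarity="bright"` negates the volume so extremum search always looks
  for maxima.

For an ideal Gaussian dip of scale σ_b the normalized center response is
proportional to σ²/(σ² + σ_b²)², which peaks exactly at σ = σ_b — this
closed form is what the scale-recovery tests exercise. The response is
covariant to translation and 90° rotation exactly, and to rescaling up to
grid discretization.

## Extremum selection and suppression

Detections are voxels of the (scale, y, x) volume that are **weak local
maxima** of their full 3×3×3 neighborhood (no neighbor exceeds them), pass
the response thresholds, lie on interior scale layers (an extremum needs a
scale neighbor on both sides) and avoid the 1-pixel spatial border. The
weak (≥) comparison is deliberate: exact response plateaus arise
systematically when an image is upsampled by pixel replication and a
symmetric peak straddles the doubled grid; a strict comparison would reject
every plateau voxel and the detector would go blind on such inputs. On
tie-free volumes the weak and strict rules coincide, and plateau duplicates
(which share one response value) are collapsed deterministically by the
suppression stage, whose tie-break is lexicographic in (y, x, σ).

Thresholds: `threshold_rel` (default 0.1) is a fraction of the volume
maximum — relative thresholding adapts to the large stain-intensity
differences between fields — plus an optional absolute floor
`threshold_abs` (default off). Responses below 1e-9 are treated as
numerical noise and never become blobs (this is the same tolerance to which
constant inputs annihilate). Suppression is greedy non-maximum suppression
on discs of radius r = √2·σ̂: a later blob is dropped when the circle–circle
intersection exceeds `overlap_max` (default 0.5) of the smaller disc's
area. No sub-pixel or sub-scale interpolation is performed; reported
centers are integer grid positions and σ̂ is always one of the scheduled
values.

The default schedule is log-spaced, 10 scales over σ ∈ [2, 16] px, spanning
nucleus sizes typical of 10×–40× cytology fields; log spacing gives a
constant relative scale step, matching the relative nature of the
one-schedule-step tolerance used throughout the tests.

## Cropping

A blob's ideal crop corners are (x ± r′, y ± r′) with r′ = scale_factor·r
(default scale_factor 1.0, exposed on the CLI — larger values take more
cytoplasm context). Rasterization floors the min corner and ceils the max
corner so no covered pixel is lost (a 1e-9 epsilon guards integer corner
positions against float fuzz in r = √2σ), then clips to the frame. Boxes
clipped below 25% of their rasterized area are dropped and logged rather
than emitting uninformative edge slivers; that floor is configurable.
Crops are cut from the original color frame even though detection runs on
grayscale.

## Evaluation

Matching is greedy nearest-first and one-to-one: candidate
(detection, truth) pairs are sorted by center distance (ties broken by
truth then detection index, so results are deterministic) and accepted when
the distance is within the gate — a fixed pixel radius (default 10 px) or
each truth cell's own radius (`match_dist="radius"`). From the resulting
counts: precision = tp/(tp+fp), recall = tp/(tp+fn), F = harmonic mean,
and accuracy = tp/(tp+fp+fn). A pure detection task has no true-negative
count, so "accuracy" is this Jaccard-style quantity; whenever fp = 0 it
equals recall. Metrics with zero denominators are reported as N/A, never
coerced to 0 or 1. Printed percentages use half-even rounding to 2
decimals.

## The synthetic generator

`cytoblob.synthetic` renders the study conditions for every ground-truth
experiment: a bright background (level 0.85) carrying a smooth
multiplicative stain drift (amplitude 0.08, from a bicubically upsampled
5×5 random field), n dark isotropic 2D-Gaussian nuclei with per-cell scale
σ ∈ [3, 6] px and contrast 0.35–0.6, additive Gaussian pixel noise
(sd 0.02), clipping to [0, 1], and a fixed pink/purple tint (nucleus
purple (0.38, 0.22, 0.55) → background pink (0.96, 0.80, 0.90), linear in
intensity) so the color-to-gray path is exercised. Nuclei are placed by
rejection sampling with a 3σ border margin and center separation
> 1.25·(r_i + r_j) unless overlap is allowed; the slight clearance beyond
tangency reflects non-overlapping nuclei in a well-spread smear. The
standard test scene is 256×256 with 20 cells and seed 11, fixed once. All
randomness comes from an explicitly pinned PCG64 generator, so scenes are
bit-reproducible across platforms. Sequences translate one rendered scene
by a per-frame drift with wrap-around, standing in for slide-sweep video.

Ground truth records each center and radius √2·σ — the detector's own
radius law — so recovery comparisons are unit-consistent.

What the generator does **not** emulate: elliptical or textured nuclei,
overlapping cell clusters, cytoplasm boundaries, blood or debris, focus
variation, and compression artifacts. Passing recovery tests therefore
demonstrates correctness of the scale-space machinery on the blob model the
LoG assumes, not clinical-grade performance on real smears; isotropic
Gaussian nuclei are deliberately matched to that model so the tests have a
clean analytic target.

## Problem sizes and runtime choices

The recovery experiments use 64×64 single-nucleus fields (50 trials per
σ ∈ {2, 3, 4, 6}, schedule log-spaced σ ∈ [1.4, 9], 12 scales — chosen to
bracket the tested scales with margin on both sides), 256×256 20-cell
scenes for end-to-end checks, and 160×160 6-cell scenes for the video
pipeline; these sizes give sub-second per-experiment runtimes while keeping
every nucleus several σ from the borders. Brute-force oracle comparisons
run on 5×32×32 volumes where the triple-loop scan is exact and fast.

## Known limitations

* Merged or overlapping nuclei produce a single (or displaced) extremum;
  there is no watershed separation.
* Centers are grid-quantized; for large σ on small fields the stain drift
  can bias the extremum by about a pixel.
* σ̂ is quantized to the schedule, so radius estimates inherit the schedule
  step.
* Video containers are decoded through imageio and require a suitable
  backend plugin; a directory of frame images is the fully supported path.
* Detection "accuracy" definitions vary across the literature; only the
  tp/(tp+fp+fn) form is computed here.
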