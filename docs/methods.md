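# Methods

## Scope and model

`odseg` localizes and segments the optic disc (OD) in RGB fundus photographs
using only classical image operations: morphology for structure suppression,
a circular Hough transform (CHT) for localization, a grow-cut cellular
automaton for boundary segmentation, and a direct least-squares ellipse for
the reported outline. Everything is deterministic; there is no training step.

The method assumes the OD is (i) among the brightest structures after
illumination normalization, (ii) roughly circular at a known physical scale,
and (iii) separated from the background by an intensity edge that grow-cut
can stall on. Images violating these assumptions (total rim washout, disc
hidden by haemorrhage) are expected failure modes.

## Preprocessing

Green channel in [0, 1] → optional 3×3 median → grayscale opening (disc
radius 8 px) → background by 89×89 arithmetic-mean filter with replicate
padding → subtraction → global linear shade correction.

* **Median prefilter** (`preprocess.median_radius`, default 1, 0 disables):
  impulse noise must be removed *before* any erosion, otherwise each dark
  impulse is smeared to the size of the structuring element and the image is
  destroyed at realistic salt-&-pepper densities. A 3×3 window removes ~5%
  density impulses while leaving 2–6 px vessels essentially intact.
* **Opening radius 8 px** (`preprocess.open_radius`): larger than bright
  specular reflexes and thin bright artifacts, much smaller than the disc
  (radius ≥ 29 px at working scale), so the disc survives.
* **Mean kernel 89 px** (`preprocess.kernel`): not critical, only needs to
  blur out every visible structure; on images narrower than the kernel the
  largest odd fitting kernel is used. Replicate padding avoids an artificial
  dark vignette at the border.
* **Shade correction**: the modal intensity of the subtracted image is found
  on a 256-bin histogram spanning its range (ties to the lowest bin, mode =
  bin center) and mapped to 0.5; values are clamped to [0, 1] *after* the
  shift (the quantity that can actually leave the interval). The map is
  invariant under constant offsets of the input, and the corrected background
  of any image sits at 0.5 ± half a bin.

## Detection

Vessel-filling grayscale closing (disc radius 15 px, above maximal vessel
caliber) → bilinear resize to a 565-px working width (DRIVE-like, making the
29–50 px radius band meaningful across cameras) → edge extraction → CHT.

* **Edge extraction**: Gaussian-derivative gradient (σ = 2) with non-maximum
  suppression and hysteresis, thresholded at the 0.80/0.95 *quantiles* of the
  gradient magnitude. Quantile thresholds make edge extraction
  contrast-adaptive: after shade correction the disc rim can be a weak
  gradient in absolute terms while still being the dominant one.
* **Accumulator**: per-radius vote counts normalized by the circle perimeter,
  so 1.0 means every perimeter pixel voted. Hypotheses are the local maxima
  of the (r, row, col) accumulator; ranking is by strength, ties broken by
  smaller radius, then row, then column, for full determinism.
* **Sensitivity ladder** (`detect.sensitivity_ladder`): accumulator-threshold
  fractions 0.95, 0.90, 0.85, 0.80, 0.70, 0.50, 0.30, 0.15, 0.05, walked
  strict-to-permissive; the strongest circle of the first non-empty level is
  the detection. Blurred, slightly elliptical rims rarely reach even half of
  the theoretical full-perimeter support (a clean phantom peaks around
  0.3–0.45), so the ladder deliberately extends well below the strict levels;
  stopping at the first level that fires preserves the preference for
  confident circles. The hypothesis set at a stricter level is by
  construction a subset of any more permissive level.
* Failure to find any circle at the most permissive level raises a distinct
  detection-failure error rather than returning a guess.

## Grow-cut segmentation

Cell state (l, θ, C): label in {+1, −1, 0}, strength θ ∈ [0, 1], value C =
shade-corrected green intensity (C_max = 1 for [0, 1] rasters, 2^L − 1 for
L-bit integers). Attack force λ(x) = g(x)·θ(x) with g = 1 − |C_p − C_x|/C_max,
a decreasing function of the intensity difference: similar pixels attack at
nearly full force.

* **Update scheme**: synchronous sweeps — all attacks computed from the
  previous sweep's state; the strongest attacker wins, exact ties go to the
  earliest neighbor in row-major scan order; a cell is conquered only by a
  strictly greater λ than its own strength, so strength-1 seeds are immovable
  and per-cell strength is non-decreasing. Termination: a sweep with zero
  conquests (or `growcut.max_iter`, default 500, reported as a non-converged
  flag, not an exception).
* **Neighborhood**: 8-connected by default (`growcut.neighborhood`, 4
  available). In the uniform-intensity limit g ≡ 1 and the converged
  partition is exactly the Chebyshev nearest-seed-set partition — one of the
  analytic checks in the test suite, alongside exact equivalence with a naive
  triple-loop reference on random grids.
* **Seeding** (`growcut.fg_scale` = 0.4, `growcut.bg_scale` = 2.5): the
  foreground disk must stay safely inside the true disc under detection
  jitter (0.4 r keeps margin even with a few px of center error), while the
  background ring must stay safely outside it (2.5 r). Near image borders the
  background radius is pulled in just enough to keep background seeds.
  Evolution runs on the bounding crop of the seeded ring (the outside is
  entirely strength-1 background and can never change), at the detection's
  working resolution.
* Post-processing keeps the connected component containing the seed center;
  vessels crossing the rim can split off fragments, which are discarded.

## Ellipse approximation

The outer boundary of the mask is traced (Moore neighborhood, holes filled so
only the outer contour is returned) and fitted with the direct least-squares
ellipse-constrained conic fit; axes are ordered and the angle folded into
[0, π). A circle-constrained (Kåsa) fit is available (`--circle`). The
reported mask is the rasterized fit; the raw grow-cut mask is also saved, and
metrics can be computed on either.

Fitting pixel-center boundary coordinates carries an inherent ~half-pixel
inward bias; at disc scales (semi-axes ≥ 20 px) the round-trip Dice of
rasterize∘fit∘trace on convex masks stays ≥ 0.98.

## Metrics

SN = TP/(TP+FN), SP = TN/(TN+FP), Acc = (TP+TN)/N, PPV = TP/(TP+FP),
FDR = FP/(FP+TP), overlap = |A∩B|/|A∪B| (Jaccard), Dice = 2|A∩B|/(|A|+|B|).
Dice = 2·overlap/(1+overlap) holds to 1e-12 by construction. Ratios with a
zero denominator are NaN and flagged in `undefined`, so batch means can
exclude them explicitly. Detection success = detected native center pixel
inside the truth mask (boundary inclusive) — a deliberately simple, formal
criterion.

Hausdorff: symmetric boundary-to-boundary Hausdorff distance in pixels, also
reported divided by the truth mask's equivalent diameter (2√(area/π)) as a
unitless boundary error. The normalization is this package's own convention;
unitless Hausdorff values from other sources may use a different one and are
not directly comparable.

## Phantom generator

`PhantomSpec` defaults describe a DRIVE-like photograph: 584×565, field-of-view
radius 0.48·min(H, W), background 0.45 with a ±0.10 horizontal illumination
ramp, disc radius 40 px (axis ratio 0.92, rim blur σ = 2) at a nasal position,
5 vessels (width 3 px, 0.18 darker than background) as quadratic Bézier
curves from the disc center to the FOV rim, optional exudates (radius 4–10 px,
kept ≥ 1.6 disc radii from the center so they stay below the Hough band), and
one of none / gaussian (σ = 0.05) / salt-&-pepper (density 0.05) / speckle
(variance 0.05) noise applied last. The truth mask is the exact disc ellipse
before blur and noise. Batch generation jitters position (±60/±40 px), radius
(±8 px — keeping every radius inside 29–50 at working scale), contrast and
ellipticity; everything is reproducible from a single seed.

What the phantoms do *not* emulate: real textural variation of the retina,
papillary atrophy rings, haemorrhages, rim-obscuring pathology, chromatic
aberration, compression artifacts. Passing the phantom-batch tests therefore
demonstrates correct mechanics and noise robustness of the pipeline, not
clinical-grade performance on patient data.

## Problem sizes and test design

The suite exercises 50 clean jittered phantoms end-to-end (detection success
≥ 98%, median ellipse-mask Dice ≥ 0.90) and 50 phantoms per noise model for
detection (success ≥ 90%), sizes chosen to estimate those rates with small
binomial error while keeping the suite quick to run. Automaton correctness is
checked exactly against a brute-force reference on 200 random 6×6 grids and
against the analytic Chebyshev partition on a uniform field; determinism is
checked at byte level on written artifacts.

## Known limitations

* The detector returns one disc; images with two equally supported circular
  structures resolve by accumulator strength and the deterministic tie-break,
  not by anatomical priors.
* Grow-cut stalls on *some* intensity edge; with a washed-out rim the flood
  can leak and the component filter only partially contains it.
* The ellipse fit assumes a convex, roughly elliptical component; grossly
  non-elliptical masks (severe leaks) produce fits that average the error
  rather than flag it.
* Working-resolution resampling quantizes the radius band; discs whose native
  radius maps just outside 29–50 px at 565-px width are not found.
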