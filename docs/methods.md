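# Methods

This note documents the models, parameter choices and numerical
conventions behind `octaperf`, and what the synthetic-data validation
does and does not establish about real OCTA images.

## Image model and conventions

An en-face angiogram is a square 8-bit grayscale array with a physical
field of 6×6 mm or 3×3 mm (nominally 304 px per side, so one pixel is
~19.7 µm or ~9.9 µm). Pixel coordinates are 0-based, row-major, origin
top-left; the point sampled by pixel `(r, c)` is its center. All
physical quantities derive from `mm_per_px = field_mm / side_px`.
Sixteen-bit inputs are linearly rescaled to 8-bit — bit depth is a
device export detail, not part of the measurement.

The quality gate rejects scans with device signal-strength index
(SSI) < 5, mirroring clinical exclusion practice. Blink and motion
artifacts, which in a clinical setting are screened visually, are
approximated by two heuristics: a blank-row fraction above 5% and a
consecutive-duplicate-row fraction above 25%. These proxies catch gross
artifacts only; the gate is deterministic and monotone in its SSI
threshold.

## Registration

Inter-visit fixation differences are modeled as a similarity transform:
rotation θ about the image center followed by translation (dx, dy), with
an isotropic scale locked to 1 by default (the protocol fixes
magnification; scale estimation is available but off). The objective is
normalized cross-correlation (NCC) of the pair after Gaussian blur
(σ = 1.5 px), which suppresses speckle while leaving the vascular
pattern — the actual registration signal — intact.

Optimization is coarse-to-fine: candidate rotations on a 1° grid over
±6°, each initialized in translation by subpixel phase
cross-correlation, then Nelder–Mead refinement of (dx, dy, θ) on the
smooth NCC surface. On synthetic pairs with known motion up to ±15 px /
±5° and 10% multiplicative speckle, recovery is typically within
0.01 px / 0.005°, far inside the 0.5 px / 0.25° requirement. A final NCC
below 0.2 raises an error and excludes the pair — the analogue of
discarding unalignable scans.

The aligned follow-up image is resampled with cubic interpolation
(bilinear inside the optimizer loop, for speed); binarization always
runs on resampled *grayscale*, never on resampled binary masks, which
would alias 1-px structures. The common-area mask is computed
analytically: a reference pixel is in the mask iff its forward-mapped
coordinate lies inside the moving image. All paired densities use this
mask as their denominator domain.

## 3-way binarization

Order of operations: noise-baseline sampling → top-hat → global noise
threshold → (Hessian branch ∥ adaptive branch) → AND. The baseline is
sampled first because the avascular zone is the only region guaranteed
to contain pure background; the global threshold is applied before both
branches so that neither operator sees sub-noise pixels.

Parameters (all exposed in `SegmentationParams`):

| parameter | default | rationale |
|---|---|---|
| noise circle radius | 50 px | the fixed radius used in the manual clinical step; configurable because 50 px is defined in pixels, so its physical extent differs between protocols, and a synthetic FAZ may be smaller (see below) |
| top-hat disk radius | 12 px | must exceed the widest vessel half-width (arcades ≈ 3–4 px) so vessels pass while background plateaus are removed |
| global threshold k | 2.0 | mean + 2·SD keeps ~2.3% of Gaussian noise pixels; the clinical description fixes only that the FAZ sample sets the noise baseline |
| Hessian scales | 1, 2, 3 px | capillary-to-arcade widths at 6×6 mm / 304 px sampling; vesselness cutoff by Otsu on the response (no published cutoff exists) |
| adaptive window | 31 px (odd) | larger than the widest vessel so the local median reflects background; offset 2 gray levels suppresses flat-region noise |

The adaptive branch uses an element-based median (`median_filter`,
reflect boundary); note that an element-based median of an odd window is
an actual sample value, not an interpolated midpoint. The AND
combination makes the final map a subset of each branch — conservative
by construction, which is why measured VD runs below the raw foreground
fraction. On pure-noise images the final map stays below 2% density.

Skeletonization is topology-preserving thinning to 1-px centerlines
(component count conserved, skeleton ⊆ vessel map).

For unattended runs a helper proposes the three darkest non-overlapping
circles near the frame center as noise-sampling sites; when the
avascular zone is smaller than the default 50-px circle (true of the
synthetic FAZ, and in fact of most real FAZs), the pipeline shrinks the
sampling radius to fit inside it — sampling vessels would inflate the
noise baseline and over-suppress the image.

## Metrics

- **VD / skeleton VD**: `100 · |mask ∩ roi| / |roi|`. Skeleton VD is
  computed on the thinned map and tracks vessel length density.
- **FD**: box counting on the skeleton (never the filled map). Box
  sizes are powers of 2 from 2 px to a quarter of the image side; for
  each size the occupied-box count is minimized over 8 grid origins —
  always including the aligned (0, 0) origin, so exactly dyadic sets
  (line, filled square, Sierpiński gasket) reproduce their analytic
  dimensions to machine precision — and the dimension is the negative
  slope of the log–log least-squares fit. An empty skeleton raises an
  error: the dimension of the empty set is undefined, not zero.
- **FAZ area**: shoelace area of each replicate trace (simple polygons
  enforced via `shapely`), scaled by `mm_per_px²` and averaged over the
  1–3 replicates; the replicate SD is retained for QC.
- **Percent change**: `100 · (post − pre) / pre`, reported to one
  decimal in tables; undefined at zero baseline.

## Statistics

Paired comparisons test the pre/post differences: Shapiro–Wilk at
α = 0.05 decides normality (the clinical convention names no specific
normality test; Shapiro–Wilk is the standard choice at n ≤ 50), then
paired *t*-test or Wilcoxon signed-rank. Constant differences are a
degenerate case: flagged, with p = 1 for all-zero differences and the
exact sign-test probability otherwise. Type-I error of the pipeline is
calibrated (~5% on null simulations).

Change prediction runs a univariate Spearman screen per baseline
predictor, then one multivariable OLS of change on all predictors
jointly — no stepwise selection, complete cases only, condition number
reported and flagged above 10⁶. Both eyes of a patient are treated as
independent units by default, matching the design this mirrors (a known
limitation of that design); a cluster-robust covariance by patient is
available but off by default. p-values are unadjusted.

## Synthetic data: what it emulates, and what it does not

The generator produces a recursive bifurcating vessel tree: root
arcades start on a peripheral ring heading inward, each tip bifurcates
with probability 0.85 down to 7 levels, segment length decays by 0.85
and width by 0.84 per level from 0.7 mm / 0.07 mm at the root (floor
0.02 mm ≈ 1 px). Segments are rejected if they would enter the foveal
avascular disk (default radius 0.30 mm, matching a typical clinical FAZ
area of ~0.3 mm²) or leave the field. Rendering anti-aliases each
segment with a 1-px linear ramp, adds Gaussian background noise
(mean 30, SD 8) and multiplicative Gaussian speckle (SD 10% of the
vessel signal, level 170). These defaults give binarized densities of
~8–12%, skeleton densities ~5–8% and FD ≈ 1.5 — FD and skeleton VD in
the clinically reported range, VD below it, because the synthetic tree
is necessarily sparser than a real capillary bed and the AND
binarization is conservative.

The longitudinal effect removes random *terminal* segments until a
target fraction of total centerline length is gone (overshoot at most
one segment), never disconnecting the retained tree — emulating
progressive capillary closure. Dropout is therefore defined on length:
at 10% length dropout the area-density ground truth falls only ~6%,
since terminals are the thinnest segments. The ground-truth record per
eye stores both, plus the applied rigid motion.

Misalignment is simulated by transforming the tree's physical
coordinates and re-rendering, not by warping the rendered image: two
real acquisitions of a shifted retina are both native samplings, and
warping an existing render would blur 1–2 px capillaries into a ~10%
spurious density loss. One resampling (of the follow-up image, at
registration) is inherent to the real workflow and is retained; it
leaves a residual ≈ −1 to −2% density offset at zero dropout, small
against the ≥5% dropout effects studied, and common to all effect
levels in paired designs.

Not modeled: OCTA decorrelation-noise physics, projection artifacts,
anatomically distinct SCP/DCP layers (slabs are independent trees),
irregular FAZ boundaries (the disk is clean, though the metrics accept
arbitrary simple polygon traces). Passing the synthetic suite therefore
establishes the *correctness of the measurement chain* — registration
recovery, oracle-exact operators, analytic fractal dimensions,
detection and ordering of known dropout effects, calibrated statistics
— not the clinical accuracy of any particular threshold choice on real
scanner output.

## Problem sizes used in validation

Registration recovery uses 50 seeded trials at the full 304-px frame.
The cohort analysis uses 40 eyes at 10% mean dropout (the cohort size
of the study design this mirrors) and 12-eye cohorts at 5% and 20% for
the ordering check, which is near-deterministic because trees are
paired across levels by seed. Floor-effect power uses 200 simulations
(change = −0.5·baseline + ε, baseline ~ N(31.3, 5.58²) like a typical
full-thickness VD distribution, ε SD 2.8 ≈ half the baseline SD) and
type-I calibration 1000 null simulations.
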