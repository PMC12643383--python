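# Methods

## Scope and model of the data

`octaskin` processes dermatological OCT-angiography (OCTA) volumes: 3D
scalar intensity fields indexed `(z, y, x)` with `z` depth below the skin
surface, `y` the fast lateral axis and `x` the slow-scan axis, so a
B-scan is the `(z, y)` frame at a fixed `x`.  Skin OCTA suffers from a
characteristic artifact inventory — skin tilt, inter-B-scan gain
fluctuations (vertical stripes in en-face views), speckle, depth
attenuation, and projection tails (false flow replicated below superficial
vessels) — and the toolkit implements a standard five-stage enhancement
pipeline against it, en-face projection and reference-mask generation, a
synthetic phantom generator, and an eleven-metric segmentation evaluation
suite that works identically on 2D and 3D binary masks.

## Preprocessing pipeline

Flattening: the surface of each A-line is the first depth at which the
axially Gaussian-smoothed intensity (sigma 2 slices) exceeds 50% of that
A-line's maximum; the index map is median-smoothed laterally (5×5), dead
A-lines borrow neighbour values, each A-line is shifted so its surface
maps to z = 0, the first 30 slow-scan frames are discarded and the volume
cropped to 90 slices (all parameters exposed).  Voxels shifted in from
below the acquisition floor are zero-filled; an error is raised only when
the requested output depth exceeds the input depth.

The four enhancement stages, applied cumulatively:

1. **B-scan normalization** — each frame is divided by its mean, removing
   inter-frame multiplicative bias (unit-mean frames; relative contrast
   within a frame untouched; all-zero frames pass through with a
   warning).  The operation is idempotent and scale-invariant.
2. **Projection-artifact attenuation** — a step-down exponential filter:
   per A-line, `C(0)=0`, `C(z)=λ·C(z−1)+in(z−1)`,
   `out(z)=max(0, in(z)−w·C(z))` with defaults λ = 0.85, w = 0.3.  The
   output never exceeds the input and `w = 0` is the identity.  The
   recursion subtracts a decaying memory of the overlying signal, which
   is exactly the depth profile of projection tails.
3. **Median + contrast stretch** — 3D median (default 3³, edge
   replication), then a volume-wide linear stretch of the [1, 99]
   percentile range onto [0, 1] with clipping (constant volumes map
   to 0).  Volume-wide rather than per-slice stretching preserves the
   depth attenuation profile instead of amplifying deep noise.
4. **Frangi vesselness** — multiscale Hessian tube enhancement at scales
   4, 6, 8 px with α = 0.01 (plate sensitivity), β = 1 (blob
   suppression), and structure constant c defaulting to half the maximum
   Hessian Frobenius norm per scale.  Eigenvalues are sorted by magnitude
   |λ1| ≤ |λ2| ≤ |λ3| and the response is zeroed wherever λ2 > 0 or
   λ3 > 0: bright tubes have negative principal curvatures, so dark
   (inverted) structures are suppressed *explicitly*.  We author this
   response (on scikit-image's Hessian primitives) rather than calling a
   library vesselness because formulations that emulate the polarity
   rule through eigenvalue clipping fail on ideal tubes where λ1 ≈ 0,
   letting dark vessels through at full response.

## En-face projection and reference masks

The superficial/deep split is a depth-band boundary, default 400 µm below
the flattened surface (slice 27 at 15 µm axial spacing) — the approximate
lower extent of the superficial dermal plexus.  Projections are
average-intensity (AIP), not maximum, because the mean is less sensitive
to speckle outliers; each AIP is clipped at its 99th percentile p and
mapped [0, p] → [0, 255].  Reference 3D masks are produced from a
normalized, tail-attenuated volume by global thresholding (default: Otsu
on the 3D histogram), morphological closing (ball radius 1; the closing
pads so border-touching vessels survive), and removal of 26-connected
components strictly smaller than 100 voxels.  2D reference masks are Otsu
binarizations of the band-wise mask projections, applied to the
fractional (mean-over-depth) projection directly.

## Evaluation metrics

From TP/FP/FN/TN voxel counts: Dice, precision, recall, balanced
accuracy.  Empty-denominator conventions: both masks empty → 1, one-sided
empty → 0; balanced accuracy applies the same rule to the complements, so
two identical full-field masks score 1.

Vascular density VD = |S|/|Ω|; vasculature fragmentation VF = connected
component count (8-connected in 2D, 26-connected in 3D); fractal
dimension FD by box counting: 20 box sizes geometrically spaced between 2
and the largest power of 2 fitting the smallest mask dimension, 5 grid
offsets per size with the minimum count retained, FD = −slope of the
least-squares fit of log N(D) vs log D.  VD/VF/FD are computed on both
masks and summarised as signed relative percentage differences
100·(pred−ref)/ref (NaN when the reference value is 0; the sign encodes
over- vs under-segmentation).  Small-lattice bias: on a filled 128²
square the slope is ≈ 1.90 because large boxes over-count partial rows;
512² reaches 1.92 and the limit tests use that size.

CAL is the product of three [0, 1] terms: connectivity
`1 − min(1, |#c(Sgt) − #c(S)| / |Sgt|)` (denominator = reference vessel
pixel count), area `|(δ₂S ∩ Sgt) ∪ (S ∩ δ₂Sgt)| / |S ∪ Sgt|`, and length
`|(φS ∩ δ₃Sgt) ∪ (δ₃S ∩ φSgt)| / |φS ∪ φSgt|`, with δr dilation by a
disc/ball of radius r and φ skeletonization (2D thinning, 3D Lee).
Both-empty similarity terms default to 1; an empty reference is an error.

## Synthetic phantom

The generator emulates the study conditions the pipeline assumes, not the
physics of OCT: random-walk branching centerline trees confined to two
depth bands (default 4 thin superficial trees, radii 1.5–2.5 px, and 2
thick deep trees, radii 3–5 px, mirroring the depth contrast of dermal
plexuses), rasterized as tubes.  Rendering: background 0.1 + vessel
signal 1.0, plus projection tails `0.4·exp(−0.05·Δz)` accumulated below
vessel voxels (1/e length ≈ 300 µm at 15 µm/slice, so tails genuinely
traverse the deep band — the defining property of the artifact), times
`exp(−0.01·z)` depth attenuation, times per-B-scan lognormal gains
(σ = 0.2, the stripe artifact), times unit-mean gamma speckle with
contrast 0.3.  All randomness flows from one seed; output is
bit-reproducible.  Not modeled: motion artifacts, shadowing, realistic
speckle correlation, scanner PSF — so passing phantom tests demonstrates
correct artifact-specific behavior of each stage, not clinical
performance on real volumes.

Mask degradation operators for metric testing: dilate/erode (full
connectivity), fragment (radius-4 spherical cuts at random skeleton
points — large enough to sever the thickest default vessels), spurious
blob insertion, and lateral shift with zero fill; magnitude 0 is always
the identity.

## Problem sizes and numerical choices

Tests and the demo run phantoms at 48×64×64 to 90×128×128, sizes at
which every stage's behavior is already fully expressed; the demo
(phantom → 5 stages → 15 AIPs → per-stage masks → 10-row metric CSV)
completes in seconds and is byte-reproducible per seed.  B-scan means
after normalization agree with 1 to single precision (~1e-6 relative),
since volumes are float32.  Degenerate rules: constant volumes stretch to
0, constant projections binarize to empty with a warning, FD of an empty
mask is an error (NaN inside the aggregate report), single-pixel masks
have FD 0.

## Known limitations

The step-down filter is subtractive and also removes some genuine deep
signal; its benefit is net (deep-band density error on phantoms shrinks
several-fold when tails are present, but the filter is not conservative).
The box-counting slope is lattice-biased low for space-filling masks at
small sizes.  3D skeletonization can erase one-voxel-thick plates (it is
designed for tubes).  The reader supports multi-page TIFF and image
directories only; proprietary scanner formats and DICOM are out of scope.
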