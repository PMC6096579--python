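# Methods

`nucorg` quantifies the 3D organization of pericentromeric heterochromatin in
early-embryo nuclei from multi-channel confocal z-stacks: where in the
nucleus FISH-labelled satellite signals sit radially, whether they are
polarized to one sector, how many distinct spots there are, and how they
relate to nucleolar precursor bodies (NPBs).  Because no suitable public
image set exists at this scale, every stage is validated against a synthetic
phantom generator with exact ground truth.

## Coordinate and intensity conventions

All grids are `(z, y, x)` arrays (z-major TIFF page order).  Spacing,
coordinates and distances are micrometres in the same axis order; the
physical position of voxel `(k, j, i)` is `(k·sz, j·sy, i·sx)`.  Intensities
are 8-bit.  Default spacing is `(0.37, 0.2, 0.2)` µm: 0.37 µm optical
sections as used on the source microscope, with a confocal-plausible
0.2 µm xy pixel (instrument xy pixel size is rarely recorded; it is
configurable everywhere).

## Eroded volume fraction (EVF) and d_max

The EVF of a point is the fraction of nuclear volume lying between the point
and the nuclear membrane: 0 at the periphery, 1 at the centre.  Its key
property is shape universality — uniformly distributed points have uniform
EVF whatever the nuclear shape — which makes radial position comparable
across nuclei without assuming sphericity.

On a voxel grid we compute the anisotropic Euclidean distance-to-background
`d(x)` (scipy EDT with physical sampling) and define

```
EVF(x) = ( #{y : d(y) < d(x)} + ½·#{y : d(y) = d(x)} ) / N
```

(mid-rank convention, `N` = mask voxel count).  A subtlety matters here: the
raw EDT is heavily tied — every voxel whose nearest background voxel lies
across a face shares exactly the same depth, and the largest such plateau
holds 5–8 % of the nucleus.  Left alone, that plateau alone breaks the
uniformity property at the 0.03-KS level no matter how fine the grid.  We
therefore sub-rank tied voxels by a secondary key, the Gaussian-smoothed EDT
(σ = 1 voxel), which orders a plateau by the depth of each voxel's
neighbourhood.  The raw depth remains the primary sort key, so
`d(x) < d(y) ⇒ EVF(x) ≤ EVF(y)` holds exactly, and the marginal EVF
distribution becomes uniform to ~1e-4.  `strict` and `inclusive` rank
conventions are available as options.

The nucleus is divided into `F` fractions of identical volume (default
`F = 1000`, clamped to `N` for small masks) ordered periphery → centre; the
per-fraction proportions `p_k` of total signal give a cumulative curve
`C_k`, and

```
d_max = D_k*  with  D_k = C_k − k/F,  k* = argmax_k |D_k|  (ties: smallest k)
```

Positive `d_max` means a peripheral bias, negative a central one, and
`|d_max| ≤ 1` always.  "Largest signed difference" could also be read as
`max_k D_k`; both rules are implemented (`rule="max_signed"`), largest
magnitude with sign retained is the default and is recorded in output.

Intensity mode (raw voxel values inside the mask, no background
subtraction) is the default profile; a `spots` mode profiles binary spot
masks, and per-spot EVF lookup supports per-spot radial histograms.

## Segmentation

**Nuclei** — optional smoothing (median/Gaussian/opening/closing and
grayscale hole filling, the latter by morphological reconstruction by
erosion from the border so dark NPB interiors do not punch holes), then an
automatic threshold: Otsu, Kapur maximum-entropy (both on 256-bin
histograms) or RATS (`t = Σ w·I / Σ w`, `w` = squared gradient magnitude,
gradients on the physical grid).  6-connected components smaller than
200 µm³ or with more than 30 % of their surface voxels on the image border
are dropped (both configurable; no values for these filters are standard,
so they are exposed).  Touching nuclei are split by a watershed on the
negated anisotropic distance map, seeded at h-maxima (default h = 1 µm,
seeds lightly dilated to fuse plateau fragments); the foreground voxel set
is preserved exactly and the operation is idempotent.

**Spots** — Gaussian smoothing (σ = 0.2 µm) and a white tophat (ellipsoidal
footprint, radius 1 µm physical) remove smooth background; spot voxels are
those at or above one quarter of the maximum denoised intensity inside the
nuclear mask.  The quarter-max reference is taken on the *denoised* signal
(the alternative, raw, is noise-fragile); components below 0.05 µm³ are
discarded.  Centroids are intensity-weighted physical coordinates
(geometric optional).

**NPBs** — dark, round bodies in the DNA counterstain.  Intensities inside
the nucleus are inverted, smoothed, thresholded by Otsu on the in-mask
inverted histogram, watershed-split (h = 0.6 µm, so near-touching voids
separate while elongated streaks stay whole), then filtered by volume
(≥ 1 µm³) and sphericity (`π^{1/3}(6V)^{2/3}/A` from a marching-cubes
surface; ≥ 0.6).  This detector is an automated reconstruction of what is
often a visual count, and a flat nucleoplasm (contrast below `min_depth`)
yields zero detections by design.  Association: an NPB is associated with a
channel if at least one spot voxel lies within `gap_µm` (default 0.5 µm,
anisotropy-aware EDT) of its surface; the associated/total ratio is
reported per channel.

## Polarity test

The statistic is the distance between the nuclear centroid and the centroid
of all spot centroids, after moment-based shape normalization: coordinates
are whitened by the unit-determinant `C^{-1/2}` of the mask's second-moment
matrix (isotropic second moments, volume preserved) and divided by the
radius of the volume-equivalent ball.  For a sphere the transform is the
identity and the scale is the radius, so a single spot at the boundary pole
scores ≈ 1 and a centro-symmetric pattern scores 0.

The null is simulated: 500 patterns of `n_spots` voxel positions drawn
uniformly over the mask (point sampling, not spot-sized patterns — a
recorded simplification), each reduced to the same distance.  Two p-values
are reported:

* `p` — one-sample t of the observed distance against the simulated sample
  (`t = (mean(null) − observed)/(sd/√n_sim)`, one-sided so that large
  distances give small p and central patterns give p near 1).  This is the
  historically used form; note that as a test of a single nucleus it is
  anti-conservative (the observed value is one draw from the null, so |t|
  scales with √n_sim under H0).
* `p_empirical` — `(1 + #{null ≥ observed})/(n_sim + 1)`, uniform under the
  null.  All calibration statements (type-I error ≈ 5 %, p-uniformity,
  power) are made with this form, and it is the recommended one.

## Statistics layer

One-sample Student's t (raw values or `(n, mean, sd)` summary form, enabling
recomputation of published stage tables; two-sided by default, which
reproduces the published 2-cell p = 0.04788 for mean 26.17 ± 5.08 vs
µ0 = 24), two-sample Kolmogorov–Smirnov (asymptotic p) for comparing d_max
distributions between stages, OLS with a categorical stage factor plus one
numeric covariate (covariate choice is the user's; residual normality by
Shapiro–Wilk and variance homogeneity by Bartlett are reported), and
Fisher's exact test (chi-square optional) for binary annotation frequencies.
No multiple-testing correction is applied by default.

## Phantom generator

The generator emulates the study's images with exact ground truth:

* **Nucleus** — ellipsoid (default semiaxes 9 × 8 × 7 µm ≈ 2100 µm³, the
  2-cell scale; volumes shrink to ~1100 µm³ by the 16-cell stage) with an
  optional smooth angular deformation (amplitude ≤ 0.3, zero-mean harmonics
  so volume is preserved to O(amplitude²)).
* **Spots** — channel A defaults to 24 centres and channel B to 12 (the
  expected metaphase counts for the two satellite families).  Each centre
  draws a target EVF from `Beta(a, b)` and takes the voxel at that EVF rank,
  so the generated radial law is exact under the same EVF definition the
  analysis uses; `(1,1)` is uniform, `(1,5)` peripheral, `(5,1)` central.
  Polarity is injected by accepting candidates with probability
  `exp(λ(cosθ − 1))` about a random pole; λ = 0 is the null.  Centres
  avoid NPB interiors and keep a minimum mutual distance (default 1.5 µm,
  ≈ the mean nearest-neighbour spacing of 24 uniform points at these
  volumes), so spots are individually resolvable as they are in the images.
* **Rendering** — DNA channel: background 5, nucleoplasm 80, NPB voids
  dimmed ×0.4; spot channels: Gaussian blobs of peak 150 with
  σ = spot_radius/√(2 ln 4), so each blob crosses quarter-max exactly at
  `spot_radius` (0.5 µm default).  Poisson shot noise then Gaussian read
  noise (σ = 2 by default; σ = 15 gives SNR 10 relative to spot amplitude),
  clipped to 8 bits.  Everything is a pure function of `(spec, seed)`.

What the phantoms do **not** model: a realistic PSF (blobs are isotropic
Gaussians), chromatic shift, photobleaching, intra-nuclear chromatin
texture, aggregated/necklace spot morphologies, or fields of many nuclei
(multi-nucleus handling is tested by tiling).  Passing tests therefore
demonstrate correctness of the measurements under controlled geometry and
noise, not robustness to every real-microscope artifact.

## Problem sizes and numerical choices

Batch validations use compact phantoms (~30 × 88 × 88 voxels, nuclei of
~600–2000 µm³) so that a full run — 100-phantom d_max batches, 200-phantom
polarity calibration at 500 simulations each, 50 noisy segmentation
phantoms and 100 watershed cases — completes in a few minutes; single-
phantom tests use the full default grid.  Thresholds are computed on
256-bin histograms; higher-depth data are rescaled.  Watershed ties follow
scikit-image's deterministic scan order.  Degenerate inputs fail loudly:
constant images (thresholds), multi-component or planar masks (EVF, shape
normalization), zero total signal (profiles), zero-variance nulls
(polarity).

## Known limitations

* The NPB detector reconstructs an undocumented (likely visual) counting
  procedure; its absolute counts should not be compared against published
  NPB counts without calibration.
* The t-form polarity p reproduces the published interpretation but is not
  a calibrated single-nucleus test; use `p_empirical` for error-rate
  claims.
* Spot declustering is not implemented: aggregated signals segment as
  single spots, mirroring the published method's behaviour.
* `d_max` from intensity profiles includes camera background (no
  subtraction), which dilutes its magnitude relative to spot-mask profiles.
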