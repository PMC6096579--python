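# nucorg

Quantification of 3D nuclear organization in early-embryo confocal stacks:
where pericentromeric heterochromatin signals sit radially within the
nucleus, whether they are polarized to one sector, how many distinct FISH
spots they form, and how they associate with nucleolar precursor bodies
(NPBs).  Built for the kind of data produced by whole-mount 3D-FISH on
preimplantation embryos — multi-channel 8-bit z-stacks with anisotropic
voxels (0.37 µm optical sections) — and for anyone who needs
shape-independent radial statistics on segmented nuclei.

## The statistics at the core

**Eroded volume fraction (EVF).**  The EVF of a point in a nucleus is the
fraction of nuclear volume between the point and the nuclear membrane: 0 at
the periphery, 1 at the centre.  For uniformly distributed points the EVF
is uniform on [0, 1] *for any nuclear shape*, so radial distributions are
comparable across nuclei without sphericity assumptions.  The nucleus is
divided into F = 1000 fractions of identical volume ordered periphery →
centre; with p_k the proportion of signal in fraction k and C_k its
cumulative sum, the radial bias statistic is

```
d_max = C_k* − k*/F,   k* = argmax_k |C_k − k/F|
```

signed so that d_max > 0 means a peripheral bias and d_max < 0 a central
one, with |d_max| ≤ 1.

**Polarity.**  Spot confinement to one sector is measured by the distance
between the nuclear centroid and the centroid of all spot centroids, after
moment-based shape normalization (unit-determinant whitening of the mask's
second moments, distances in units of the volume-equivalent ball radius).
The observed distance is compared with 500 simulated uniform spot patterns
per nucleus; both the classical one-sample-t p-value and a calibrated
empirical-quantile p-value are reported.

Around these sit a nucleus segmenter (Otsu / maximum-entropy / RATS
thresholds, border and size filters, watershed separation on anisotropic
distance maps), a quarter-of-maximum tophat spot segmenter, an NPB
dark-body detector with surface-association scoring, a stage-wise
statistics layer (one-sample t against expected metaphase spot counts,
two-sample KS, linear models with a stage factor, Fisher's exact test), and
a phantom generator that renders synthetic nuclei with exact ground truth
for validation.  See `docs/methods.md` for the full model description.

## Worked example

Generate a default phantom (a ~2100 µm³ nucleus, 24 centre-biased spots in
channel A, NPB voids, realistic noise) and push it through the pipeline:

```python
from nucorg import (PhantomSpec, generate_phantom, segment_nuclei, segment_spots,
                    spot_metrics, evf_map, equal_volume_fractions, radial_profile,
                    dmax, polarity_test)

spec = PhantomSpec(radial_bias=(5, 1), seed=42)   # Beta(5,1): central bias
channels, truth = generate_phantom(spec)

nuclei = segment_nuclei(channels["dna"], preprocess_steps=["gaussian(1)", "gray_hole_fill"])
mask = nuclei.binary(1)

spots = segment_spots(channels["spots_a"], mask)
m = spot_metrics(spots, nuclei.table.volume_um3.iloc[0])

emap = evf_map(mask, spec.spacing)
profile = radial_profile(equal_volume_fractions(emap, 1000), channels["spots_a"])
res = polarity_test(mask, spec.spacing, spots.centroids, n_sim=500, seed=1)
```

Output:

```
nuclear volume: 2105.3 um^3 (truth 2113.0)
channel A spots: 24 (expected 24), total volume 20.02 um^3, volume fraction 0.0095
d_max (intensity mode): -0.054
polarity: distance 0.147, null 0.145 +/- 0.062, p_empirical 0.439
```

The segmented volume recovers the generated nucleus to 0.4 %; all 24 spots
are found; d_max is negative, correctly reporting the generated central
bias (its magnitude is damped because intensity-mode profiles include the
uniform camera background); and the polarity test does not reject — the
spots were sampled without a polar preference, and the observed centroid
distance sits in the middle of the simulated null.

A `nucorg` command-line tool wraps the same stages (`simulate`,
`segment-nuclei`, `segment-spots`, `evf`, `polarity`, `npb`, `measure`,
`run-all`, `report`); `run-all` drives the whole pipeline from a YAML
config and writes per-nucleus CSV tables stamped with the config hash and
seed.

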