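# Methods

## The detection model

The package treats camouflaged-region detection as an online,
single-cube feature-selection problem. A pushbroom VNIR cube
`data[line, sample, band]` (S samples × L lines × B bands) is assumed
to contain exactly two spectral populations: a majority background and
a minority camouflaged object (< 50% of pixels) whose reflectance
departs from the background only in a small part of the spectrum. No
training data, labels, or reference spectra are used.

**Stage 1 — spectral ranking.** For each band the pixel intensities are
partitioned into two classes by 1-D two-means. The fit is exact: the
optimal two-class partition in one dimension is a threshold partition,
so the implementation scans every threshold between consecutive
distinct sorted values with prefix sums and keeps the split minimising
the within-class sum of squares (first minimiser on ties — fully
deterministic, no seed). The band's discriminability is

    D(b) = |mu1 - mu2| / (sigma1 + sigma2)

with class means mu_i and *population* standard deviations sigma_i, the
lower-mean class first. A constant band is degenerate and scores D = 0.
When sigma1 + sigma2 <= 1e-12·|mu1 - mu2| the classes are perfectly
separated and D is capped at 1e6 (the cap is also applied to any finite
ratio above it), so perfect separation ranks first instead of
producing infinity. The ratio is invariant to affine intensity changes
(gain and offset), which makes the ranking insensitive to global
illumination scaling.

Candidates are local maxima of the D(b) curve after a centred moving
average (default window 5 bands, edges truncated), kept only if their
topographic prominence reaches a floor (default 0.1 of the smoothed
curve maximum). Plateau peaks report their leftmost band; a curve
endpoint counts as a peak only if it strictly exceeds its two nearest
inward values. An empty candidate set is legal (featureless curve); the
pipeline then falls back to the global maximum so the detector always
receives one band. A `global_maximum` mode returns just the argmax.

One numerical fact worth knowing: two-means applied to pure Gaussian
noise does not give D ≈ 0 but D ≈ 1.32 (splitting a normal sample near
its mean yields half-normal classes with |Δmu| ≈ 1.60σ and
sigma-sum ≈ 1.21σ). The discriminability curve therefore rides on a
pedestal of ~1.3, and what distinguishes a signal band is its
*contrast* above that pedestal — the reason candidate selection is
prominence-based rather than threshold-based.

**Stage 2 — spatial pruning.** A band can be strongly bimodal yet
useless if its two intensity classes are spatially scrambled (sensor
artefacts, striping, saturated speckle). Each candidate's binary
segmentation is decomposed into connected components — by default
8-connectivity, counted within each class separately and numbered
across both classes (both choices config-exposed) — and scored with the
region entropy

    H(b) = - sum_i p_i log2 p_i,   p_i = N_i / (S·L)

in bits. Base 2 makes the stated working threshold of 1 coincide with
the entropy of an equal two-region split, the method's ideal outcome;
H <= log2 M always, every region split strictly increases H, and any
two-region segmentation satisfies H <= 1 bit regardless of size ratio.
Candidates with H above the threshold (default 1.0 bit) are discarded;
survivors keep wavelength order. If nothing survives, the single
lowest-entropy candidate is retained and the selection flagged — the
detector needs at least one band. No minimum-region-size cleanup is
applied before the entropy: small specks are precisely the evidence
that a band is spatially noisy.

**Stage 3 — detection.** Pixels are represented by their intensity
vectors over the selected bands, each band standardised to zero mean /
unit variance (constant bands contribute nothing), and two-means
clustered by Lloyd's algorithm with a deterministic initialisation: the
two centroids start at the feature vectors of the pixels holding the
lowest and highest intensity of the lowest-index non-constant selected
band, falling back to the extremes of the feature-vector norm if those
coincide (this fallback matters on noiseless cubes, where the first
selected band of the full-profile baseline can be spatially constant).
Iteration runs to relative centroid movement < 1e-8 or 300 rounds.
The minority cluster is labelled camouflaged; an exact tie is broken
toward the cluster lying further, on average, from the global feature
mean, and the rule used is recorded in the result. Bands are
deduplicated and sorted internally, so the mask is invariant to the
order in which bands are listed. A single selected band short-circuits
to the exact 1-D two-means split of that band, making single-band
detection consistent with the segmentation stage by construction.

**Baselines.** (1) PCA loading-curve selection: principal components of
the mean-centred pixel spectra; the chosen component's loading curve
(1-based index, default 2 — the first component mostly carries overall
brightness) is scanned for maxima *and* minima with the same
smoothing/prominence machinery, the prominence floor referenced to the
maximum absolute smoothed loading. Loadings are sign-normalised so the
largest-magnitude loading is positive. If the requested component has
no variance the index is clamped to the numerical rank with a warning
(on rank-1 data this means PC1, the difference spectrum); a constant
cube yields an empty selection. (2) Profile clustering: stage-3
detection with all B bands as features.

**Evaluation.** Pixel-level detection rate DR = 100·tp/(tp+fn) and
false-alarm rate FAR = 100·fp/(fp+tn); DR is reported as NaN when the
truth has no positive pixels. The comparison harness runs PCA, profile,
spectral-only selection ("Proposed 1") and spectral+spatial selection
("Proposed 2") on one cube with one config. Timing is not measured or
asserted anywhere — it is hardware-bound.

## The synthetic scene generator

`SceneSpec`/`make_cube` emulate what the acquisition geometry produces,
at desk scale: default 64×64 pixels × 100 bands over 400–1000 nm
(≈6 nm sampling, the same VNIR band-density character as a line-scan
spectrograph), 12-bit quantisation, additive i.i.d. Gaussian sensor
noise (default sd 32 counts ≈ 0.8% of full scale), an optional linear
illumination ramp across the sample axis, and a minority target
(rectangle/ellipse/blob, default ellipse at 10% area) whose reflectance
differs from the background only inside configurable Gaussian windows.
Spectra are Gaussian-bump sums over a baseline, clipped to [0, 1]; the
packaged leaf-like background has a green reflectance bump at 550 nm
and a broad NIR shoulder near 780 nm.

`leaf_scene(separation=s, ...)` sets the foreground bump amplitude to
`s · 2 · noise_sd / full_scale`, so `separation_profile` — the per-band
expected class separation `|fg − bg| · full_scale / (2 · noise_sd)`,
the oracle for where D(b) should peak — reaches s at each window
centre. Injected "noisy bands" replace whole band images with spatially
i.i.d. bimodal values at ±8·noise_sd around mid-scale: strong two-class
structure, no spatial coherence — the failure mode stage 2 exists to
catch. Randomness uses three independent streams spawned from the one
scene seed (target shape, sensor noise, noisy bands), so enabling one
feature never perturbs another's draws, and identical specs give
bit-identical cubes.

What the generator does **not** emulate: textured or multi-class
backgrounds, specular highlights, mixed pixels at target edges, sensor
PSF/smile, band-to-band noise correlation, or dark/white-reference
artefacts. Passing the synthetic suites therefore demonstrates the
pipeline's mechanics (ranking finds planted windows, entropy separates
coherent from scrambled segmentations, detection recovers the planted
mask) — not field performance on real scenes, whose nuisance structure
is exactly what degrades the full-profile and PCA baselines in
practice.

## Numerical and design choices

- **Two-means, not a Gaussian-mixture EM fit, for the per-band split.**
  The class statistics are moment-matched within the two-means classes.
  This is deterministic and exact, but it has a consequence worth
  stating: for a minority class at moderate contrast (separation ≈ 2,
  i.e. class means ~4 noise-sd apart) the WCSS-optimal threshold sits
  ~1σ inside the background mode, so the binary split carries 10–25%
  background false positives. The resulting speckle raises the region
  entropy of genuinely discriminative bands above 1 bit, and pruning
  can then fall back to a single band. An EM fit with class priors
  would place a Bayes-like threshold (~2% false positives) and keep
  such bands; it was not adopted because the two-means realisation is
  the method's own definition of the class statistics. At separation
  ≥ 5 the effect is negligible and the pipeline is exact on every
  tested seed.
- **Entropy threshold 1.0 bit, base 2** (see above); connectivity 8 by
  default because diagonal contact should not split an object into
  pieces — the 8×8 checkerboard regression (2 regions at
  8-connectivity, 64 at 4-connectivity) pins the convention.
- **Curve smoothing window 5 bands, prominence floor 0.1** — both
  exposed in `PipelineConfig`; bands are ranked, never limited to a
  fixed count.
- **Axis convention** `(line, sample, band)` enforced at the I/O
  boundary; ENVI BIL/BIP/BSQ are normalised on read, and wavelengths
  are nm floats, strictly increasing, reported to 1 decimal in all
  user-facing output. The ENVI dialect requires `samples`, `lines`,
  `bands`, `interleave`, `data type`, `wavelength` and ignores unknown
  keys.
- **Determinism end to end.** The detection path contains no random
  draw; two runs on identical inputs produce byte-identical CSV/JSON/
  PNG artifacts. Only scene synthesis consumes a seed.
- **Problem sizes.** The test and reproduction suites use 20 seeds of
  the 64×64×100 default geometry per condition — large enough for the
  planted effects to be unambiguous, small enough that the entire
  pipeline runs in well under a second per cube.

## Known limitations

- Single camouflaged object, two-way clustering only (no K > 2, no
  abundance/soft maps).
- The minority-cluster rule misassigns the target if a camouflaged
  region ever covers more than half the scene (excluded by
  construction in the generator).
- Low-contrast regimes (separation ≲ 2–3) inherit the two-means
  threshold bias described above; the spatial-pruning threshold of
  1 bit is then conservative and may reject true bands.
- No radiometric calibration or reflectance conversion: the pipeline
  operates on whatever intensities it is given.
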