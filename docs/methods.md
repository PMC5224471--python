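# Methods

## Detection model

The detector treats a vesicle as a near-diffraction-limited spot riding on
smooth background. Each 2D plane is convolved with a difference of
Gaussians,

    K = G(σ_small) − G(σ_large),    σ_small = 150 nm, σ_large = 300 nm,

where both Gaussians are *discretized on the pixel grid, truncated at
4 σ_large from the center, and then renormalized to sum to exactly 1*. The
renormalization is what makes "unit area" meaningful on a grid: the kernel
sums to zero to machine precision, so any spatially constant signal —
camera offset, uniform cytosolic fluorescence — produces a response bounded
by ~1e−16 of its level, and the zero-response property holds for every
pixel size rather than only asymptotically. Sigmas are specified in
nanometres and divided by the lateral calibration (nm/pixel), so the same
parameters transfer across instruments; calibration is mandatory and never
defaulted. Convolution uses reflective boundaries (zero padding would
manufacture spurious edge responses against a bright background).
Filtering is strictly 2D per plane or slab; there is no 3D PSF model
anywhere in the pipeline.

## Thresholding

The original workflow thresholded filtered images by eye, which cannot be
reproduced; the package's default is Otsu's between-class criterion applied
to the strictly positive filtered values only ("otsu-positive"). The
negative DoG lobe carries no object evidence, and including it skews Otsu
toward zero. A fixed per-channel threshold and a quantile rule are
available, and every mask records the threshold that produced it. For
z-stacks the default scope is one threshold per channel per stack ("global
threshold"), pooled over all slab responses; this matters because
re-running Otsu inside a slab that happens to contain no puncta would
otherwise place a threshold inside pure noise and emit spurious
detections. Per-slab re-thresholding remains available
(`threshold_scope="slab"`).

## Overlap statistic and its null

For binary masks A, B the reported quantity is
100 · Σ(A·B) / Σ(B) ("B with A"; denominator Σ(A) for the other
direction). An empty denominator yields an *undefined* result, flagged and
excluded from aggregation — never coerced to 0, so an empty channel cannot
impersonate "no co-localization". Three-way overlap normalizes Σ(A·B·C) by
any named channel.

The chance-overlap control rotates one mask by 180° (index reversal on both
axes, exact for odd and even dimensions) and re-evaluates the same
equation. For channels with independently positioned signal the expected
null equals the on-pixel density of the non-rotated channel, so at
realistic vesicle densities (a fraction of a percent of pixels) the null
sits far below 1%; values above that flag either excess signal density or
genuine structure. Rotation acts on the binary mask, not the raw image,
because the equation being re-evaluated is defined on masks.

## Slabs and whole-cell integration

Z-stacks are partitioned into consecutive groups of
round(slab_nm / z_spacing_nm) slices (500 nm slabs by default; e.g. 100 nm
sections → groups of 5) and each group is max-projected — maximum rather
than mean because the detector is tuned to punctate peaks, which averaging
would dilute. A trailing partial group is kept and flagged. Whole-cell
values pool numerator and denominator pixel counts across slabs before
dividing ("integrated for the whole cell"); pooling weights slabs by their
signal content and stays well-defined when some slabs are empty. Averaging
slab-wise ratios instead is exposed for sensitivity analysis but is not
the contract. Filtering happens after projection (one filter pass per
slab); filtering each slice before projection is available as an option.

## Confocal-style readouts

`total_intensity` sums a channel over the image or a region mask.
`perinuclear_readout` samples the image along a user-supplied line at 1 px
steps (bilinear interpolation; nearest-neighbor for exact-integer
fixtures), requires the line to cross the nucleus mask in one contiguous
interval, and reports the intensities exactly 10 px beyond each boundary
crossing, along the line, in native pixel units. Line endpoints are
explicit inputs; the package never auto-draws them. Both flank values and
their mean are emitted.

## Synthetic scenes

The generator emulates the imaging regime the pipeline is built for:
diffraction-limited endosomal puncta over diffuse membrane-associated
signal. Defaults, chosen once as a realistic working point:

| parameter | default | meaning |
|---|---|---|
| field | 512 × 512 px at 100 nm/px | one cell-sized field of view |
| n_puncta | 50 per channel | moderate endosome load |
| psf_sigma_nm | 130 | near-diffraction-limited spot, just under the detector's 150 nm matched scale |
| background_offset | 10 counts | camera offset + diffuse signal |
| read_sigma | 2 counts | Gaussian read noise |
| amplitude | ≈ 112 counts | peak SNR 10 under shot + read noise |
| min separation | 5 × psf_sigma | keeps puncta resolvable |

Peak SNR is defined as amplitude / √(amplitude + background + read_sigma²);
`amplitude_for_snr` inverts this, and the default amplitude is the SNR-10
solution. A designated channel pair shares a controllable fraction of
punctum positions (jitter optional); the minimum-separation rule applies
within each channel, and optionally across channels
(`min_sep_scope="all"`) so that a zero co-location fraction is true at
object level — with `"channel"` scope the two channels are positioned
independently, the right regime for chance-overlap calibration. Shot noise
is sampled as two independent Poisson components — constant-rate background
via exact inverse-CDF lookup, punctum signal on its sparse support — which
is distributionally identical to sampling Poisson(background + signal)
pixelwise and considerably faster on large volumes. Ground truth records
every center (nm), the co-located index pairs, and the noiseless rendered
total per channel, so photometry is checkable to rounding error.

What the generator does *not* model: time-lapse motion, photobleaching,
structured-illumination reconstruction artifacts, fixed-pattern camera
noise, chromatic mis-registration (beyond optional isotropic jitter), and
3D PSF structure. Passing tests therefore certify the quantification
chain — detection, thresholding, overlap arithmetic, null calibration,
aggregation — not robustness to those acquisition pathologies.

## Statistics

Per-cell percents are grouped by (time, label pair, direction); SEM is the
sample standard deviation over cells divided by √n, reported only for
n ≥ 2. Group comparisons default to the pooled-variance two-sample t-test
(two-tailed), with Welch's variant one flag away; no multiple-testing
correction is applied by default, matching the per-timepoint starring
convention (* 0.05, ** 0.01, *** 0.001). All outputs are plain CSV, and
every summary number is re-derivable from the per-cell table.

## Problem sizes and determinism

The validation suites run at deliberately modest sizes: the recovery
battery uses single-plane 512 × 512 scenes (5 fractions × 20 replicates);
the null-calibration battery in the test suite uses 20 z-stacks of 50 × 100 nm
sections (ten 500 nm slabs each), while `scripts/acceptance.py` runs 40
stacks at the full 10 µm acquisition height (100 sections, twenty slabs),
simulated one at a time to bound memory. Every stochastic component flows
from an explicit seed through `numpy.random.SeedSequence`; identical seed
and parameters give bit-identical scenes, and the batch pipeline's CSV
outputs are byte-identical across reruns.

## Known limitations

- Pixel-overlap percentages depend on mask dilation: soft spot edges mean
  the measured percent at full true co-location lands near 96%, not 100%.
- The rotation null is a density-matched control, not a spatial-structure
  control; channels sharing large-scale spatial organization (e.g. both
  perinuclear) can exceed the chance level without object-level identity.
- Otsu-positive thresholding assumes at least some true positive response;
  a channel with no detectable puncta is reported as undefined rather than
  guessed.
- 2D analysis of 500 nm slabs counts a punctum pair as co-localized when
  they coincide laterally within the slab thickness; axial co-incidence
  finer than the slab is not resolved.
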