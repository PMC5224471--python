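# vesicoloc

Object-respecting, pixel-overlap co-localization analysis for multi-channel
fluorescence microscopy of vesicular trafficking — the kind of question where
a fluorescently labeled cargo (say, a cholesterol-conjugated siRNA) is chased
against endocytic pathway markers (EGF, transferrin, GFP-tagged endosome
proteins) and one asks *what fraction of the cargo's vesicles carry the
marker, at each time point, beyond chance?*

The package implements the full quantification chain:

1. **Vesicle-matched detection.** Each 2D plane is convolved with a
   difference-of-Gaussians (DoG) filter: a narrow Gaussian of unit area
   (σ = 150 nm) matched to a near-diffraction-limited spot, minus a wide
   inverted Gaussian of unit area (σ = 300 nm) that estimates and subtracts
   local background. Both Gaussians are renormalized on the pixel grid, so
   the kernel sums to zero and flat background filters to nothing.
2. **Global thresholding and binarization.** One global threshold per channel
   (Otsu's criterion over the strictly positive filtered values by default,
   or a fixed/quantile override) turns the filtered image into a binary
   detection mask A(x, y, t) ∈ {0, 1}.
3. **Overlap percent.** For binary masks A and B, the percent co-localization
   of "B with A" at time *t* is

   100 · Σₓ Σᵧ [A(x, y, t) · B(x, y, t)] / Σₓ Σᵧ B(x, y, t)

   i.e. the fraction of B's detected pixels that also carry A. The
   normalization is asymmetric; both directions are computed. Two-way and
   three-way overlaps are supported.
4. **Rotation null.** Chance overlap is estimated by rotating one mask 180°
   in-plane and re-evaluating the same equation; for genuinely co-trafficking
   labels the null should sit far below the signal (well under 1%).
5. **Whole-cell integration.** Z-stacks are max-projected into 500 nm optical
   slabs; numerator and denominator pixel counts are pooled across slabs
   before forming the whole-cell ratio.
6. **Time-course statistics.** Per-cell percents are aggregated per time
   point as mean ± SEM and compared with a two-tailed Student's (or Welch's)
   t-test.

Because this kind of study rarely ships raw images, the package includes a
first-class synthetic-scene generator (`vesicoloc.synthetic_scenes`):
diffraction-limited puncta with a controllable true co-location fraction,
diffuse membrane-like background, Poisson shot noise and Gaussian read
noise, fully seed-deterministic and with exact ground truth — every pipeline
stage is validated against it. Confocal-style readouts (total intensity,
perinuclear line profiles sampled 10 px outside the nucleus boundary) are in
`vesicoloc.intensity_profiles`.

## Worked example

```python
import vesicoloc as v

# a 512x512 two-channel scene, 50 puncta per channel, half truly co-located
spec = v.SyntheticSceneSpec(seed=1, coloc_fraction=0.5)
stack, truth = v.simulate_scene(spec)

res = v.cell_coloc(stack, "cargo", "marker")   # DoG -> threshold -> overlap
print(f"measured: {res.percent:.1f}%  rotation null: {res.null_percent:.2f}%")
```

prints

```
measured: 48.3%  rotation null: 0.11%
```

Half the marker puncta sit on cargo puncta, and the measured pixel-overlap
percent lands at 48.3% — slightly under the true 50% because detected spots
have soft edges whose peripheral pixels don't fully overlap. The rotation
null of 0.11% says essentially none of that overlap is explained by chance
at these signal densities.

The `analysis/` scripts run the same machinery as a narrative study:
`01_simulate_scenes.py` (scene battery + ground truth), `02_measure_colocalization.py`
(batch pipeline; tidy CSVs), `03_null_calibration.py` (rotation-null
distribution on independent channels), `04_recovery_curve.py` (measured
percent vs true fraction: means 0.0 / 23.2 / 48.3 / 73.4 / 96.8 for true
fractions 0–1, object-level MAE 0.004), `05_timecourse_stats.py` (pulse-chase
time course with mean ± SEM and per-timepoint t-tests). Each writes its
tables under `results/`.

A `vesicoloc` CLI exposes the same steps (`simulate`, `detect`, `coloc`,
`summarize`, `profile`); see `vesicoloc --help`.

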