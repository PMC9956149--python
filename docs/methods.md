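# Methods

`fusagg` quantifies the aggregation behaviour of fluorescently tagged,
aggregation-prone proteins (the motivating system is FUS-mCherry and its
ALS-linked R521C variant, co-expressed with wild-type or mistranslating
serine tRNAs) from live-cell fluorescence images, and provides the
companion quantifications used alongside such imaging: dye-exclusion
cytotoxicity ratios, SDD-AGE densitometry, and tRNA-seq count-table
accounting. Every stage can be exercised end to end on synthetic data with
known ground truth.

## Image quantification model

### Background estimation

`segquant.estimate_background` excludes the upper tail of the pixel
population (default: everything above the 75th percentile — cells, foci,
saturated pixels) and corrects the moments of the remaining sample for the
truncation under a Gaussian background model. For an upper-truncated
normal with cut point τ and ξ = (τ − μ)/σ,

    E[X | X < τ]   = μ − σ·φ(ξ)/Φ(ξ)
    Var[X | X < τ] = σ²·(1 − ξ·φ(ξ)/Φ(ξ) − (φ(ξ)/Φ(ξ))²)

which is solved for (μ, σ) by a bisection on ξ. Without this correction a
pure-noise frame would be reported ≈0.42 σ too low; with it the estimate
is unbiased, and bright outliers (up to the tail quantile's worth of
pixels) cannot shift it. Degenerate inputs (constant frames) return
σ = 0 with a flag, and cell segmentation then falls back to a
multiplicative threshold. For frames above 2 M pixels the moments are
taken on a strided subsample (≥2 M pixels retained), which changes
estimates by far less than the frame-to-frame noise.

### Cell and aggregate masks

Fluorescent cell area is the set of 8-connected components of pixels above
`background_mean + k_cell·background_sd` (k_cell = 3) after removing
components below `min_cell_area_px` (20 px). Aggregates are detected with
the stringent intensity rule: the threshold is `mean + k_sigma·SD` of the
pixel intensities **within the cell mask of that frame**, with
k_sigma = 18 by default; aggregate components need ≥2 px and are by
construction a subset of the cell mask. The statistic's basis (per frame,
rather than per condition or per experiment) is a configuration choice;
per-frame is the default because it makes frames self-contained and the
threshold is recorded per frame in `threshold_used`.

### Median size adjustment

Counting is area-ratio based, not object based: the total cell area and
total aggregate area of a frame are divided by the *median* cell and
aggregate component areas pooled over the **entire experiment** (all
conditions, replicates and time points — one `MedianCalibration` per
experiment). This makes counts robust to touching cells (merged
components change component counts but barely change areas) and yields
deliberately fractional counts; `aggregates_per_cell` is the ratio of the
two adjusted counts. Even-length medians use the midpoint convention.

`total_fluorescence` is the background-corrected integrated density over
the cell mask (Σ pixel − background_mean·area, clamped at 0);
`fluorescence_per_cell` divides it by the median-adjusted cell count.
Background correction matters because every downstream comparison is a
ratio of per-cell fluorescence between conditions: an additive background
offset would bias ratios toward 1 by several percent, which is comparable
to the effect sizes being measured.

### Kinetics

Time courses are per-replicate series of the per-frame quantities.
Fold changes between conditions evaluate each replicate at the query time
(exact points returned as stored; otherwise linear interpolation), average
replicates arithmetically, then form the ratio. Plateau levels average the
final `window_h` hours (default 5 h, the final-window convention of the
underlying experiments). Rupture (saw-tooth) events are consecutive-pair
drops of more than `min_drop` (default 0.25) of the previous value —
purely ratio based, hence scale invariant.

## Synthetic data generator

The generator emulates only what the pipeline measures — areas and
intensities:

- **Cells** are soft-edged disks (radial cosine falloff over 2 px) at
  non-overlapping random centres (dart throwing with bounded retries;
  failure raises `PlacementError`). Transfected cells carry a diffuse
  intensity drawn lognormally (σ_log = 0.2) around `cell_mean_intensity`;
  untransfected cells are dark. Background is Gaussian
  (`background_level` + noise).
- **Foci** are small flat-topped disks fully inside their parent cell,
  Poisson-distributed per transfected cell with rate λ(t), at pixel
  intensity `cell intensity × aggregate_intensity_multiplier`.
- **Time-lapses** keep the cell layout and intensities fixed, redraw foci
  each frame around λ(t), and remove a rupturing cell *and its foci* from
  that frame onward with per-frame probability `rupture_rate`; rupture
  times are logged in the ground truth.
- **Count tables** are independent Poisson draws per transcript, sample
  and replicate; **toxicity plates** draw post-lysis totals and pre-lysis
  (dead-cell) signal = total × injected ratio × lognormal noise;
  **lane profiles** are a Gaussian monomer band plus a half-Gaussian
  high-molecular-weight smear whose areas split the lane total by the
  injected aggregated fraction, over a constant offset and smooth noise.

Everything is deterministic given (configuration, seed).

What the generator does **not** model: realistic morphology, nuclei,
optics (PSF), photobleaching, focus drift, cell motility or division,
overdispersed sequencing counts, or lane-to-lane loading differences.
Passing recoveries therefore demonstrate that the *quantification* is
correct and unbiased under the stated noise model, not that segmentation
would be this clean on real micrographs.

### Sizing the kinetics scenarios for the 18-SD rule

The stringent threshold interacts with the foci themselves: foci pixels
inflate the SD of the cell-mask intensity distribution. With foci area
fraction f (of the cell mask) at intensity multiplier M ≫ 1, the
threshold is ≈ c̄·(f·M + 18·M·√f), so foci remain detectable only while
`f + 18·√f < c_min/c̄`. With the lognormal intensity spread (σ_log = 0.2)
this requires f ≲ 0.0012 at the highest focus rate for near-complete
(≈99%) detection — otherwise detection efficiency differs between
conditions and fold recovery compresses. The time-lapse presets therefore
use large fields of large cells (≈200 cells of 45–57 px radius in
2530–3250 px frames, ~5 px foci), keeping f ≤ ≈0.0013 at λ_max while
providing enough foci per condition (≥400 in the baseline arm at a single
time point) that Poisson counting noise stays near 5% for the fold
estimates. The baseline focus rate is λ0 = 0.5 per transfected cell; the
conditions encode only fold factors relative to it.

### Rupture detection scenario

Under the rupture model above, `aggregates_per_cell` is per-cell
normalized: removing a cell removes numerator and denominator together,
so population-scale courses barely move. Ruptures are visible in
*extensive* metrics instead; the paired-seed rupture comparison therefore
runs the detector on `total_fluorescence` of small fields (20 cells in a
750 px frame, one replicate), where a single cell is ~5% of the total
signal, with `min_drop = 0.04` matched to that single-cell loss fraction.
The rupture-free control arm of each pair produces an essentially smooth
rising course, so detected events separate cleanly (typically ~10 vs ≤3).

## Companion assays

- **Cytotoxicity**: per-well dead/total ratio = pre-lysis / post-lysis
  fluorescence; replicate ratios are normalized by the *mean* of the
  control condition (wild-type tRNA + reporter alone). Malformed wells
  (pre > post) are retained with a warning, never clipped. The
  normalization is scale invariant.
- **SDD-AGE**: rolling-minimum baseline (window 20% of lane length,
  wider than any band) with clamping; the monomer window defaults to
  μ ± 3 SD of a Gaussian fit around the tallest peak (±2 SD would
  misassign 4.6% of the monomer band to the smear, a bias comparable to
  the 10% tolerance of the fraction-ratio recoveries); the aggregated
  fraction is the trapezoidal area outside the window over the lane total.
- **tRNA-seq**: multi-mapped transcripts (identical gene copies) are
  summed into per-family pools before comparison; total-count
  normalization rescales each sample to the mean total (pooling and
  normalization commute). Differential abundance uses Welch's t-test per
  transcript and a fold change of group means floored at a pseudocount of
  0.5 (exact ratios for nonzero means, finite for zero-count groups),
  with 1.5× and 2× flags; multiple-testing correction (Benjamini–
  Hochberg) is available but off by default, matching the
  raw-pairwise-test reporting convention of the source assays. Pool
  fractions are computed on raw within-condition means, and the
  transfection-adjusted fraction divides by the transfection efficiency
  without clamping (values > 1 are flagged).
- **Statistics**: two-sided Welch tests assembled from the textbook
  formulas (only the t CDF comes from scipy); star annotation with strict
  boundaries (p = 0.05 → "n.s."). A pooled-variance Student mode exists
  for data with comparable group variances.

## Numerical conventions and edge cases

- Coordinates are row-major and 0-based; connectivity is 8-neighbour;
  images are float32 AU (no integer quantization is assumed anywhere).
- A frame with no cell area reports per-cell quantities as NaN (missing),
  not zero; an experiment with no aggregates anywhere leaves the
  aggregate median undefined and aggregate counts at 0.
- Fold changes with a zero denominator mean are NaN; zero-total samples
  reject normalization; zero-variance Welch inputs return p = 1 (equal
  means) or the smallest positive float (unequal means).
- Sub-seeds for replicate streams are drawn from a master generator and
  kept below 2³¹.

## Problem sizes

The validation suite and the acceptance script run the presets at their
native sizes: 8 replicate fields of 400 cells per condition for the
reporter-fluorescence scenario, 100 seeded fields for transfection
efficiency, 200 seeded tables (3 replicates each) for counts, 4 replicate
20-frame time-lapses per condition for the two kinetics scenarios, 50
paired seeds for rupture detection, 200 seeded plates for toxicity, and
100 seeded lane sets for densitometry. The two time-lapse recoveries
dominate the runtime (a few minutes each); everything else completes in
seconds.

## Known limitations

- The 18-SD rule's statistical basis ("per cell" vs per frame) is
  genuinely ambiguous in the field; the per-frame pixel-statistics
  reading implemented here is stringent and self-contained but makes
  detection efficiency depend on the foci load (quantified above).
- Area-ratio counting assumes foci and cells of one experiment share a
  common size scale; strongly condition-dependent object sizes would bias
  counts (the medians are pooled deliberately, to keep conditions
  comparable).
- The rupture model removes whole cells; real rupture leaves debris and
  released aggregates that could transiently inflate background or
  aggregate area.
- Poisson counts understate the overdispersion of real tRNA-seq
  replicates; the differential-abundance tolerances here should not be
  read as statements about real library noise.
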