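# Methods

## The measurement

A pulse of fluorescent-protein expression is induced in adult flies with a
conditional driver (mifepristone-activated Gene-Switch or
doxycycline-activated Tet-ON). Once the inducing drug is withdrawn, synthesis
stops and whole-animal fluorescence declines in proportion to degradation of
the reporter. Under first-order kinetics

    F(t) = F_peak · exp(b · (t − t_peak)),   b < 0,

so ln F is affine in t and the half-life is t½ = ln 2 / |b|. The package
estimates b by ordinary least squares of ln(fluorescence) on time over the
**peak-to-minimum window**: from the global maximum of the group-mean time
course (earliest index on ties) to the global minimum among strictly later
points (earliest on ties). Interior bumps are retained — the window is a
contiguous range, not a monotone subsequence — matching a plain linear
regression over a chosen range. If the series plateaus and then ticks up, the
global post-peak minimum still ends the window; restricting to the last
recorded day instead can be had by passing an explicit `window` to
`DecayModel.fit`.

The same fit applies unchanged to three data sources, distinguished only by
their time unit (carried explicitly, never converted silently): daily in vivo
video data (days), per-fly microscope time courses (days), and plate-reader
kinetics sampled every 30 s (minutes).

## Per-frame quantification

Within a rectangular ROI, minus an optional binary exclusion mask, every
pixel with raw intensity **strictly greater** than the detection threshold is
a candidate fly pixel. Candidates are grouped into 8-connected components;
components with fewer than `min_blob_px` pixels are discarded (default 1, so
object filtering is a no-op unless requested); total fly fluorescence is the
sum of raw intensities over the surviving pixels. Summation is over the
thresholded pixels themselves, with no dilation and no background
subtraction — background is suppressed experimentally (dyed media, black
filter paper), and subtracting it computationally would make the per-frame
value depend on an unknowable per-pixel baseline.

Two deliberate conventions, chosen once and used everywhere: the threshold
comparison is strict (`>`), and coordinates are 0-based, half-open,
row-major. Color inputs are out of contract; a channel-extraction pre-step
(green for eGFP, red for DsRED/mCherry) must produce single-channel frames
before quantification.

One caution discovered by property testing: the **object count** is not
monotone in the threshold — raising the threshold can remove a dim bridge
pixel and split one component into two. Total fluorescence *is* monotone
non-increasing in both the threshold and the mask.

## Merging, filtering, aggregation

The two cameras view different projections of the same flies and the decay
slope is invariant to the sum-vs-mean choice under the log transform, so the
merged per-frame value is the **sum** of the two per-frame totals. Frames
whose merged total is ≤ the signal threshold are dropped (the filter acts on
the merged value; pixel-level thresholding already happened upstream). The
per-vial daily value is the arithmetic mean of surviving frames; the group
time course is the mean across vials with the sample SD (n−1). A day on
which every frame was filtered yields an explicit "no signal" error rather
than a zero — zero would silently break the ln transform downstream. Missing
vial-days are excluded from the group mean, never imputed.

Fits are performed on group means by default; per-vial fitting is available
by constructing a `DecayModel` per vial column (models built from replicate
vials show no advantage in separating groups, and the group-mean fit is what
the reported slopes refer to).

Nonpositive fluorescence values inside the fit window are dropped with a
logged warning before the log transform; an epsilon offset would bias the
slope. A fit with slope ≥ 0 reports `half_life = NaN` with
`half_life_defined = False`, never a fabricated large number.

## Statistics

* **Equality of slopes (ANCOVA).** Pooled OLS of ln F on time, group, and
  time×group over the windowed, ln-transformed points — exactly the points
  behind the reported slopes (`kinetics.windowed_ln_points`). The p-value is
  the extra-sum-of-squares F-test of the interaction; for two groups this is
  the classic "are the slopes equal?" test. Degenerate cases are explicit:
  zero interaction SS → F = 0, p = 1; zero residual with nonzero interaction
  (noiseless lines of different slopes) → p = 0 with a `degenerate` flag and
  warning.
* **Half-life collections.** Unpaired two-tailed t-test, Welch by default
  (spread differs across experiments), pooled-variance option for textbook
  reproduction.
* **Age × sex.** Two-factor ANOVA with interaction on a table of half-life
  values, sequential (Type-I) sums of squares to match `anova(lm(...))` in
  base R. On balanced designs Type-I and Type-II coincide (asserted
  numerically in the tests). An all-equal response is reported as F = 0,
  p = 1 with a warning.
* **Peaks and AUC.** Per-vial peak-day values compared by t-test; total
  accumulation summarized as the trapezoidal area under the group-mean curve
  over the full day grid, with fold changes as AUC ratios.

No multiple-testing correction is applied; reports carry the number of
comparisons so the reader can apply one.

## The synthetic-experiment generator

`simulate_video_experiment` emulates the assay geometry: `n_flies` hard
disks of uniform intensity (radius `fly_radius_px`; total blob intensity is
therefore analytically known) perform a Gaussian-step random walk
(`step_sd_px`, default 2 px/frame) reflected at the vial-ROI boundary. Fly
pixels carry the summed intensity of the flies covering them — flies occlude
the background — and all other pixels sit at `background_level`; additive
Gaussian pixel noise (SD `noise_sd`) is applied last and clipped at zero,
respecting non-negative detector counts. The two cameras are independent
position realizations of the same vial: the pipeline only sums intensities
and never triangulates, so no geometric stereo model is needed.

Per-fly intensity follows the induction-pulse shape: linear rise to
`peak_day`, then exact exponential decay
I_d = I_peak · 2^(−(d−peak_day)/t½). Ground truth records the exact per-day
per-vial totals, the true slope −ln 2/t½ and every fly trajectory.

Defaults are the study conditions of the assay: 6 flies per vial, 4 vials
per group, 6 daily recordings, peak one day after induction ends, half-life
3.5 days (tissue-general eGFP in untreated flies), two cameras at 30 fps.
Background level (50 AU), fly peak intensity (1000 AU) and pixel noise
(SD 10 AU, i.e. 1% of peak; recovery studies use 50 AU = 5%) are free
parameters of the generator — no instrument calibration exists for them —
chosen so that blobs are unambiguous above background at every assay day.
The per-day recording is 30 frames (one second of video at 30 fps) on a
64×64 frame: the daily value is a mean over frames, so recording length only
shrinks within-day variance, and one second is already far below the
between-vial variance floor. Frames are written as 16-bit grayscale PNG
sequences with a manifest CSV (video codecs are not bit-reproducible;
image sequences are), which quantizes intensities to integers — keep
simulated intensities below 65535.

What the generator does **not** emulate: realistic fly gait or wall-climbing,
optics (LED spectra, filters, vignetting), glare, occlusion by the vial
plug, autofluorescent media, or day-to-day illumination drift. Passing
tests therefore demonstrate that the pipeline arithmetic and inference are
correct under the stated forward model, not that the threshold/ROI/mask
choices are robust on any particular real video.

`simulate_plate_series` produces exponential decay sampled every 30 s with
multiplicative lognormal noise of given CV (mean 1, unbiased).
`simulate_daily_decay` is the timecourse-level counterpart used for
slope-test power and calibration studies where rendering frames adds
nothing. `simulate_halflife_table` draws a balanced 2×2 (age × sex) table
from a linear model with specified effects in days and Gaussian residuals
(baseline 4 days ≈ tissue-general eGFP); draws are not clipped at zero —
with the default baseline and residual SD ≤ 0.5 d a nonpositive half-life
is a >6σ event.

## Numerical choices

* Window ties resolve to the earliest index; `peak == last point` is a
  "no decay window" error, not a silent empty fit.
* `half_life × |slope| = ln 2` holds to machine precision by construction.
* OLS via `scipy.stats.linregress`; slope SE reported as NaN below 3 points.
* Degenerate-statistics tolerance: sums of squares below 1e−12 of the total
  response variation are treated as zero.
* Determinism: every stochastic function takes a seed and uses
  `numpy.random.default_rng`; identical seed + config is bit-identical at
  every stage, including written CSVs.
* Display rounding (half-life to 2 decimals) happens only in `summary()` and
  reports; full precision is retained in the objects.

## Problem sizes in the validation suite

The Monte-Carlo studies run at: 100 simulated experiments (4 vials × 6 days
× 2 cameras × 30 frames) for pipeline half-life recovery; 200 pairs for
slope-test power (6 timepoints, lognormal CV 10%); 1000 pairs for type-I
error; 200 tables (10 per cell) for ANOVA recovery. These sizes give
Monte-Carlo standard errors of a few percent on each rate while keeping the
whole suite to about a minute.

## Known limitations

* No per-fly identity tracking; the assay quantifies the vial population.
* Only log-linear (single-compartment) decay; no direct nonlinear
  exponential fits, no multi-phase models.
* The green→red maturation ratio of timer proteins is out of scope; only
  single-channel decay is fitted.
* ANCOVA uses group means as units by default, so its residual degrees of
  freedom come from timepoints, not vials.
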