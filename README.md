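# fpturnover

In vivo fluorescent-protein turnover from video assays of free-moving flies.

Protein turnover — the balance of synthesis and degradation — is classically
measured by isotope labeling and mass spectrometry, which requires
sacrificing the animal. A non-destructive alternative: induce a pulse of
fluorescent-protein expression with a conditional driver (Gene-Switch,
Tet-ON), withdraw the inducing drug, and film the flies daily. Once synthesis
stops, fluorescence decays in proportion to degradation of the reporter, so

&nbsp;&nbsp;&nbsp;&nbsp;F(t) = F_peak · e^{b(t − t_peak)},&nbsp;&nbsp; t½ = ln 2 / |b|,

and the half-life falls out of a linear regression of ln F on time over the
peak-to-minimum window. `fpturnover` implements the complete analysis chain:

1. **quantify** — per-frame total fly fluorescence: pixels inside an ROI,
   outside an exclusion mask and strictly above a threshold, grouped into
   8-connected blobs (`quantify_frame`, `quantify_stack`);
2. **merge** — sum the two synchronized camera streams per frame and drop
   frames below a signal threshold (`merge_cameras`);
3. **aggregate** — per-vial daily means, then group mean ± SD across vials
   (`vial_day_value`, `aggregate_group`, summary CSV);
4. **fit** — peak-to-minimum OLS of ln F vs time; `DecayModel(...).fit()`
   returns a `DecayFit` with slope, SE, r², half-life and `summary()`
   (`find_decay_window`, `half_life_from_slope`, `compute_auc`);
5. **compare** — ANCOVA on decay slopes (time×group interaction F-test),
   Welch/pooled t-tests on half-life collections, per-vial peak t-tests, and
   sequential two-factor ANOVA of half-life on age × sex
   (`compare_slopes_ancova`, `compare_halflives_ttest`, `halflife_anova`);
6. **simulate** — synthetic experiments with exact ground truth: flies as
   moving disks in two camera views with programmed exponential decay,
   plate-reader decay series in minutes, and age×sex half-life tables
   (`simulate_video_experiment`, `simulate_plate_series`,
   `simulate_halflife_table`).

The same fit serves daily in vivo video data (days), microscope time courses
(days) and plate-reader kinetics at 30-s sampling (minutes); the time unit is
carried explicitly. See `docs/methods.md` for the model, conventions and
limitations.

## Worked example

Simulate a control experiment (true half-life 3.5 days) and a
degradation-inhibited one (17 days), run the full pipeline on each, and test
the slopes:

```python
from fpturnover import (SimConfig, QuantConfig, simulate_video_experiment,
                        compare_slopes_ancova, windowed_ln_points)
from fpturnover.pipeline import analyze_stacks

qc = QuantConfig(threshold=300.0, roi=(0, 64, 0, 64))
ctrl, _ = simulate_video_experiment(SimConfig(seed=11, true_half_life=3.5, noise_sd=50.0))
inhb, _ = simulate_video_experiment(SimConfig(seed=12, true_half_life=17.0, noise_sd=50.0))
tc_c, fit_c = analyze_stacks(ctrl, qc, group="control")
tc_i, fit_i = analyze_stacks(inhb, qc, group="inhibited")
print(fit_c.summary())
print(compare_slopes_ancova({"control": windowed_ln_points(tc_c),
                             "inhibited": windowed_ln_points(tc_i)}).summary())
```

prints

```
Exponential decay fit (OLS on ln fluorescence)
----------------------------------------------
slope        -0.198112 per day
slope SE      0.000229711
half-life    3.50 days
r-squared     1.0000
n points     5
window       1..5 (inclusive)
ANCOVA equality-of-slopes test (2 groups)
  control: slope -0.198112
  inhibited: slope -0.0409626
  F(1, 6) = 3.02e+05, p = 2.45027e-15
```

The control fit recovers the programmed 3.5-day half-life (slope
−0.198 ≈ −ln 2/3.5 per day) over the 5-point window from the day-1 peak, and
the interaction F-test rejects slope equality decisively: inhibiting
degradation five-fold is unmistakable after six daily recordings.

The same chain is available from the shell, configured by one YAML file in
place of a hand-edited batch script:

```sh
fpturnover simulate --out exp/ --seed 11 --half-life 3.5
fpturnover run --config pipeline.yaml     # quantify → merge → fit → compare
fpturnover fit --series summary_control.csv --time-unit days
```

Subcommands: `simulate`, `quantify`, `merge`, `summarize`, `fit`, `auc`,
`ancova`, `ttest`, `anova`, `run`, `plot`. Exit codes: 0 success, 2
configuration error, 3 data error, 4 statistical degeneracy under
`--strict`.

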