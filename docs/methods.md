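# Methods

This note records the models behind `corneafluor`, the defaults and why
they were chosen, and what the synthetic validation does and does not
demonstrate.

## Signal model

A recording is a pair of equally sampled intensity series (arbitrary
detector units): the corneal channel and the eyelid reference channel.
The generator composes each corneal series as

```
corneal[t] = baseline + gain · c · T + drift[t] + ε[t] + interference[t]
eyelid[t]  = eyelid_baseline + drift[t] + η[t]
```

where `c` is the subject's true AGE concentration (µg/mL), `T ∈ (0, 1]`
the round-trip pigment transmittance, `drift` a slow illumination
component shared by both channels, and `ε, η` white Gaussian noise.

The affine fluorescence–concentration relation is an explicit assumption:
the device operates in a near-linear regime over the 2–7 µg/mL working
range, and no published response curve contradicts it. Detector
saturation and nonlinearity at high intensities are deliberately *not*
modelled; they are a known failure mode of the linear calibration, not of
this package.

**Defaults** (detector units unless noted): `n_samples = 500`,
`n_repeats = 3` (repeated measurements are standard practice for this
device class), `gain = 20` per µg/mL, `baseline = 50`,
`eyelid_baseline = 120` (the eyelid signal is markedly stronger than the
corneal one), `noise_sd = 1`, `eyelid_noise_sd = 0.5`,
`drift_amplitude = 6` (sum of three sinusoids with periods drawn from
150–400 samples — slow relative to the 50-sample analysis window, fast
enough that every recording sees several drift swings). No sampling rate
or record length is published for the device; these are declared desk-
scale choices, sized so the windowed trend analysis has ~19 windows per
recording to work with.

### Interference model

Interference episodes arrive as a Poisson count (`interference_rate =
1.5` per recording) of 150-sample transients. Each transient
*anti-tracks* the shared drift at factor `interference_tracking = 2` and
adds a linear ramp of amplitude `3 × noise_sd` whose slope sign opposes
the concurrent eyelid trend, so the contaminated corneal segment trends
against the eyelid channel — the defining signature the quality filter
detects. A per-sample boolean truth mask (simulator-only) marks
contaminated samples.

Design rationale: a transient that merely adds an opposing ramp and then
snaps back creates a step at the episode end that *co-trends* with the
drift and systematically fools windowed-correlation detection near
episode boundaries; anti-tracking the drift across a window-spanning
episode produces the clean "opposite trend" phenomenology throughout the
contaminated stretch. Episode length (150) is deliberately longer than
the analysis window (50) so the filter's resolution, not the generator,
limits detection. With these defaults roughly 40% of samples per
recording are contaminated — interference is the rule, not the exception,
which is precisely the regime in which a reference-channel filter earns
its keep.

## Cohort model

Per subject: `diet ~ U(0, 1)` (high-AGE-diet propensity),
`c = U(2.0, 5.5) + 1.5 · diet` µg/mL (inside the 2–7 µg/mL physiological
envelope), `BMI = N(23, 3²) + 6 · diet` kg/m² clipped to [15, 45], iris
pigment class and skin tone (A–E) uniform. Only the *positive direction*
of the diet → (AGE, BMI) coupling is empirically supported; the
magnitudes (1.5 µg/mL and 6 kg/m² per unit diet score) are free
parameters chosen to give a visible but not dominant lifestyle signal.
The serum ELISA reference is `c` times a unit-mean lognormal factor with
CV = 5%, a typical intra-assay ELISA precision; no assay CV is published
for the reference method.

## Pigment optics

Round-trip transmittance is decadic Beer–Lambert,
`T = 10^(−(a_ex + a_em) · conc · path · s)`, with per-pigment effective
absorbances at the excitation and emission bands and a skin-tone scale
`s` linear in ordinal rank (A = 1.0 … E = 1.4). Scattering is folded into
the effective absorbances. The bundled nine-pigment coefficient table is
a **synthetic fixture**: only its ordering is empirically constrained
(purple, blue strongest; green, pink weakest; the dark neutrals in
between), not its magnitudes. The pipeline default iris loading
(`pigment_conc = 0.002 g/100 mL`, `path = 1 cm`) keeps per-subject
transmittance in ≈ 0.91–0.99, consistent with the observation that iris
colour perturbs corneal readings only mildly under controlled
illumination.

## Quality filter

Windows of 50 samples, step 25 (50% overlap; the final window is anchored
to the series end so every sample is covered). Default statistic:
within-window Pearson correlation between the channels; windows with
statistic < 0 (anti-correlated) are rejected. This is the minimal faithful
reading of the opposite-trend criterion; a slope-sign-agreement statistic
is available as an alternative. Zero-variance windows score +1 — a flat
corneal signal cannot oppose the eyelid trend, so there is no evidence of
interference. Repeats whose kept-window fraction falls below
`min_valid_fraction = 0.3` are dropped; if no repeat survives, the
measurement is flagged unusable rather than averaged from scraps. The
corrected intensity is the mean over the union of kept-window samples,
pooled across surviving repeats; rejection happens *before* averaging.
The eyelid channel is used only as a validity reference — it is never
subtracted from the corneal signal, because the retain/reject behaviour is
the only correction the underlying procedure describes.

Filter performance is scored against the simulator truth mask at window
level: a window counts as *contaminated* when ≥ 50% of its samples are
truth-masked and *clean* when none are; windows touched below 50% are
ambiguous at the filter's one-window resolution and excluded from the
confusion counts. Under the default conditions (20-seed grid of
200-subject cohorts) the filter reaches sensitivity ≈ 0.89 and
specificity ≈ 0.93, and the corrected mean is closer to the clean signal
level than the naive full-series mean.

## Prediction models

Per-subject features: corrected corneal intensity, mean eyelid reference,
kept-window fraction, BMI. (Age and diet score can be supplied but are
excluded by default: age's predictive stability is limited by individual
metabolic variation, and diet enters indirectly through BMI.) Screening
removes features with variance ≤ 10⁻⁸ (numerically constant) or
|Pearson r| < 0.3 with the serum reference; an empty selection is an
explicit error, never a silent fallback.

* **MLR** — ordinary least squares on the raw selected features; a rank-
  deficient design raises an error naming the collinear columns.
* **SVR** — ε-insensitive RBF support vector regression, C = 10, γ = 0.1,
  ε = 0.01, fitted on features standardized with training-split
  mean/scale (a fixed kernel width is meaningless across arbitrary
  feature scales). Targets are left unstandardized.
* **Hybrid** — `ŷ = 0.7 · MLR(x) + 0.3 · SVR(x)`. The source material is
  internally inconsistent about which component carries 0.7; the equation
  as printed (0.7 on MLR) is implemented as the default and the weights
  are configurable. Two identically printed equations are treated as one
  model. Because the hybrid's absolute error is pointwise bounded by the
  convex combination of component errors, its mean absolute relative
  error can never exceed the worse component's.

Evaluation uses a seeded 70/30 train/validation split (no split protocol
is published; k-fold can be substituted). Under the default synthetic
conditions the held-out hybrid MARE is ≈ 4–6%, inside the 8% bound, and on
interference-free unit-attenuation cohorts OLS recovers the generating
calibration (slope `1/gain`, intercept `−baseline/gain`) within 10% on
every seed of the grid.

Fitted models serialize to a JSON document carrying the OLS coefficients,
SVR support vectors/dual coefficients/intercept, standardization and
weights; document predictions reproduce the live estimator's to numerical
round-off without refitting. All serialized artifacts (model, config,
agreement report) carry a major.minor schema version and readers reject
unknown major versions.

## Agreement statistics

Differences are `reference − test` (serum minus device): a device that
reads high produces a *negative* bias, matching the sign conventions of
the bundled clinical comparison. Limits of agreement are bias ± 1.96 ×
sample SD (n − 1); 1.96 is used verbatim, not a t-quantile. Relative
error is `100 · (test − reference)/reference`, positive when the device
reads high; MARE is the mean of absolute values. Report values are
displayed at 3 d.p. (1 d.p. for percent errors). No confidence intervals
for the limits and no proportional-bias regression variants are provided.

The bundled 20-pair dataset's printed relative-error column was evidently
computed from unrounded concentrations: recomputing from the two printed
concentration columns reproduces the printed value at 1 d.p. only for
rows 1, 2, 6, 7, 12, 14, 17, 20 (`agreement.CONSISTENT_ROWS`); the
remaining rows disagree in the last digit and are documented as
print/recompute mismatches. The summary statistics (r = 0.991, bias
−0.029, limits −0.347/0.290, MARE 3.7%) all reproduce exactly from the
printed concentrations.

## Exposure safety validator

The 365 nm source is Class 3B; the validator enforces the strict
single-exposure limits — dose (irradiance × duration) < 3.9 mJ/cm²,
duration < 10 s, beam spot diameter > 7 mm — reading each limit as a
strict inequality and reporting *every* violated limit, not just the
first. Irradiance is user input; only the three limits above are checked
(no full laser-classification logic).

## What the synthetic validation shows — and what it does not

Passing the simulation studies demonstrates that the filter detects the
opposite-trend signature it was designed for, that the calibration is
recoverable when the generating model holds, and that the whole pipeline
is deterministic and within the stated error budget *under the generator's
assumptions*: affine response, additive Gaussian noise, sinusoidal drift,
anti-tracking interference, lognormal assay noise. Real recordings add
blink artifacts, tear-film variation, detector nonlinearity at high
intensity, pigment spectra that vary within a colour class, and
population structure none of which the generator emulates. Synthetic
results therefore validate the *software*, not the clinical performance
of any device.

## Numerical and degenerate-input conventions

* Deterministic seeding throughout: per-recording streams derive from
  `(config seed, CRC32 of subject id, repeat index)`, so any recording can
  be rebuilt in isolation; a pipeline's artifacts are byte-identical
  across reruns of the same configuration.
* Attenuation must lie in (0, 1]; concentrations must be positive;
  correlation on a constant series is an explicit error rather than NaN.
* Ranking ties in the pigment table break lexicographically by name, and
  sorting is stable, so equal specs keep input order.
* Simulation study sizes (20-seed grids, 200-subject cohorts, 3 repeats,
  500 samples) are the package's declared validation conditions; they run
  in about a minute on one CPU.
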