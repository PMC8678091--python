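# Methods

This note documents the models and procedures the package implements, the
choices made where the method description leaves the design open, and what
the synthetic-data tests do and do not establish.

## Stimulus model

The source signal for one phase of one run is built in four steps: a binary
indicator at 1 kHz (finer than stimulus-timing accuracy), convolution with
the canonical HRF, point evaluation at the volume acquisition times
t = k·TR (k = 0 … n_volumes−1, 0-based), and z-scoring over the full run
with the population (n) denominator.

* **Indicator shape.** The indicator is a boxcar equal to 1 for the full
  stimulus duration (1,800 ms memory sets, 2,000 ms probes), because the
  presentations have non-trivial durations; `stimulus_shape="impulse"`
  switches to a single 1 ms pulse at onset for sensitivity analysis.
* **HRF.** Double-gamma difference h(t) = g(t; a₁=6, s=1) − g(t; a₂=16, s=1)/6
  sampled at 1 ms over 32 s, peak-normalised (scale is irrelevant after
  z-scoring). Shape = delay/dispersion, scale = dispersion, so the defaults
  are the standard canonical form: positive peak at ≈ 5.0 s, undershoot
  near 15 s, h(0) = 0. No temporal or dispersion derivatives, and no
  subject-specific HRF estimation.
* **Resampling** is point evaluation, not within-TR averaging — the
  simplest reading of resampling to 1/TR.
* Encoding (memory sets) and retrieval (probes) series are built
  separately; mask presentations never enter either series.

## Source events, target events, correlations

A source event opens at every upward crossing of the z-scored series
through threshold 1 (previous sample ≤ 1 < current; index 0 qualifies if
the series starts above threshold — so a sustained plateau yields one
event, never several) and spans 5 consecutive TRs including the crossing,
enough to cover the HRF's positive peak. Windows that would overrun the
run end are discarded and logged.

Events inherit the labels of the most recent same-phase trial at or before
the crossing (a gap > 12 s triggers a warning). An encoding event
additionally takes the probe type and the response of its block's probe —
the first retrieval trial after the memory set — because condition cells
are keyed by probe and response in both phases; without that label the
encoding cells could not enter the response model.

Target events are the ROI BOLD values at exactly the source-event volumes.
The per-event statistic is the Pearson correlation of the two 5-sample
segments; a zero-variance segment yields a missing value that is excluded
from cell averages (and from `n_events`). Cell means are Fisher
transformed after clamping |r̄| at 1 − 10⁻⁷, since 5-point correlations
reach ±1 exactly. Negative-probe cells are computed and written, and only
dropped later when the model frame is built.

## Delays

The delay of an event in one ROI is **peak-to-peak**: the refined time of
the closest BOLD local maximum, irrespective of its size, minus the
refined stimulus-series peak inside the event window. Local maxima are
strict (plateau runs count once, at their midpoint rounded down; run
endpoints never count), and every peak is refined by the parabola through
its three samples: δ = (y₋ − y₊) / (2(y₋ − 2y₀ + y₊)), δ = 0 for collinear
samples. The refinement reproduces the vertex of an exact quadratic to
machine precision and never moves a peak by more than half a TR.

Candidate BOLD peaks must have their integer index inside a forward search
window of [0, 9] TRs; the candidate minimising the absolute refined time
difference is chosen, ties going to the earlier peak. Because refinement
at the window edges can spill slightly outside, refined delays are kept on
[−1, 10] TR; records outside it, and events with no candidate at all, are
marked invalid with a reason and reported, never silently dropped.

**Window anchor.** Where the [0, 9] window opens is a genuine design
choice, and it matters at the boundaries. Anchoring at the rounded
stimulus peak censors the left edge: a response with zero true shift has
its peak at the window's first admissible index, noise pushes it out about
a third of the time, and the median delay inflates by ≈ +0.6 TR at SNR 2
(measured on pooled synthetic runs). Anchoring at the trial onset censors
the right edge symmetrically for shifts near 5 TR (bias up to −1.3 TR).
The default therefore anchors at the source event's threshold crossing —
the event's time stamp, 1–2 TR before the stimulus peak — which leaves at
least 1.5 TR of margin at both edges for response shifts of 0–5 TR;
population median errors are then ≤ 0.4 TR at SNR 2, the largest part
(≈ 0.26 TR) being the peak shift that the 0.01–0.1 Hz band-pass imposes on
the BOLD response while the synthetic stimulus series stays unfiltered —
an asymmetry inherent to the pipeline, not an estimator error.
`anchor="peak"` and `anchor="onset"` remain available as switches.

Delay histograms are accumulated over [−1, 10] with a configurable bin
width (default 0.5 TR; the source material does not state one); modes are
the local maxima of a 3-bin moving average of the counts, and the invalid
count is carried alongside.

The conventional lagged-cross-covariance delay is deliberately not a
feature; the event-wise definition is the point of the method.

## Preprocessing

Per ROI column, in this order: linear detrend, OLS residualisation against
the nuisance set plus an intercept (collinear columns dropped by pivoted
QR with a warning), then an ideal (rectangular) band-pass mask on the
discrete Fourier grid, default 0.01–0.1 Hz. The mask convention matches
the preprocessing software family the upstream analysis used; the step
order follows the order in which the steps are usually listed. The DC bin
is outside the pass band, so outputs are mean-zero. The residualisation is
idempotent and out-of-band spectral power is < 10⁻⁶ relative.

Global/mean-signal regression is part of the default nuisance set (it can
be disabled by omitting the column). Framewise displacement is the maximum
absolute inter-volume difference over the translation parameters, with
rotations converted to arc length on a 50 mm sphere when supplied. The
motion/event QC reports the fraction of supra-threshold displacement
volumes falling 0–9 TRs after any source-event crossing. Spatial
preprocessing (slice timing, realignment, normalisation, smoothing,
subject exclusion) is out of scope.

## Response model

Observations are condition cells; the outcome is the recognition response
with "no" coded 1, so a positive trend means more "no" answers.
Negative-probe cells are excluded (too few errors to carry information).
Factors — phase, probe, condition (session time), ROI — use sum-to-zero
coding with alphabetically ordered levels, which makes the per-term
likelihood-ratio tests type-III. Cells are unweighted by default
(`weight_by_events=True` switches to event-count frequency weights).

* **Term set.** Intercept, probe, condition, probe x condition, and every
  correlation-containing term up to the four-way interactions
  corr x ROI x {phase,probe}, corr x ROI x {phase,condition},
  corr x ROI x {probe,condition} and corr x phase x probe x condition.
  Phase and ROI main effects, and their correlation-free interactions,
  are excluded a priori: responses cannot depend on them marginally.
  The set is closed under correlation-containing marginality; term degrees
  of freedom are products of (levels − 1), e.g. 89 for
  corr x phase x probe x ROI with 90 ROIs.
* **Fitting.** Maximum likelihood via iteratively reweighted least squares
  (statsmodels, binomial family). AIC = 2k − 2·logL. Non-convergence or
  runaway coefficients (possible separation) flag the fit with a warning
  rather than failing silently.
* **Type-III table.** For each term, the model is refitted with exactly
  that term's columns removed (all others retained);
  χ² = 2(logL_full − logL_reduced), df = column difference.
* **AIC reduction.** Among deletable terms (those whose removal keeps the
  marginality of the remaining set; correlation-containing terms protect
  their correlation-containing sub-terms, factor-only terms protect their
  factor-only sub-terms), the deletion minimising AIC is examined at each
  step; the reduction stops when that candidate is itself significant at
  p < 0.05. `require_improvement=True` adds a stop when no deletion lowers
  the AIC, making the procedure strictly greedy (and its AIC trace
  non-increasing by construction); the default follows the looser rule in
  which significance is the only stopping criterion. Every step is traced.
* **Marginal trends.** The trend of P("no") in the correlation is
  evaluated on the full factor grid at the sample-mean correlation,
  averaged with *equal* weights over omitted factor levels
  (estimated-marginal-means semantics, not observed-frequency weighting),
  and back-transformed from the logit scale by the delta method:
  dμ/dz = p(1−p)·(dη/dz), with the gradient propagated through both the
  slope and the evaluation point. Contrasts (e.g. lure − positive per
  phase x ROI, or morning − evening) are Sidak-adjusted over the whole
  family produced in one call, p_adj = 1 − (1 − p)^m, and the confidence
  limits use the Sidak-adjusted critical value.

Behavioral descriptives (proportions of hits/misses and correct
rejections/false alarms per probe type, with RT mean ± SD) are computed
directly from the trial schedules; proportions sum to one within probe.

## Synthetic data generator

The generator emulates the study design and nothing more. Defaults are
design constants: 60 memory sets (1,800 ms), 25 positive / 25 lure / 10
negative probes (2,000 ms) in random order, 1,000 ms set-mask gap,
mask-probe delays on 2,000–16,000 ms, 709 volumes at TR = 1,800 ms, 90
ROIs, two sessions (morning/evening), two tasks.

* **Mask-probe delays** follow a truncated exponential whose rate is
  solved numerically so the mean equals 6,097 ms — chosen because the
  stated mean sits far below the range midpoint, implying right skew;
  the generating distribution itself is not documented in the source
  material.
* **Unstated timing.** The mask duration is not published; the generator
  uses 500 ms. Post-probe intervals are not published either; they get a
  2 s floor plus a Dirichlet split of the remaining run time, so the run
  fills the 709 volumes exactly (with a lead-in of 2 TR and a tail margin
  of 10 TR that keeps the last event window inside the run). Generation
  retries with a fresh draw when a sample does not fit, and is
  deterministic per seed.
* **Responses and RTs** are sampled at the study's observed accuracy rates
  (hits 0.82, lure correct rejections 0.74, negative correct rejections
  0.98) with per-category RT means/SDs matching the reported
  descriptives, truncated at 200 ms.
* **BOLD forward model.** Each ROI column is the sum over stimulus groups
  of amplitude × the peak-normalised HRF response shifted by the ROI's
  `shift_tr`, plus AR(1) noise (coefficient 0.3; `noise_sd` is the
  stationary SD, so SNR = amplitude / noise_sd at the response peak;
  default 0.5, i.e. SNR 2 at unit amplitude) plus a random-slope linear
  drift. The nuisance set carries the drift basis and six scripted motion
  series (slow sinusoids plus a small random walk).
* **Response simulation** draws each cell's response Bernoulli with
  P("no") = logistic(Σ β_term · x_term), where `corr` codes as the cell's
  Fisher z and two-level factors as ±1 (alphabetical first level
  positive); ROI-containing coefficients are per-ROI mappings.
* **Fixture bundles** are plain-text TSV/JSON with a manifest of SHA-256
  checksums and the seed; all randomness descends from that one seed, and
  identical seeds give identical bundles.

What the generator does *not* emulate: voxel geometry and spatial
smoothing, physiological noise spectra, HRF variability across regions or
subjects, behavioural dependence of responses on the actual simulated
BOLD (accuracy rates are scheduled, not emergent). Passing recovery tests
therefore demonstrate that the estimators invert this forward model at
the design's scale and noise level — not that the method's assumptions
hold in real data.

## Problem sizes and numerical choices

The test suite runs reduced-scale runs (12 trials, 180 volumes, 4 ROIs)
for unit checks and full-scale 709-volume runs where counts are the point.
Delay recovery is evaluated on 12 ROIs with shifts 0–5 TR at SNR 2,
pooling encoding events from eight runs (480 events per ROI), mirroring
how delay distributions are pooled across subjects and conditions in
practice; a single 60-event run leaves the median's sampling noise
comparable to the margin between the shift-0 population bias and the
0.5 TR recovery bound. The factorial model checks fit ~4,000–6,000 cells
with 635 parameters; coefficient recovery uses 50,000 cells; coverage and
null calibration use 200 replicates at reduced scale.

Numerical conventions worth knowing: population-SD z-scoring; Fisher
clamp 10⁻⁷; collinearity tolerance from pivoted-QR diagonal decay;
delay ties broken toward the earlier peak; Sidak computed as
−expm1(m·log1p(−p)) for small-p stability; all simulation randomness from
`numpy.random.default_rng` seeded explicitly.

## Known limitations

* The delay estimator's "closest peak irrespective of size" rule is noise
  sensitive by design; at SNR 2 roughly a quarter of events lock onto a
  noise peak, which widens the delay distributions (the pooled median
  stays within 0.4 TR of truth). Interpreting per-event delays
  individually is not supported by the method.
* The band-pass shifts BOLD response peaks by ≈ +0.26 TR relative to the
  unfiltered stimulus reference; delay distributions inherit that offset.
* With one cell per condition as an observation, the logistic model treats
  cells as exchangeable and ignores within-subject correlation; a
  mixed-effects extension is out of scope.
* The full 635-parameter model on small synthetic frames can sit near
  separation; the fit flags this, and the type-III degrees of freedom are
  unaffected, but coefficient magnitudes from such fits should not be
  interpreted.
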