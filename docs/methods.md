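# Methods

`oxiscale` studies how the diagnostic value of pulse-oximetry (SpO2) features
for sleep-apnea severity depends on the temporal resolution of the signal.
The pipeline has five stages: signal ingestion and cleaning, multi-scale
coarse-graining, feature extraction, Spearman relevance screening with
scale-trend classification, and repeated seeded severity classification.
Everything is exercisable on synthetic oximetry with known ground truth.

## Signal model and cleaning

A recording is a uniform 1 Hz saturation series with a per-sample validity
mask. Readings strictly below 60 % or strictly above 100 % are treated as
sensor artifacts and *masked*, never deleted: window-based markers need an
intact clock, and deleting samples would silently shift every downstream
window. The boundary values 60.0 and 100.0 are physiological and retained.
No sleep/wake restriction is applied; all markers are normalised by total
recording time.

## Coarse-graining

Scale `tau` replaces the series by means of consecutive non-overlapping
`tau`-second windows (one sample per window, trailing remainder discarded).
The standard grid is {1..10, 15..60 by 5, 120..600 by 60} seconds — 29
scales. Within a window only valid samples are averaged; a fully masked
window yields a masked sample, so no value is ever fabricated. Windows start
at sample 0 and partial windows are dropped, because a short final window
would have inflated variance. For i.i.d. noise the window mean has variance
sigma^2/tau, the usual low-pass interpretation; this is verified by test.

## Desaturation events and oximetry biomarkers

A desaturation event is a maximal run of samples at least `drop_pct`
(default 3 %) below the trailing-mean baseline of the preceding
`baseline_win_s` (default 120 s), lasting at least `min_dur_s` (default
10 s). The baseline is frozen at event onset — updating it during the event
would erode the reference and truncate long events — and the event ends when
a valid sample rises back above (onset baseline − drop). Durations are
measured in seconds (`samples x dt`), so the same configuration applies at
any coarse scale; at `tau` = 60 s a single deep sample already satisfies the
10 s criterion, and the collapse of event counts at coarse scales comes from
depth averaging, which is the physically meaningful mechanism.

Markers: ODI (events per hour), POD (fraction of time inside events), AODmax
(event area below the pre-event local maximum; "local" = the maximum valid
value in the baseline window before onset, not the recording-wide maximum,
which a single early artifact-free peak would otherwise dominate), AOD100
(event area below the 100 % level), CA (integral of the deficit below a
fixed level, default 93 %), and M (percentage of samples at least 2 % below
the median). Areas and integrals are normalised by total recording time.

## Feature bank

All features are pure functions of one series; entropy and complexity
estimators operate on the valid samples concatenated in time order, since
template matching across a masked gap is meaningless. A feature that cannot
be computed (too short a series, no PRSA anchors, infeasible DFA range)
returns NaN rather than raising, which feeds the downstream missingness
filter naturally.

Statistical: mean absolute change, variance, Pearson kurtosis, mean-crossing
rate, Hjorth mobility and complexity, and the central tendency measure
(fraction of successive first-difference pairs inside a disc of radius 0.25).

Entropies (tolerance r = 0.25 x SD unless noted): ApEn (m = 1, with
self-matches), SampEn (m = 1, no self-matches), FuzzEn (m = 2,
mean-subtracted templates, membership exp(-(d/r)^2)), K2En (correlation-sum
estimate with Euclidean distances, m = 2), PermEn (order 3, normalised by
ln 3!), ComplexEn (ordinal statistical complexity: normalised permutation
entropy x normalised Jensen-Shannon disequilibrium; zero for both constant
and fully random signals), ShannonEn (histogram entropy over the 41
one-percent bins 60..100), DispEn (normal-CDF mapping, 6 classes, m = 2),
IncrEn (sign/magnitude-coded increments, 4 quantisation levels, words of 2),
CondEn (Porta's corrected conditional entropy, 6 amplitude classes, minimum
over word lengths up to 5), DistEn (normalised histogram entropy of
inter-template Chebyshev distances, 512 bins), PhasEn (entropy of the
second-order-difference angle distribution in 8 sectors). Degenerate
constant series return 0 for the tolerance- and symbol-based entropies (the
tolerance 0.25 x SD is ill-defined at SD = 0, and a constant signal carries
no irregularity). Each estimator with a tractable brute-force definition is
tested to 1e-9 against an independent loop-based reference.

Complexity: LZ76 phrase count of the median-binarised sequence (ties count
as "below"; deterministic), normalised by n/log2(n); DFA exponent with
linear detrending over log-spaced window sizes 4..n/4 (non-overlapping, and
a 50 %-overlap variant); PRSA capacity with half-length d = 10 over
decrease anchors, capacity = (xbar(0)+xbar(1)-xbar(-1)-xbar(-2))/4.

The bank is extensible: `register_feature(name, fn)` adds a column under a
new name, and `extract_all(..., include=...)` restricts computation — the
O(n^2) template entropies dominate runtime at native resolution, so
cohort-scale studies typically compute them at coarse scales only.

## Screening

The feature matrix is subjects x `{feature}@{tau}s`. Columns with more than
20 % missing or more than 40 % zero cells are excluded (strict inequalities).
Spearman rho against AHI uses pairwise-complete rows and average ranks for
ties; columns with fewer than 3 complete pairs are reported missing.

Each feature's rho-vs-tau profile is assigned a trend group with precedence
D > C > B > A: **D** (constant high) if |rho| > 0.4 at every scale up to
60 s; **C** (polarity shift) if the sign flips between any two scales where
|rho| >= 0.1; **B** (coarser peak) if the native |rho| < 0.3 and a peak
|rho| >= 0.4 occurs at tau >= 6 s; **A** (decaying) if the peak is at
tau <= 5 s and |rho(30 s)| has fallen to at most half the peak. The
thresholds are configurable (`TrendConfig`); they operationalise a
qualitative taxonomy, so profiles that fit none of the rules remain
`unclassified` rather than being forced.

## Severity classification protocol

Severity labels derive from AHI with the clinical cut-offs 5/15/30
(binary tasks, positive = at/above the cut-off) and a four-class label.
Each experiment: stratified 80/20 split (stratification avoids empty
classes in the imbalanced cut-off-30 task), median imputation and standard
scaling fitted on training rows only, a small per-model hyperparameter grid
searched with 5-fold CV, metrics on the held-out 20 %. Experiments repeat
over consecutive seeds (default 50) and report mean ± SD per metric plus a
mean confusion matrix in percent. Metrics are computed in closed form from
the stored confusion counts — accuracy, positive-class precision/
sensitivity/F1 and MCC for binary tasks; macro averages and the Gorodkin
(Rk) multiclass MCC otherwise; AUC only for binary tasks (rank-statistic
form). Models sit behind a fit/predict interface: naive Bayes, logistic
regression, decision tree, k-NN, XGBoost, LightGBM, and a small MLP. The
two boosted-tree entries play the role gradient-boosting ensembles play in
the severity-classification literature; their internals are consumed as
standard components, not tested math.

## Synthetic oximetry

The generator emulates overnight wearable oximetry at 1 Hz:

* baseline ~96.5 % with a slow sinusoidal drift (amplitude 0.4 %, period
  1 h, random phase);
* measurement noise: white noise of SD 0.3 % passed through a 6-sample
  moving average — the internal smoothing pulse oximeters apply — leaving
  autocorrelated noise of effective SD ~0.12 %;
* 1 % output quantisation, as in clinical oximetry exports. Quantisation
  matters: a healthy subject's trace is long runs at a single integer level,
  which is what makes irregularity measures genuinely low for normals and
  monotone in event rate;
* desaturation events: trapezoidal dips whose onset lags the underlying
  respiratory event by 10-40 s. Depths are right-skewed within [3, 10] %
  (exponential scale 0.9 above the 3 % floor): most events are
  near-criterion hypopneic dips, deep ones are rare. A small fraction
  (0.45 %) are "major" events — three times longer and deep — standing in
  for prolonged, deeply desaturating apneas; these are what keeps
  event-based markers weakly informative at very coarse scales;
* event times from a Poisson process thinned by a hard-core spacing rule
  (non-paralyzable dead time), with the nominal intensity dead-time-
  corrected so the realised rate tracks the requested one. The ground-truth
  AHI is always the realised count per hour. `exact_count=True` instead
  places exactly `round(rate x hours)` events with guaranteed spacing, for
  tests that need a known count;
* isolated artifact samples below 60 % at ~1/h, removed by cleaning.

The default inter-event gap (130 s) exceeds the 120 s detection baseline
window so that consecutive events never contaminate each other's baseline;
with the default 15-60 s plateaus this caps the feasible rate near 19/h.
Severe-apnea rates therefore use an adapted morphology — shorter plateaus
(>=12 s), shorter ramps and gaps down to 15 s — which is also the
physiological picture: severe OSA produces short, back-to-back cyclic
events. Cohort builders apply one morphology (adapted to the largest
nominal rate in the cohort) to every subject, so severity differences are
driven by the event rate and depth mix, not by shape artefacts. A
severity-mix preset reproduces a large-cohort class distribution
(13.6/38.4/30.3/17.7 % for normal/mild/moderate/severe).

What the generator does *not* model: REM/NREM architecture, body-position
effects, cardio-respiratory coupling, periodic-breathing oscillation within
events, or device dropouts longer than single samples. Passing tests
therefore demonstrate internal consistency of the method and its qualitative
scale behaviour, not clinical performance on real cohorts.

## Problem sizes and numerical choices

Tests and the acceptance script use scaled-down cohorts chosen as the
smallest sizes at which the qualitative contrasts are stable: 200 subjects x
2 h for the trend-reproduction checks, 100-120 subjects x 1.5 h for the
classification protocol, 10-50 repeats for seeded evaluations. Brute-force
oracle comparisons use series of 50-200 samples, where the O(n^2) references
are exact and fast. Floating-point agreement thresholds are 1e-12 for pure
arithmetic identities (metric closed forms, window means) and 1e-9 for
entropy estimators (log-of-ratio amplification of rounding).

Known limitations: trend-group boundaries are sharp thresholds on estimated
correlations, so profiles near a boundary can change group under resampling;
DFA on very short coarse series is reported missing rather than extrapolated;
the EDF reader takes the first matching oximetry channel label and does not
parse EDF+ annotations.
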