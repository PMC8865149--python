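# Methods

This note documents the models, estimators and numerical choices behind
phenotrack, what the synthetic cohorts do and do not emulate, and the known
limitations.

## Study design emulated by the simulator

The default `SimConfig` describes a transdiagnostic outpatient cohort:
four diagnostic groups (healthy control, major depressive disorder,
bipolar disorder, schizophrenia/schizoaffective), 10 subjects per group,
followed for 8 weeks with a baseline clinician visit and four biweekly
follow-ups. Self-report (PHQ-8, range 0–24) is delivered in-app every
Saturday at 09:00 local time; clinician severity (MADRS, range 0–60) is
rated at visits. A configurable fraction of subjects (default 3/41) is
truncated after the first follow-up, mirroring typical early dropout.

**Latent severity.** Each subject's daily severity follows a mean-reverting
AR(1) process `s_{d+1} = μ_g + ρ (s_d − μ_g) + ε`, clipped to [0, 60], with
group anchors μ_g (SDs in parentheses): HC 0.7 (1.2), MDD 20.0 (12.7),
BP 9.7 (10.6), SCZ 6.2 (5.4). ρ = 0.95 and innovation SD 1.5 per day are
free parameters chosen so that within-subject change is smooth on the
biweekly visit spacing; no published distributional facts constrain them.

**Movement.** A subject has a home and 1–4 recurring away anchors 0.5–5 km
out. Each day draws a Poisson number of excursions (base 2.5/day) with
departure times in 08:00–21:00; an excursion is a straight flight to an
anchor (speed lognormal around 8 m/s — urban door-to-door, mostly
vehicular), a lognormal dwell (base 90 min), and a flight home. Severity
couples multiplicatively: the excursion rate scales by
`exp(c_trip · s/60)` (default c_trip = −1) and dwell by
`exp(c_dwell · s/60)` (default −0.5), so expected distance decreases and
home time increases monotonically in severity; with couplings at zero the
behaviour distribution is severity-invariant by construction (the RNG draws
are identical). The dense path is exact piecewise-linear geometry; GPS
observations sample it inside on-cycles (10 s resolution by default) with
5 m Gaussian noise, and the accelerometer stream (5 s resolution) is
1 g gravity plus 0.01 g rest noise, with 0.3 g per-axis oscillation during
active minutes drawn from a 24-hour diurnal profile (near-zero overnight,
rising from 07:00, plateau 09:00–13:00) scaled down by
`exp(−0.7 · s/60)`.

**What the simulator does not emulate.** Curved roads and within-trip
turning (so distance traveled equals straight-line anchor distance); GPS
multipath/urban-canyon error structure; phone-not-carried accelerometer
missingness distinct from phone-off outages; platform (iOS/Android)
sampling differences; battery dynamics. Passing tests therefore certify
the estimators under idealized motion geometry with realistic duty-cycling
and block missingness — not robustness to every artifact of field data.

## GPS mobility estimation

Coordinates are projected equirectangularly about the subject's median
position (sub-meter accurate over daily extents); timestamps are UTC epoch
milliseconds and all day/hour semantics use the subject's IANA timezone
(day = [00:00, 24:00) local; weekend = Saturday/Sunday).

**Segmentation.** Fixes with reported accuracy worse than 250 m are
dropped. Samples separated by more than `burst_gap_s` (120 s) delimit
on-cycle bursts. Within a burst, a run of points staying within the pause
radius (10 m) of its first point for at least 30 s collapses to a pause at
the run centroid. Transit runs — including their bounding pause states —
are simplified greedily: a sub-path merges into one straight flight while
every interior point lies within the pause radius of the chord. This makes
segmentation resolution-consistent: a densely sampled straight flight is
one flight, not hundreds of sample-step micro-flights, so features
computed from a dense track agree with the generating geometry (the test
suite asserts < 1% relative error).

**Imputation.** Gaps between bursts are filled either by a single straight
flight (`linear`) or by resampling (`resampling`, the default): donors are
the subject's observed flights and pauses within ±24 h, weighted by
`exp(−|Δt|/3 h)` with a 2× bonus for matching weekday/weekend type. The
pause-vs-flight decision uses duration-weighted shares — the probability
that a random instant lies in a pause — and the specific donor of the
chosen kind is drawn by count, so donated flights keep representative
lengths and durations. Donated flights take free headings unless the gap
endpoint would become unreachable at the 90th-percentile donor speed, in
which case they head for it; the final segment is rescaled to land exactly
on the observed endpoint. Count-only draws were measured to over-produce
movement (imputed distance ≈ 3× truth) and always-aim-at-endpoint flights
collapse distance to the linear answer; the implemented scheme reduces the
mean normalized feature error ≈ 2.2–3.1× relative to linear interpolation
across seeds at 30–70% missingness, which is the behaviour the acceptance
suite checks (the direction, not a specific fold improvement).

**Features.** Home is the centroid of the heaviest 21:00–06:00 pause
cluster over follow-up; significant locations are time-weighted k-means
over pause centroids with k grown until every pause is within 200 m of its
centroid (k ≤ 10). Daily features use the imputed (complete) trajectory;
home time integrates exact segment–circle intersections (200 m radius);
the radius of gyration is the time-weighted RMS distance from the
time-weighted centroid, integrated analytically along segments;
probability of pause divides by the full 1440 min; entropy uses the day's
pause-time shares across clusters. Missing GPS minutes count expected
on-cycle minutes (240/day under the 2/10 schedule, midnight phase) without
a raw sample — raw observation only, never imputed coverage. Circadian
(vs all other days) and weekend–weekday (vs opposite-type days) routines
are the mean fraction of co-observed 30-min bins whose representative
positions lie within 500 m; this binned-similarity definition is this
package's documented stand-in for a construct whose exact published
formula is deferred to supplementary material not reproduced here. All
thresholds are config-exposed (`MobilityConfig`).

## Accelerometer activity

A minute is observed with ≥ 5 samples and active when the SD of
`sqrt(x² + y² + z²)` exceeds 0.1 g — platform-neutral and
orientation-robust, chosen over step counting because no step algorithm is
part of the target analysis. Under the 10 s/10 s duty cycle every minute
contains an on-cycle, so fully adherent streams have zero missing minutes
(the completeness denominator is all minutes). Hourly weekday/weekend
curves divide total active by total observed minutes per hour across days:
a ratio estimator invariant to duplicating days, which avoids overweighting
intervals when data happen to be collected.

## Aggregation and models

Each follow-up visit's passive vector holds exactly 32 named statistics:
weekday and weekend means of the 14 GPS features and the activity level
over the 7 days strictly preceding the visit (the visit day is excluded),
plus GPS and accelerometer missing-minute totals over the window. Days
with no data contribute nothing to means (never zeros); only the
missing-minute totals encode absence. The self-report predictor is the
completed survey with the latest completion time at or before local
midnight of the visit day — completion, not delivery, because the score
exists only at completion.

Mixed models use a random subject intercept, fit by maximum likelihood —
ML rather than REML so fits with different fixed-effect sets are
comparable across folds; predictions use fixed effects only, so the
criterion affects nothing but the coefficients. When the likelihood is
degenerate (zero residual variance on noise-free inputs) the fit falls
back to ordinary least squares with zero random-intercept variance, which
is the ML limit. Complete-case exclusion applies at fit time and at
prediction (excluded rows are counted). Diagnosis is dummy-coded against
the healthy-control reference; sex enters as a male indicator.

Leave-one-subject-out CV refits the feature standardizer and PCA inside
every training fold by default (no leakage into loadings); a
`pca_refit_per_fold=False` / `--pca-global` switch reproduces the
descriptive full-data PCA instead, since either reading of the original
procedure is defensible. PCA is computed by SVD of the z-scored complete
rows; constant features are dropped with a warning and components are
sign-fixed so the weekend distance-traveled loading is nonnegative. The
reported average RMSE is the mean of per-subject RMSEs (subjects with no
scorable visit are excluded and logged), not a pooled RMSE. No statistical
model-comparison tests are computed; the package reports fit only.

## Problem sizes and numerical choices

Validation experiments use 100 synthetic days at 30–70% missingness for
the imputation benchmark, 200 replicates of 40 subjects × 4 visits
(σ_b = 3, σ_e = 4) for coefficient coverage (±3 SE) and LOSO RMSE recovery
(target √(σ_b² + σ_e²) = 5, tolerance 15%), and a 40-subject 8-week cohort
for the end-to-end grid — sizes at which the Monte-Carlo checks are stable
while a full run stays in the minutes range on one CPU. Cohort streams are
generated at 10 s (GPS) / 5 s (accelerometer) resolution; the
dense-stream consistency tests use 1 Hz where the invariant demands it.
k-means uses a fixed `random_state`; all simulation randomness derives
from one root seed through named substreams (per subject, per sensor), so
cohorts are byte-reproducible and components can be regenerated
independently. Flight SD uses the sample convention with a single flight
defined as SD 0. Ties in the largest-remainder split of self-report totals
across the 8 items break by item index; only totals are analyzed, so the
split need only respect the 0–3 item range.

## Known limitations

* Home detection needs nighttime pauses; shift workers would defeat the
  21:00–06:00 window (config-exposed).
* Entropy and significant-location counts depend on the clustering radius;
  places closer than 200 m merge.
* The first/last partial days of follow-up have incomplete trajectory
  coverage, which biases probability-of-pause and routine bins for those
  days only.
* The leading gap of a subject's very first burst and the tail after the
  last burst are not imputed (no bounding observations).
* With ~40 subjects, LOSO RMSE differences of a few tenths of a point are
  within resampling noise; the model grid is descriptive, and small-sample
  grids (see the README example) can invert tier orderings.
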