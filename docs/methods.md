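# Methods

This note records the statistical conventions, the generator's assumptions,
and the numerical choices behind `eclorhythm`, in the order the pipeline runs.

## Data model and binning

The unit of analysis is one experiment: one genotype monitored for a
multi-day week at a native cadence of 10 min (or 1 min), binned into
half-open 1-h bins [t, t+1h) labelled by their start. Timestamps are local
standard time; tz-aware input crossing a daylight-saving transition is
rejected unless explicitly overridden (naive input cannot encode one).
Missing native intervals are zero-filled by default, but the missingness
fraction is computed from the expected cadence and analyses refuse to run
above 20% missing (configurable); an `error` policy is available for users
who prefer dropping such experiments. Eclosion being a once-per-fly event,
count conservation through read → bin → pool is asserted throughout.

## Rhythmicity measures

**Autocorrelation / RI.** The correlogram uses the biased estimator
r_k = Σ(y_t−ȳ)(y_{t+k}−ȳ) / Σ(y_t−ȳ)², which decays roughly as (N−k)/N for
a periodic signal; that decay is what the "third peak" convention assumes.
RI is read at the maximum within ±4 h of lag 48 (the lag-0 peak counts as
the first peak); if that maximum is not a local maximum of the correlogram
the value at exactly lag 48 is used and the result flagged. The white-noise
band is ±2/√N. Band boundaries are assigned to the stronger class
(RI = 0.3 → strong, RI = 0.1 → weak): the published bands use strict
inequalities and leave the boundaries undefined, and ties are rare at
floating-point precision anyway.

**Lomb–Scargle.** Periodogram on a 16–32 h grid at 0.1 h steps,
normalised by the sample variance (ddof = 1), so each ordinate is ≈ Exp(1)
under white noise. The 5% line solves 1−(1−e^(−z))^M = 0.05. For M we use
the Horne–Baliunas empirical count for a full 0–Nyquist scan
(−6.362 + 1.193N + 0.00098N²) scaled by the fraction of the Nyquist range
the grid spans. The naive count (band width × duration ≈ 3.75 at N = 120)
under-counts the effective number of independent maxima on an oversampled
grid and yields a ~10% false-positive rate; the band-scaled Horne–Baliunas
count calibrates at 4–5% across N = 96–168 (the package's calibration test
checks this at 1000 replicates). Both the raw peak and the above-line
"nonlinear power" are reported; rhythmicity means power strictly above the
line.

**Cosinor.** Period fixed at 24 h (not fitted). The design is
[1, cos ωt, sin ωt] with t in absolute clock hours, so the acrophase is the
clock time of the fitted peak. The zero-amplitude test is the exact F test
of (β, γ) = (0, 0) on (2, n−3) df; a constant series returns amplitude 0,
p = 1, flagged degenerate.

**Winfree's R.** The gate is the best circular run of 8 consecutive hours —
wrapping midnight, because clockless genotypes eclose well into the second
half of the night, and a non-wrapping window would truncate their gate.
Window ties go to the earliest start hour. R is computed on the pooled
daily profile by default; per-day values can be obtained by pooling each
day separately. Since the best window of a noisy uniform profile is chosen
by maximisation, pooled-count R for a finite uniform sample sits below the
closed-form 200 (≈165 at 400 flies over 5 days).

**Circular statistics.** Hours map to angles by θ = 2πh/24. Circular SD
uses the Mardia convention √(−2 ln r)·24/2π hours rather than the angular
deviation √(2(1−r)); the choice is recorded in the CLI output metadata
because published SDs do not state their convention. The daily peak phase
ψ_PK is the modal 1-h bin of each day, ties resolved to the circular mean
of the tied bins; days without eclosion are omitted. The circular–linear
correlation is Mardia's r_cl with the large-sample nχ²(2) p-value; a seeded
permutation test (default 9999 permutations) is available for small n.

## Discrete-time hazard model

Rows are (group × day × hour) binomial observations: `emerged` out of
`at_risk`, where at-risk flies are those of the same experiment-day that
eclose from that hour onward. The same-day denominator is the default
because a pharate census is unobservable in field data; a
`remaining_total` denominator (all of the experiment's later emergers) is
exposed as an option. Days 2–5 of each week enter the frame; the first and
last days carry too few eclosions to be informative.

Covariates: hour of day centred at 1200 h; hour² built from the centred
hour *before* scaling, so the quadratic captures a before-noon peak;
temperature, light and nautical dawn centred at their pooled means. All are
divided by the root mean square of their centred values, giving z-like
scales so coefficient magnitudes are comparable. Humidity is excluded — it
is strongly anti-correlated with temperature. The centring constants and
RMS divisors are stored on the frame for back-transformation.

The likelihood is binomial-logistic with a single Gaussian random intercept
per experimental group (the minimal reading of environmental covariates
"nested into" the group factor; random slopes are out of scope). The
marginal likelihood integrates the intercept by adaptive Gauss–Hermite
quadrature: per group, a scalar Newton iteration finds the conditional
mode, nodes are centred and scaled there, and the 11-node rule is applied
in log space. The log-likelihood is monotone under node refinement
(7 → 11 → 15) to ~1e-6, and the whole fit matches lme4's `glmer`
(nAGQ = 11) to 2e-3 in coefficients and 0.01 in σ on shared data. With
σ → 0 the fit reduces exactly to an ordinary weighted logistic regression
(verified against statsmodels GLM). Optimisation is L-BFGS-B with σ bounded
at 0; a σ below 1e-6 switches to the exact fixed-effects likelihood.
Standard errors come from the numerically differentiated observed
information. |coefficient| > 15 flags likely separation. A single-group
frame is rejected (σ unidentifiable).

**Backward simplification.** Starting from all main effects plus all
second-order interactions except hour × hour², the removable term
(marginality-respecting: no main leaves while an interaction contains it,
hour stays while hour² is present) with the largest block-Wald p is refit
without; the drop is accepted if the likelihood-ratio p exceeds α = 0.05,
and the procedure stops the first time a candidate drop is significant.
Wald ties go to the later term in the canonical ordering. The procedure is
deterministic and row-order invariant.

**Survival.** S(T) = Π_{h<T}(1 − p_h), S(first hour) = 1. This is the
model's own accounting identity; the package verifies it against empirical
cohort survival (sup-norm < 0.03 at n = 10,000).

## Synthetic data: what it emulates, and what it does not

The generator produces the statistical structure the analysis assumes, not
fly physiology. Per experiment:

- **Environment.** Hourly temperature is a skewed diel curve (piecewise
  cosine warped to a minimum at dawn and a maximum at 15:00) with daily
  mean drawn from 16–24 °C and diel amplitude 6–12 °C, plus 0.5 °C
  hour-to-hour weather noise. Light is a day-length-15.5-h sine of solar
  elevation scaled by a daily lognormal cloud factor (σ = 0.3) and an
  hourly one (σ = 0.4); the hourly factors matter — without them light is a
  deterministic function of hour of day and the hazard model's light term
  is unidentifiable against hour + hour². RH is 70% plus −2.5 %/°C
  temperature coupling, clipped to [0, 100]. Nautical dawn starts at 04:30
  and drifts 0.02 h/day. These ranges put daily minima/maxima inside the
  span reported for temperate outdoor monitoring.
- **Readiness.** Each fly's developmental readiness is Gaussian with mean
  day 3.0 and SD 1.5 days of a 5-day week, so days 2–5 carry most of the
  eclosion and the first/last days are light — the envelope under which
  population monitors are actually scored.
- **Gated genotypes** eclose at the first daily gate time at/after
  readiness; the gate time is a wrapped-normal draw around ψ (default 9 h,
  i.e. a few hours after dawn) with σ = 1.2 h for the strong fixture and
  3 h for the weak one. A `temp_phase_slope` (h/°C of daily minimum
  temperature) shifts ψ per day for thermally coupled genotypes. There is
  no oscillator dynamics — gating is "delay to next opening", the minimal
  mechanism behind the delay argument.
- **Gate-free genotypes** eclose after an exponential waiting time with
  baseline hazard 0.25 h⁻¹ multiplied by exp(0.8 × standardised dawn-onset
  signal), the onset signal being the positive rate of change of
  log-light. Masking responds to the light *transition*: an
  intensity-proportional multiplier would centre eclosion near noon,
  whereas clockless flies in the field eclose around dawn with substantial
  night-time activity. With these defaults the gate-free cohort shows a
  circular mean hours before the gated one, r ≈ 0.2, and Winfree's R near
  the arrhythmicity boundary — the clock-mutant phenotype the analysis is
  meant to detect. Setting `light_slope = 0` gives the within-day-uniform
  null cohort.
- **Hazard-generator option.** `simulate_hazard_dataset` draws binomial
  frames directly from the logistic hazard equation with chosen
  coefficients and group-intercept SD, for parameter-recovery testing.

Not emulated: molecular clock dynamics, development-rate thermal biology,
mortality, monitor failure modes beyond missing intervals, and any spatial
structure. Passing recovery tests therefore shows the *statistics* behave
correctly on data with the assumed structure — not that field data satisfy
those assumptions.

## Problem sizes used in validation

Oracle equivalence runs 200 random profiles per statistic; calibration uses
1000 white-noise series of 120 h; classification recovery 100 seeds × 400
flies × 5 days per condition; hazard recovery 12 replicate fits of ≈52,000
fly-hours across 24 groups (the study-scale number of experimental weeks),
with model selection over 20 seeds at ≈16,000 fly-hours and 10 groups; the
directional contrast 50 paired seeds; the survival identity n = 10,000.
These sizes give the binomial/normal error bars quoted in the tests while
keeping a full validation run around half a minute.

## Known limitations

- The 2-SE coverage of the hazard coefficients is checked in aggregate
  (≥85% of 96 recoveries, the binomial floor of the nominal 95%); a single
  seed can always place one of eight coefficients just outside 2 SE.
- Between-group fixed effects (intercept, genotype main effect) are
  evaluated against the conditional truth given the realised group
  intercepts; their marginal values are unresolvable from finitely many
  groups at σ = 0.5.
- The Lomb–Scargle M is an empirical calibration, not an exact null theory;
  its validity is established by the Monte-Carlo calibration test, for
  hourly series of 3–7 days and the 16–32 h grid.
- Backward simplification stops at the first significant candidate drop; a
  true-null term can in principle survive behind it (observed in ~5% of
  selection seeds when covariates correlate).
- The cosinor period is fixed at 24 h; no multi-component cosinor,
  chi-square periodogram or wavelet methods are provided.
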