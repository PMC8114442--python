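# eclorhythm

Rhythmicity analysis and event-timing modelling for insect **eclosion** — the
once-per-lifetime emergence of the adult fly from the pupal case. Under a
functioning circadian clock, eclosion of a *Drosophila* population is *gated*:
each day the clock opens a permissive window of a few hours, and flies whose
development completes while the gate is closed wait for the next opening.
Whether that gating survives the noisy, fluctuating zeitgebers of the field —
and how it degrades in clock mutants — is a question of population-level
statistics on multi-day event-count records.

`eclorhythm` provides the full analysis stack for such records, plus a
synthetic-data generator that emulates gated and clockless populations under
temperate outdoor conditions so that every stage can be validated against
known ground truth. It is aimed at chronobiologists analysing eclosion (or
other population-gated event) monitors, and at methodologists who need a
reference implementation of the classical rhythmicity statistics.

## What it computes

For an experiment binned into 1-h counts (native monitor cadence 10 min or
1 min):

- **Autocorrelation rhythmicity index (RI)** — the biased (divide-by-*N*)
  correlogram of the mean-subtracted counts; RI is the height of the third
  peak (near lag 2 × 24 h). Bands: RI > 0.3 strong, 0.1–0.3 weak, < 0.1
  arrhythmic.
- **Lomb–Scargle "nonlinear power"** — variance-normalised periodogram on a
  16–32 h period grid; the reported power is the peak height *above* the 5%
  significance line *z*\* solving 1 − (1 − e^(−z))^M = 0.05, with *M* the
  effective number of independent frequencies in the band. Power 0 ⇒
  arrhythmic by this test.
- **Single cosinor** — least squares of *y(t) = M + A·*cos(2π(*t* − φ)/24)
  with the zero-amplitude *F* test on (2, *n* − 3) df; reports mesor *M*,
  amplitude *A*, acrophase φ.
- **Winfree's R** — find the 8-consecutive-hour window (wrapping midnight)
  holding the most eclosions; *R* = 100 × outside/inside. Bands: R < 60
  strong, 60–90 weak, > 90 arrhythmic.
- **Circular statistics** — mean eclosion hour, mean vector length
  *r* = |Σe^(iθ)|/n, circular SD √(−2 ln r) (in hours), daily peak phase
  ψ_PK, and Mardia's circular–linear correlation between phase and an
  environmental covariate.
- **Discrete-time logistic hazard model** — the probability *p_h* that a fly
  eclosing today does so in hour *h*, given it has not yet emerged today:
  logit(*p_h*) = genotype + hour + hour² + temperature + light + nautical
  dawn (+ all second-order interactions except hour × hour²) + a Gaussian
  random intercept per experimental group. Covariates are centred (hour at
  1200 h) and scaled by their root mean square. The marginal likelihood is
  maximised with adaptive Gauss–Hermite quadrature (11 nodes), and the model
  is reduced by backward simplification with likelihood-ratio acceptance.
  The daily survival identity S(T) = Π_{h<T}(1 − p_h) links the fitted
  hazards to the fraction not yet emerged.

## Worked example

```python
import numpy as np
import eclorhythm as er
from eclorhythm.synthetic_data import wildtype_gated, clockless
from eclorhythm.circular_stats import circular_summary
from eclorhythm.io_formats import pool_daily

env = er.simulate_environment(er.SeasonSpec(), seed=1)
for spec in (wildtype_gated("WT"), clockless("per01_like")):
    events, truth = er.simulate_cohort(er.CohortSpec(n_flies=400, seed=2), spec, env, seed=2)
    profile = er.bin_hourly(events)
    report = er.analyze_profile(profile)
    circ = circular_summary(np.arange(24) + 0.5,
                            weights=pool_daily(profile).counts_by_hour)
    print(f"{spec.label}: RI={report.ri:.2f} ({report.ri_class}), "
          f"LS power={report.ls_power:.1f}, cosinor A={report.cos_amplitude:.1f} "
          f"(p={report.cos_p:.2g}), R={report.winfree_r:.1f} ({report.winfree_class}), "
          f"mean={circ.mean_hour:.2f} h, r={circ.r:.3f}")
```

prints

```
WT: RI=0.45 (strong), LS power=12.5, cosinor A=5.2 (p=1.3e-09), R=0.0 (strong), mean=9.10 h, r=0.951
per01_like: RI=0.39 (strong), LS power=0.0, cosinor A=1.2 (p=0.094), R=89.9 (weak), mean=3.43 h, r=0.194
```

The gated wild-type cohort is strongly rhythmic by every measure, with all
eclosion inside the best 8-h gate (R = 0) and a tight morning peak
(mean 09:06-like, *r* = 0.95). The clockless, dawn-masked cohort eclosed
hours earlier on average with a broad distribution: Winfree's R is at the
edge of arrhythmicity, the Lomb–Scargle power and cosinor find no 24-h
rhythm — yet the autocorrelation still picks up the day-to-day regularity of
the dawn burst. The four measures disagreeing in exactly this way is the
expected signature of light-driven ("masked") rather than clock-gated
eclosion.

A command-line pipeline wraps the same stages:

```
eclorhythm simulate --seed 11 --out-dir runs/demo
eclorhythm analyze --events runs/demo/fixtures/strong_gated_events.csv --out-dir runs/demo/an
eclorhythm model --events ... --env ... --dawn ... --out-dir runs/demo/model
eclorhythm report --reports runs/demo/an/*_report.tsv --out-dir runs/demo/pooled
```

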