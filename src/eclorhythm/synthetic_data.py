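"""Synthetic eclosion experiments under fluctuating temperate zeitgebers.

The generator emulates the statistical structure the analysis stack assumes:

* a multi-day population of pharate adults whose developmental readiness is
  Gaussian across days;
* clock-gated genotypes whose eclosion is deferred to the next daily gate
  opening, with wrapped-normal dispersion inside the gate and an optional
  temperature-dependent phase shift (the gate tracks the daily minimum
  temperature for thermally coupled genotypes);
* gate-free (clockless) genotypes that eclose after an exponential waiting
  time whose hourly hazard is multiplied by exp(light_slope · standardized
  dawn-onset signal) — purely light-driven ("masked") eclosion that clusters
  after dawn rather than at peak intensity;
* diel temperature / light / relative-humidity traces with day-to-day
  variability, a linearly drifting dawn, and the negative temperature–RH
  coupling seen in temperate field records.

Gating delays flies that become ready while the gate is closed, so gated
cohorts eclose later and more tightly than gate-free ones — the headline
contrast the analysis is meant to detect.

All randomness flows from a single seed through `numpy.random.default_rng`
child streams; fixture manifests record every parameter.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    EnvironmentSeries,
    EventSeries,
    write_environment,
    write_events,
)
from .hazard_model import ModelFrame, _NUMERIC_COLUMNS, build_design

__all__ = [
    "GenotypeSpec",
    "SeasonSpec",
    "CohortSpec",
    "simulate_environment",
    "simulate_cohort",
    "make_fixture_suite",
    "simulate_hazard_dataset",
    "wildtype_gated",
    "weak_gated",
    "clockless",
    "temperature_coupled",
]

_EPOCH = pd.Timestamp("2015-06-01 00:00")


@dataclass(frozen=True)
class GenotypeSpec:
    """Behavioral parameters of a simulated genotype.

    ``gate_phase_hour`` is the population gate center ψ (hours after
    midnight); ``gate_sd_hours`` the wrapped-normal within-gate dispersion σ;
    ``temp_phase_slope`` shifts ψ by that many hours per °C of daily minimum
    temperature away from ``temp_reference_c``. Gate-free genotypes ignore the
    gate parameters and eclose with baseline hourly hazard
    ``base_hazard_per_hour`` multiplied by exp(light_slope · onset_s), where
    onset_s is the standardized positive rate of change of log light.
    """

    label: str
    gated: bool
    gate_phase_hour: float = 9.0
    gate_sd_hours: float = 1.2
    light_slope: float = 0.8
    temp_phase_slope: float = 0.0
    temp_reference_c: float = 15.0
    base_hazard_per_hour: float = 0.25

    def __post_init__(self) -> None:
        if self.gated and self.gate_sd_hours <= 0:
            raise ValueError("gate_sd_hours must be positive")
        for v in (self.light_slope, self.temp_phase_slope):
            if not np.isfinite(v):
                raise ValueError("slopes must be finite")


@dataclass(frozen=True)
class SeasonSpec:
    """Day-to-day structure of a temperate monitoring week.

    Daily mean temperature and diel amplitude are drawn uniformly from the
    configured intervals; the dawn drifts linearly across days; lognormal
    cloud factors modulate light; RH couples negatively to temperature.
    """

    n_days: int = 5
    dawn_start_hour: float = 4.5
    dawn_drift_per_day: float = 0.02
    temp_mean_range: tuple[float, float] = (16.0, 24.0)
    temp_amp_range: tuple[float, float] = (6.0, 12.0)
    cloud_sd: float = 0.3
    cloud_sd_hourly: float = 0.4
    temp_noise_sd: float = 0.5
    rh_coupling: float = -2.5
    rh_baseline: float = 70.0
    day_length_hours: float = 15.5
    peak_light: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be at least 1")
        if self.temp_amp_range[0] < 0 or self.temp_amp_range[0] > self.temp_amp_range[1]:
            raise ValueError("invalid temperature amplitude range")
        if self.temp_mean_range[0] > self.temp_mean_range[1]:
            raise ValueError("invalid temperature mean range")


@dataclass(frozen=True)
class CohortSpec:
    """Developmental envelope of a simulated pharate-adult population."""

    n_flies: int = 400
    readiness_mean_day: float = 3.0
    readiness_sd_days: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies <= 0:
            raise ValueError("n_flies must be positive")
        if self.readiness_sd_days <= 0:
            raise ValueError("readiness_sd_days must be positive")


def _diel_temperature(hour_of_day: np.ndarray, dawn: float, mean: float,
                      amp: float) -> np.ndarray:
    """Skewed diel curve: minimum at dawn, maximum at 15:00 local.

    The hour axis is warped piecewise-linearly so that a plain cosine puts its
    trough at dawn and crest at 15:00 (short rise, long fall).
    """
    peak = 15.0
    h = (hour_of_day - dawn) % 24.0
    rise = (peak - dawn) % 24.0
    phase = np.where(
        h <= rise,
        np.pi + np.pi * h / rise,          # trough -> crest
        2 * np.pi + np.pi * (h - rise) / (24.0 - rise),  # crest -> trough
    )
    return mean + 0.5 * amp * np.cos(phase)


def simulate_environment(
    season: SeasonSpec, seed: int, start: pd.Timestamp = _EPOCH
) -> EnvironmentSeries:
    """Generate hourly temperature/light/RH plus per-day nautical dawn."""
    rng = np.random.default_rng(seed)
    n = season.n_days * 24
    ts = pd.date_range(start, periods=n, freq="h")
    hod = ts.hour.to_numpy(float)
    day = np.arange(n) // 24
    means = rng.uniform(*season.temp_mean_range, size=season.n_days)
    amps = rng.uniform(*season.temp_amp_range, size=season.n_days)
    clouds = np.exp(rng.normal(0.0, season.cloud_sd, size=season.n_days))
    dawns = season.dawn_start_hour + season.dawn_drift_per_day * np.arange(season.n_days)
    # hour-to-hour weather variation keeps light from being a deterministic
    # function of hour of day (passing clouds, fronts)
    temp = _diel_temperature(hod, dawns[day], means[day], amps[day])
    temp = temp + rng.normal(0.0, season.temp_noise_sd, size=n)
    elev = np.sin(np.pi * (hod - dawns[day]) / season.day_length_hours)
    hourly_clouds = np.exp(rng.normal(0.0, season.cloud_sd_hourly, size=n))
    light = season.peak_light * clouds[day] * hourly_clouds * np.clip(elev, 0.0, None)
    light[(hod < dawns[day]) | (hod > dawns[day] + season.day_length_hours)] = 0.0
    rh = season.rh_baseline + season.rh_coupling * (temp - temp.mean())
    rh = np.clip(rh, 0.0, 100.0)
    hourly = pd.DataFrame(
        {"timestamp": ts, "temperature_c": temp, "light": light, "rh_percent": rh}
    )
    dawn_by_date = {
        (start.normalize() + pd.Timedelta(days=int(d))).date(): float(dawns[d])
        for d in range(season.n_days)
    }
    return EnvironmentSeries(hourly=hourly, dawn_by_date=dawn_by_date)


def _daily_min_temperature(env: EnvironmentSeries) -> dict:
    df = env.hourly
    dates = pd.DatetimeIndex(df["timestamp"]).normalize()
    return {d.date(): float(g) for d, g in df.groupby(dates)["temperature_c"].min().items()}


def _standardized_light_onset(env: EnvironmentSeries) -> np.ndarray:
    """Standardized dawn-onset signal: positive rate of change of log light.

    Masking responses of clockless flies track the light transition rather
    than absolute intensity (their eclosion clusters near sunrise, not noon),
    so the hazard multiplier uses the onset signal.
    """
    light = env.hourly["light"].to_numpy(float)
    onset = np.clip(np.diff(np.log1p(light), prepend=np.log1p(light[0])), 0.0, None)
    c = onset - onset.mean()
    rms = np.sqrt(np.mean(c**2))
    return c / rms if rms > 0 else c


def simulate_cohort(
    cohort: CohortSpec,
    genotype: GenotypeSpec,
    env: EnvironmentSeries,
    seed: int | None = None,
) -> tuple[EventSeries, dict]:
    """Simulate one eclosion experiment; returns events plus a ground-truth manifest.

    Each fly draws a developmental readiness instant. Gated genotypes eclose
    at the first daily gate time at or after readiness, the gate time being a
    wrapped-normal draw around the (possibly temperature-shifted) gate phase
    of that day. Gate-free genotypes wait an exponential time whose hourly
    hazard follows the light profile. Flies whose eclosion falls beyond the
    environment window are censored and counted in the manifest.
    """
    rng = np.random.default_rng(cohort.seed if seed is None else seed)
    start, end = env.window()
    n_hours = len(env.hourly)
    horizon = n_hours  # hours from start
    readiness = rng.normal(
        cohort.readiness_mean_day * 24.0, cohort.readiness_sd_days * 24.0,
        size=cohort.n_flies,
    )
    readiness = np.clip(readiness, 0.0, None)
    tmin = _daily_min_temperature(env)
    dates = sorted(tmin)
    psi_by_day = {}
    for i, d in enumerate(dates):
        shift = genotype.temp_phase_slope * (tmin[d] - genotype.temp_reference_c)
        psi_by_day[i] = genotype.gate_phase_hour + shift
    ecl_times = np.full(cohort.n_flies, np.nan)
    if genotype.gated:
        max_day = len(dates)
        for f in range(cohort.n_flies):
            d = max(int(readiness[f] // 24) - 1, 0)
            while d < max_day + 2:
                psi = psi_by_day.get(min(d, max_day - 1), genotype.gate_phase_hour)
                offset = rng.normal(0.0, genotype.gate_sd_hours)
                t = d * 24.0 + (psi + offset) % 24.0
                if t >= readiness[f]:
                    ecl_times[f] = t
                    break
                d += 1
    else:
        onset_s = _standardized_light_onset(env)
        log_h0 = np.log(genotype.base_hazard_per_hour)
        hazard = np.exp(log_h0 + genotype.light_slope * onset_s)
        for f in range(cohort.n_flies):
            h = int(readiness[f] // 1)
            t = readiness[f]
            while h < horizon:
                rate = hazard[min(h, horizon - 1)]
                wait = rng.exponential(1.0 / rate)
                if t + wait < h + 1:
                    ecl_times[f] = t + wait
                    break
                t = float(h + 1)
                h += 1
    censored = int(np.sum(~(ecl_times <= horizon)))
    ok = ecl_times[ecl_times <= horizon]
    # aggregate to 10-min native records over the full window
    n_slots = n_hours * 6
    slot = np.minimum((ok / (10.0 / 60.0)).astype(int), n_slots - 1)
    counts = np.bincount(slot, minlength=n_slots)
    timestamps = pd.date_range(start, periods=n_slots, freq="10min")
    events = EventSeries(
        experiment_id=f"{genotype.label}-s{seed if seed is not None else cohort.seed}",
        genotype=genotype.label,
        timestamps=timestamps,
        counts=counts,
        cadence_minutes=10,
    )
    truth = {
        "genotype": asdict(genotype),
        "cohort": asdict(cohort),
        "n_eclosed": int(len(ok)),
        "n_censored": censored,
        "gate_phase_by_day": {str(k): float(v) for k, v in psi_by_day.items()},
        "eclosion_hours": [float(v) for v in ok],
    }
    return events, truth


def wildtype_gated(label: str = "WT") -> GenotypeSpec:
    return GenotypeSpec(label=label, gated=True, gate_phase_hour=9.0, gate_sd_hours=1.2)


def weak_gated(label: str = "weak") -> GenotypeSpec:
    return GenotypeSpec(label=label, gated=True, gate_phase_hour=9.0, gate_sd_hours=3.0)


def clockless(label: str = "clockless") -> GenotypeSpec:
    return GenotypeSpec(label=label, gated=False, light_slope=0.8)


def temperature_coupled(label: str = "tempcoupled") -> GenotypeSpec:
    return GenotypeSpec(label=label, gated=True, gate_phase_hour=9.0,
                        gate_sd_hours=1.5, temp_phase_slope=-0.3)


def make_fixture_suite(out_dir, seed: int) -> dict:
    """Write a small battery of experiments with ground-truth manifests.

    Emits strong-gated, weak-gated, gate-free and temperature-coupled cohorts
    under one shared environment, in the package's event/environment dialects,
    plus a YAML manifest per experiment. Deterministic for a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(seed)
    season = SeasonSpec()
    env = simulate_environment(season, seed=int(root.integers(2**31)))
    write_environment(env, out / "environment.csv", out / "dawn.csv")
    manifest_index = {}
    specs = [wildtype_gated("strong_gated"), weak_gated("weak_gated"),
             clockless("gate_free"), temperature_coupled("temp_coupled"),
             GenotypeSpec("uniform", gated=False, light_slope=0.0)]
    # only the clear-cut designs carry an expected Winfree class; the
    # intermediate fixtures straddle the published bands by construction
    expected = {"strong_gated": "strong", "uniform": "arrhythmic"}
    for spec in specs:
        sub_seed = int(root.integers(2**31))
        cohort = CohortSpec(n_flies=400, seed=sub_seed)
        events, truth = simulate_cohort(cohort, spec, env, seed=sub_seed)
        write_events(events, out / f"{spec.label}_events.csv")
        truth["season"] = asdict(season)
        truth["expected_class"] = expected.get(spec.label)
        with open(out / f"{spec.label}_manifest.yaml", "w") as fh:
            yaml.safe_dump(truth, fh)
        manifest_index[spec.label] = {
            "events": f"{spec.label}_events.csv",
            "manifest": f"{spec.label}_manifest.yaml",
        }
    with open(out / "suite.yaml", "w") as fh:
        yaml.safe_dump({"seed": seed, "experiments": manifest_index}, fh)
    return manifest_index


# ---------------------------------------------------------------------------
# direct simulation from the hazard model


def simulate_hazard_dataset(
    coefficients: dict,
    *,
    n_groups: int = 10,
    flies_per_group_day: int = 130,
    days: tuple[int, int] = (2, 5),
    sigma_group: float = 0.5,
    seed: int = 0,
    season: SeasonSpec | None = None,
) -> tuple[ModelFrame, dict]:
    """Simulate binomial frames directly from the logistic hazard equation.

    ``coefficients`` maps design-column names (as produced by
    :func:`eclorhythm.hazard_model.build_design`, e.g. ``intercept``, ``hour``,
    ``genotype[mut]:temp``) to true values on the standardized scale; missing
    columns are zero. Groups alternate between two genotypes ``wt`` and
    ``mut``. Within each day the at-risk count starts at
    ``flies_per_group_day`` and eclosed flies leave the risk set. Returns the
    frame and a truth dict (coefficients, sigma, per-group intercepts).
    """
    rng = np.random.default_rng(seed)
    season = season or SeasonSpec()
    rows = []
    b_by_group = rng.normal(0.0, sigma_group, size=n_groups)
    for g in range(n_groups):
        env = simulate_environment(season, seed=int(rng.integers(2**31)))
        geno = "wt" if g % 2 == 0 else "mut"
        df = env.hourly
        hod = pd.DatetimeIndex(df["timestamp"]).hour.to_numpy()
        day_idx = np.arange(len(df)) // 24 + 1
        for d in range(days[0], days[1] + 1):
            sel = day_idx == d
            date = (df["timestamp"].iloc[np.where(sel)[0][0]]).date()
            dawn = env.dawn_by_date[date]
            for h, t, li in zip(hod[sel], df["temperature_c"][sel], df["light"][sel]):
                rows.append(
                    {"group_id": f"g{g}", "genotype": geno, "day_index": d,
                     "hour": int(h), "temp": float(t), "light": float(li),
                     "dawn": float(dawn)}
                )
    df = pd.DataFrame(rows)
    from .hazard_model import _standardize

    scales = {}
    df["hour_c"], c, s = _standardize(df["hour"].to_numpy(), center=12.0)
    scales["hour"] = (c, s)
    hq = (df["hour"].to_numpy(float) - 12.0) ** 2
    rms = float(np.sqrt(np.mean(hq**2)))
    df["hour_c2"] = hq / rms
    scales["hour2"] = (0.0, rms)
    for name in ("temp", "light", "dawn"):
        df[_NUMERIC_COLUMNS[name]], c, s = _standardize(df[name].to_numpy())
        scales[name] = (c, s)
    df["at_risk"] = 0
    df["emerged"] = 0
    frame = ModelFrame(data=df, scales=scales)
    from .hazard_model import default_terms

    terms = default_terms()
    X, names, _ = build_design(frame, terms)
    beta = np.array([coefficients.get(nm, 0.0) for nm in names])
    group_codes = pd.factorize(df["group_id"])[0]
    eta = X @ beta + b_by_group[group_codes]
    p = 1.0 / (1.0 + np.exp(-eta))
    at_risk = np.zeros(len(df), dtype=int)
    emerged = np.zeros(len(df), dtype=int)
    key = df["group_id"].astype(str) + "/" + df["day_index"].astype(str)
    for _, idx in df.groupby(key, sort=False).indices.items():
        idx = np.sort(idx)
        alive = flies_per_group_day
        for i in idx:
            at_risk[i] = alive
            if alive == 0:
                continue
            e = rng.binomial(alive, p[i])
            emerged[i] = e
            alive -= e
    df = df.assign(at_risk=at_risk, emerged=emerged)
    df = df[df["at_risk"] > 0].reset_index(drop=True)
    frame = ModelFrame(data=df, scales=scales)
    truth = {
        "coefficients": {nm: float(b) for nm, b in zip(names, beta)},
        "sigma_group": float(sigma_group),
        "group_intercepts": b_by_group.tolist(),
        "terms": terms,
        "column_names": names,
    }
    return frame, truth
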