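"""Circular summaries of eclosion time of day and circular-linear correlation.

Hour-of-day values h map to angles θ = 2πh/24. The mean direction and mean
vector length r come from the resultant of unit vectors; circular SD uses the
Mardia convention √(−2 ln r), converted back to hours. The circular-linear
correlation is Mardia's coefficient with either the large-sample chi-square
p-value or a seeded permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date

import numpy as np

from .io_formats import HourlyProfile

__all__ = [
    "CircularSummary",
    "PeakPhase",
    "circular_summary",
    "daily_peak_phase",
    "circular_linear_correlation",
    "circular_difference_hours",
]

_HOURS_TO_RAD = 2 * np.pi / 24.0


@dataclass(frozen=True)
class CircularSummary:
    mean_hour: float        # [0, 24); NaN when r == 0
    r: float                # mean vector length in [0, 1]
    circ_sd_hours: float    # Mardia circular SD in hours; inf when r == 0
    n: int


@dataclass(frozen=True)
class PeakPhase:
    date: _date
    psi_pk_hour: float      # hour of day of the daily peak, [0, 24)
    peak_count: int


def _circular_mean_hours(hours: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    theta = np.asarray(hours, float) * _HOURS_TO_RAD
    w = np.asarray(weights, float)
    c = float(np.sum(w * np.cos(theta)))
    s = float(np.sum(w * np.sin(theta)))
    n = float(w.sum())
    r = np.hypot(c, s) / n
    mean = (np.arctan2(s, c) / _HOURS_TO_RAD) % 24.0
    return mean, r


def circular_summary(event_hours, weights=None) -> CircularSummary:
    """Circular mean, vector length and circular SD of event hours of day.

    ``weights`` are per-value event counts; with none given every value counts
    once. r = 1 iff all mass sits at one angle; r = 0 leaves the mean
    undefined (NaN) and the SD infinite.
    """
    hours = np.asarray(event_hours, dtype=float)
    if weights is None:
        weights = np.ones_like(hours)
    weights = np.asarray(weights, dtype=float)
    if hours.size == 0 or weights.sum() <= 0:
        raise ValueError("circular summary needs at least one event")
    mean, r = _circular_mean_hours(hours, weights)
    r = min(max(r, 0.0), 1.0)
    if r == 0.0:
        return CircularSummary(np.nan, 0.0, np.inf, int(round(weights.sum())))
    sd = np.sqrt(-2.0 * np.log(r)) / _HOURS_TO_RAD if r < 1.0 else 0.0
    return CircularSummary(float(mean), float(r), float(sd), int(round(weights.sum())))


def daily_peak_phase(profile: HourlyProfile) -> list[PeakPhase]:
    """Per-day peak eclosion phase ψ_PK: the modal 1-h bin of each day.

    Ties are resolved to the circular mean of the tied bins; days with zero
    eclosion are omitted.
    """
    out: list[PeakPhase] = []
    hours = profile.hours
    counts = profile.counts
    days = hours.normalize()
    for day in days.unique():
        sel = days == day
        c = counts[sel]
        if c.sum() == 0:
            continue
        h = hours[sel].hour.to_numpy()
        peak = c.max()
        tied = h[c == peak]
        if len(tied) == 1:
            psi = float(tied[0])
        else:
            psi, _ = _circular_mean_hours(tied, np.ones(len(tied)))
        out.append(PeakPhase(date=day.date(), psi_pk_hour=psi % 24.0,
                             peak_count=int(peak)))
    if not out:
        raise ValueError("no day with nonzero eclosion")
    return out


def circular_linear_correlation(
    phases_hours,
    x,
    *,
    method: str = "chi2",
    n_permutations: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mardia's circular-linear correlation between phase and a linear covariate.

    With r_xc = corr(x, cos θ), r_xs = corr(x, sin θ), r_cs = corr(cos θ, sin θ):

        r_cl² = (r_xc² + r_xs² − 2 r_xc r_xs r_cs) / (1 − r_cs²)

    The p-value tests independence via n·r_cl² ~ χ²(2) (``method='chi2'``) or
    by a seeded permutation of x (``method='permutation'``).
    """
    phases = np.asarray(phases_hours, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(phases)
    if n < 4 or len(x) != n:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate covariate: x is constant")
    theta = phases * _HOURS_TO_RAD
    c, s = np.cos(theta), np.sin(theta)
    if np.ptp(c) == 0 and np.ptp(s) == 0:
        raise ValueError("degenerate covariate: phase is constant")

    def _rcl(xv: np.ndarray) -> float:
        rxc = np.corrcoef(xv, c)[0, 1]
        rxs = np.corrcoef(xv, s)[0, 1]
        rcs = np.corrcoef(c, s)[0, 1]
        num = rxc**2 + rxs**2 - 2 * rxc * rxs * rcs
        den = 1 - rcs**2
        return float(np.sqrt(max(num / den, 0.0)))

    r_cl = min(_rcl(x), 1.0)
    if method == "chi2":
        from scipy import stats

        p = float(stats.chi2.sf(n * r_cl**2, 2))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        hits = sum(
            _rcl(rng.permutation(x)) >= r_cl for _ in range(n_permutations)
        )
        p = (hits + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return r_cl, p


def circular_difference_hours(a: float, b: float) -> float:
    """Signed circular difference a − b on the 24-h clock, in (−12, 12]."""
    d = (a - b) % 24.0
    return d - 24.0 if d > 12.0 else d
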