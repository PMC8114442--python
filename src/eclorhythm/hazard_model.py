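"""Discrete-time logistic hazard model of within-day eclosion timing.

The response is the number of flies eclosing in a given hour out of those at
risk — flies of the same experiment-day that had not yet emerged before that
hour. The linear predictor combines genotype (factorial), hour of day and its
square, temperature, light intensity and nautical dawn (all standardized),
their second-order interactions (hour × hour² excluded), and a Gaussian random
intercept per experimental group. The marginal likelihood is maximized with
adaptive Gauss–Hermite quadrature; model reduction proceeds by backward
simplification with likelihood-ratio acceptance.

The daily survival identity S(T) = Π_{h<T} (1 − p_h) gives the probability of
not having eclosed before hour T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats

from .io_formats import EnvironmentSeries, EventSeries, bin_hourly

__all__ = [
    "ModelFrame",
    "HazardFit",
    "build_frame",
    "combine_frames",
    "fit_hazard",
    "backward_simplify",
    "survival_curve",
    "DEFAULT_TERMS",
]

# canonical term vocabulary -> frame column (genotype is expanded as a factor)
_NUMERIC_COLUMNS = {
    "hour": "hour_c",
    "hour2": "hour_c2",
    "temp": "temp_s",
    "light": "light_s",
    "dawn": "dawn_s",
}

MAIN_TERMS = ("genotype", "hour", "hour2", "temp", "light", "dawn")


def default_terms(include_genotype: bool = True) -> list[str]:
    """All main effects plus all second-order interactions except hour × hour²."""
    mains = [t for t in MAIN_TERMS if include_genotype or t != "genotype"]
    terms = list(mains)
    for i, a in enumerate(mains):
        for b in mains[i + 1 :]:
            if {a, b} == {"hour", "hour2"}:
                continue
            terms.append(f"{a}:{b}")
    return terms


DEFAULT_TERMS = default_terms()


@dataclass(frozen=True)
class ModelFrame:
    """Aggregated binomial rows (group × day × hour) with standardized covariates.

    ``scales`` records the centering constant and RMS divisor used for each
    covariate so that coefficients can be mapped back to natural units.
    """

    data: pd.DataFrame
    scales: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        req = {"group_id", "genotype", "day_index", "hour", "at_risk", "emerged"}
        missing = req - set(self.data.columns)
        if missing:
            raise ValueError(f"frame missing columns {sorted(missing)}")
        d = self.data
        if (d["emerged"] > d["at_risk"]).any() or (d["emerged"] < 0).any():
            raise ValueError("emerged must lie in [0, at_risk]")

    @property
    def fly_hours(self) -> int:
        return int(self.data["at_risk"].sum())

    @property
    def n_groups(self) -> int:
        return self.data["group_id"].nunique()


def _standardize(values: np.ndarray, center: float | None = None) -> tuple[np.ndarray, float, float]:
    """Center (default: at the mean) then divide by the RMS of the centered values."""
    v = np.asarray(values, dtype=float)
    c = float(v.mean()) if center is None else float(center)
    centered = v - c
    rms = float(np.sqrt(np.mean(centered**2)))
    if rms == 0.0:
        raise ValueError("covariate is constant; cannot standardize")
    return centered / rms, c, rms


def build_frame(
    experiments: Sequence[tuple[EventSeries, EnvironmentSeries]],
    days: tuple[int, int] = (2, 5),
    denominator: str = "same_day",
) -> ModelFrame:
    """Assemble the binomial model frame from event/environment pairs.

    Each pair is one experimental group. Days are indexed from 1 at the first
    monitored calendar day; only ``days[0]..days[1]`` enter the frame (the
    first and last days carry too few eclosions to be informative). The
    at-risk denominator is, per day, the flies that eclose from that hour
    onward — same-day emergers by default, or all remaining emergers of the
    experiment with ``denominator='remaining_total'``. Humidity is excluded
    (collinear with temperature). Hour is centered at 1200 h; all covariates
    are centered then divided by their root mean square on the pooled frame.
    """
    if denominator not in ("same_day", "remaining_total"):
        raise ValueError(f"unknown denominator {denominator!r}")
    rows = []
    for events, env in experiments:
        profile = bin_hourly(events)
        env_ts = pd.DatetimeIndex(env.hourly["timestamp"])
        env_lookup = env.hourly.set_index(env_ts)
        day0 = profile.start.normalize()
        hours = profile.hours
        counts = profile.counts
        day_index = ((hours.normalize() - day0).days + 1).to_numpy()
        keep = (day_index >= days[0]) & (day_index <= days[1])
        missing_env = [h for h in hours[keep] if h not in env_lookup.index]
        if missing_env:
            raise ValueError(
                f"environment series lacks hours {missing_env[:5]} "
                f"for experiment {events.experiment_id}"
            )
        total_after = np.cumsum(counts[::-1])[::-1]  # incl. current hour
        for d in range(days[0], days[1] + 1):
            sel = day_index == d
            if not sel.any():
                continue
            idx = np.where(sel)[0]
            day_total = counts[idx].sum()
            emerged_before = np.concatenate([[0], np.cumsum(counts[idx])[:-1]])
            if denominator == "same_day":
                at_risk = day_total - emerged_before
            else:
                at_risk = total_after[idx]
            for j, i in enumerate(idx):
                if at_risk[j] <= 0:
                    continue
                h = hours[i]
                erow = env_lookup.loc[h]
                dawn = env.dawn_by_date.get(h.date(), np.nan)
                rows.append(
                    {
                        "group_id": events.experiment_id,
                        "genotype": events.genotype,
                        "day_index": d,
                        "hour": h.hour,
                        "at_risk": int(at_risk[j]),
                        "emerged": int(counts[i]),
                        "temp": float(erow["temperature_c"]),
                        "light": float(erow["light"]),
                        "dawn": float(dawn),
                    }
                )
    if not rows:
        raise ValueError("no at-risk fly-hours in the requested day range")
    df = pd.DataFrame(rows)
    if df["dawn"].isna().any():
        raise ValueError("nautical dawn missing for some experiment dates")
    scales: dict = {}
    df["hour_c"], c, s = _standardize(df["hour"].to_numpy(), center=12.0)
    scales["hour"] = (c, s)
    hq = (df["hour"].to_numpy(float) - 12.0) ** 2
    rms = float(np.sqrt(np.mean(hq**2)))
    df["hour_c2"] = hq / rms
    scales["hour2"] = (0.0, rms)
    for name in ("temp", "light", "dawn"):
        df[_NUMERIC_COLUMNS[name]], c, s = _standardize(df[name].to_numpy())
        scales[name] = (c, s)
    return ModelFrame(data=df, scales=scales)


def combine_frames(frames: Sequence[ModelFrame]) -> ModelFrame:
    data = pd.concat([f.data for f in frames], ignore_index=True)
    return ModelFrame(data=data, scales=dict(frames[0].scales))


# ---------------------------------------------------------------------------
# design matrix


def _term_columns(term: str, frame: ModelFrame, levels: list[str]) -> tuple[np.ndarray, list[str]]:
    d = frame.data
    parts = term.split(":")
    mat = np.ones((len(d), 1))
    names = [""]
    for part in parts:
        if part == "genotype":
            cols = np.column_stack(
                [(d["genotype"] == lv).to_numpy(float) for lv in levels[1:]]
            )
            sub = [f"genotype[{lv}]" for lv in levels[1:]]
        elif part in _NUMERIC_COLUMNS:
            cols = d[_NUMERIC_COLUMNS[part]].to_numpy(float)[:, None]
            sub = [part]
        else:
            raise ValueError(f"unknown term component {part!r}")
        mat = np.concatenate(
            [mat[:, [i]] * cols for i in range(mat.shape[1])], axis=1
        )
        names = [f"{a}:{b}".strip(":") for a in names for b in sub]
    return mat, names


def build_design(frame: ModelFrame, terms: Sequence[str]) -> tuple[np.ndarray, list[str], dict]:
    """Treatment-coded design matrix with an intercept; returns term → column slices."""
    levels = sorted(frame.data["genotype"].unique())
    X_parts = [np.ones((len(frame.data), 1))]
    names = ["intercept"]
    slices: dict[str, slice] = {}
    pos = 1
    for t in terms:
        mat, sub = _term_columns(t, frame, levels)
        X_parts.append(mat)
        names.extend(sub)
        slices[t] = slice(pos, pos + mat.shape[1])
        pos += mat.shape[1]
    return np.concatenate(X_parts, axis=1), names, slices


# ---------------------------------------------------------------------------
# marginal likelihood via adaptive Gauss-Hermite quadrature


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _log1pexp(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    big = x > 30
    out[big] = x[big]
    out[~big] = np.log1p(np.exp(x[~big]))
    return out


class _Marginal:
    """Marginal binomial log-likelihood with a per-group Gaussian intercept."""

    def __init__(self, X: np.ndarray, y: np.ndarray, m: np.ndarray,
                 groups: np.ndarray, n_quad: int = 11):
        self.X, self.y, self.m = X, y.astype(float), m.astype(float)
        self.groups = groups
        self.n_groups = int(groups.max()) + 1
        self.nodes, self.weights = hermgauss(n_quad)
        self.logw = np.log(self.weights)
        self.const = float(
            np.sum(special.gammaln(self.m + 1) - special.gammaln(self.y + 1)
                   - special.gammaln(self.m - self.y + 1))
        )

    def _cond_by_group(self, eta: np.ndarray) -> np.ndarray:
        ll = self.y * eta - self.m * _log1pexp(eta)
        return np.bincount(self.groups, weights=ll, minlength=self.n_groups)

    def loglik(self, params: np.ndarray) -> float:
        beta, sigma = params[:-1], params[-1]
        eta0 = self.X @ beta
        if sigma < 1e-6:
            return float(self._cond_by_group(eta0).sum()) + self.const
        # Laplace mode per group by Newton on the scalar intercept
        b = np.zeros(self.n_groups)
        for _ in range(50):
            eta = eta0 + b[self.groups]
            p = _sigmoid(eta)
            grad = (
                np.bincount(self.groups, weights=self.y - self.m * p,
                            minlength=self.n_groups)
                - b / sigma**2
            )
            hess = (
                -np.bincount(self.groups, weights=self.m * p * (1 - p),
                             minlength=self.n_groups)
                - 1.0 / sigma**2
            )
            step = grad / hess
            b -= step
            if np.max(np.abs(step)) < 1e-10:
                break
        scale = 1.0 / np.sqrt(-hess)
        # adaptive nodes b + sqrt(2)*scale*x_k
        logf = np.empty((len(self.nodes), self.n_groups))
        for k, x in enumerate(self.nodes):
            bk = b + np.sqrt(2.0) * scale * x
            eta = eta0 + bk[self.groups]
            logf[k] = (
                self._cond_by_group(eta)
                - bk**2 / (2 * sigma**2)
                + self.logw[k]
                + x**2
            )
        log_int = special.logsumexp(logf, axis=0) + np.log(np.sqrt(2.0) * scale)
        ll = log_int - 0.5 * np.log(2 * np.pi * sigma**2)
        return float(ll.sum()) + self.const

    def nll(self, params: np.ndarray) -> float:
        return -self.loglik(params)


def _numeric_hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    h = step * (1.0 + np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


@dataclass(frozen=True)
class HazardFit:
    """A fitted (possibly simplified) discrete-time hazard model."""

    terms: tuple[str, ...]
    coef: pd.Series                  # named fixed-effect coefficients
    se: pd.Series
    wald_p: pd.Series                # per coefficient
    term_p: pd.Series                # block Wald p per term (drop ordering)
    random_intercept_sd: float
    loglik: float
    aic: float
    n_quad: int
    converged: bool
    separation_flag: bool
    frame: ModelFrame
    term_slices: dict
    elimination_trail: tuple = ()
    cov: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return len(self.coef) + 1

    def predict_hazard(self, data: pd.DataFrame | None = None) -> np.ndarray:
        """Population-typical hazard (random intercept at zero) per frame row."""
        frame = self.frame if data is None else ModelFrame(data=data, scales=self.frame.scales)
        X, _, _ = build_design(frame, list(self.terms))
        return _sigmoid(X @ self.coef.to_numpy())

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "wald_p": self.wald_p}
        )


def fit_hazard(
    frame: ModelFrame,
    terms: Sequence[str] | None = None,
    *,
    n_quad: int = 11,
    max_iter: int = 500,
    tol: float = 1e-9,
    compute_se: bool = True,
) -> HazardFit:
    """Maximum-likelihood fit of the mixed binomial logistic hazard model.

    The group random intercept is integrated out with adaptive Gauss–Hermite
    quadrature (``n_quad`` nodes, centered and scaled at the per-group Laplace
    mode). Standard errors come from the observed information. A frame with a
    single group cannot identify the random-effect variance and is rejected.
    """
    if terms is None:
        terms = default_terms(include_genotype=frame.data["genotype"].nunique() > 1)
    terms = list(terms)
    d = frame.data
    if frame.n_groups < 2:
        raise ValueError("random-effect variance unidentifiable with a single group")
    X, names, slices = build_design(frame, terms)
    y = d["emerged"].to_numpy(float)
    m = d["at_risk"].to_numpy(float)
    groups = pd.factorize(d["group_id"])[0]
    marg = _Marginal(X, y, m, groups, n_quad=n_quad)

    # fixed-effects start values from an ordinary weighted logistic fit
    import statsmodels.api as sm

    glm = sm.GLM(np.column_stack([y, m - y]), X, family=sm.families.Binomial())
    try:
        beta0 = glm.fit(maxiter=100).params
    except Exception:
        beta0 = np.zeros(X.shape[1])
    x0 = np.append(beta0, 0.3)
    bounds = [(None, None)] * X.shape[1] + [(0.0, None)]
    res = optimize.minimize(
        marg.nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
    )
    if not res.success and np.linalg.norm(res.jac) > 1e-2:
        raise RuntimeError(
            f"hazard fit did not converge: |grad| = {np.linalg.norm(res.jac):.3g} "
            f"after {res.nit} iterations ({res.message})"
        )
    beta_hat, sigma_hat = res.x[:-1], float(res.x[-1])
    separation = bool(np.max(np.abs(beta_hat)) > 15)
    ll = -float(res.fun)
    k = X.shape[1] + 1
    cov = None
    se = np.full(X.shape[1], np.nan)
    if compute_se:
        H = _numeric_hessian(marg.nll, res.x)
        try:
            cov_full = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov_full = np.linalg.pinv(H)
        cov = cov_full[:-1, :-1]
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
    zs = beta_hat / np.where(se > 0, se, np.nan)
    wald_p = pd.Series(2 * stats.norm.sf(np.abs(zs)), index=names)
    term_p = {}
    if cov is not None:
        for t, sl in slices.items():
            c = beta_hat[sl]
            V = cov[sl, sl]
            try:
                w = float(c @ np.linalg.solve(V, c))
                term_p[t] = float(stats.chi2.sf(w, len(c)))
            except np.linalg.LinAlgError:
                term_p[t] = np.nan
    return HazardFit(
        terms=tuple(terms),
        coef=pd.Series(beta_hat, index=names),
        se=pd.Series(se, index=names),
        wald_p=wald_p,
        term_p=pd.Series(term_p),
        random_intercept_sd=sigma_hat,
        loglik=ll,
        aic=2 * k - 2 * ll,
        n_quad=n_quad,
        converged=bool(res.success),
        separation_flag=separation,
        frame=frame,
        term_slices=slices,
        cov=cov,
    )


def _removable_terms(terms: Sequence[str]) -> list[str]:
    """Terms droppable without violating marginality.

    An interaction is always droppable. A main effect is droppable only if no
    retained interaction contains it; ``hour`` is additionally protected while
    ``hour2`` is retained.
    """
    interactions = [t for t in terms if ":" in t]
    protected = {p for t in interactions for p in t.split(":")}
    if "hour2" in terms:
        protected.add("hour")
    out = []
    for t in terms:
        if ":" in t or t not in protected:
            out.append(t)
    return out


def backward_simplify(
    frame: ModelFrame,
    terms: Sequence[str] | None = None,
    alpha: float = 0.05,
    *,
    n_quad: int = 11,
    full_fit: HazardFit | None = None,
) -> HazardFit:
    """Backward model simplification with likelihood-ratio acceptance.

    At each step the removable term (respecting marginality) with the largest
    block Wald p is refit without; the drop is accepted when the
    likelihood-ratio comparison has p > ``alpha`` and the procedure stops the
    first time a drop would significantly worsen the model. Ties in Wald p go
    to the term later in the canonical ordering. The procedure is
    deterministic and invariant to the row order of the frame.
    """
    current = full_fit if full_fit is not None else fit_hazard(
        frame, terms, n_quad=n_quad
    )
    trail: list[tuple[str, float, float]] = []
    while True:
        removable = _removable_terms(current.terms)
        if not removable:
            break
        ps = current.term_p
        # later canonical position wins ties: iterate in order, >= keeps later
        best, best_p = None, -np.inf
        for t in current.terms:
            if t in removable and ps.get(t, np.nan) >= best_p:
                best, best_p = t, ps.get(t, np.nan)
        if best is None:
            break
        reduced_terms = [t for t in current.terms if t != best]
        reduced = fit_hazard(frame, reduced_terms, n_quad=n_quad)
        lr = 2 * (current.loglik - reduced.loglik)
        df = current.term_slices[best].stop - current.term_slices[best].start
        p = float(stats.chi2.sf(max(lr, 0.0), df))
        if p > alpha:
            trail.append((best, float(lr), p))
            current = reduced
        else:
            break
    from dataclasses import replace

    return replace(current, elimination_trail=tuple(trail))


def survival_curve(hazards) -> np.ndarray:
    """Daily survival S(T) = Π_{h<T} (1 − p_h); S at the first hour is 1.

    Given hazards for hours h = 1..H, returns S of length H+1 where S[0] = 1
    and S[T] is the probability of not having eclosed before hour T+1.
    """
    p = np.asarray(hazards, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("hazards must lie in [0, 1]")
    return np.concatenate([[1.0], np.cumprod(1.0 - p)])
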