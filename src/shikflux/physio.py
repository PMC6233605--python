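"""Logistic-growth physiology models for batch fermentations.

Biomass follows a logistic curve X(t); glucose consumption and shikimate
production are described by integrated two-rate models in which an
exponential-phase specific rate and a stationary-phase specific rate are
blended by the phase weights (1 - X/X_max) and (X/X_max).  Acetate, which is
produced, consumed and produced again during a typical run, is summarised by
two approximated specific rates obtained from early-phase linear regressions.

All specific rates q are expressed per unit biomass (g . gX^-1 . h^-1); the
model trajectories they generate are volumetric (g/L).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "TimeSeries",
    "PhysioParams",
    "FitStats",
    "logistic_biomass",
    "simulate_consumption",
    "simulate_production",
    "fit_physio",
    "acetate_rates",
    "estimate_yields",
    "fit_statistics",
]


@dataclass
class TimeSeries:
    """Sampled fermentation state: time (h) plus g/L concentrations."""

    times: np.ndarray
    biomass: np.ndarray
    glucose: np.ndarray
    shikimate: np.ndarray
    acetate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.biomass = np.asarray(self.biomass, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        self.shikimate = np.asarray(self.shikimate, dtype=float)
        if self.acetate is not None:
            self.acetate = np.asarray(self.acetate, dtype=float)
        n = len(self.times)
        for name in ("biomass", "glucose", "shikimate"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name!r} length != times length")
        if self.acetate is not None and len(self.acetate) != n:
            raise ValueError("channel 'acetate' length != times length")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        for name in ("biomass", "glucose", "shikimate", "acetate"):
            v = getattr(self, name)
            if v is not None and np.any(v < -1e-12):
                raise ValueError(f"negative concentrations in channel {name!r}")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class PhysioParams:
    """Parameter vector of the physiological models for one experiment.

    ``x0``/``x_max`` (g/L) and ``mu_max`` (1/h) parameterise the logistic
    biomass curve; the q's are phase-specific rates (g/gX/h); yields in g/g.
    """

    x0: float
    x_max: float
    mu_max: float
    q_glc_exp: float
    q_glc_sta: float
    q_sa_exp: float
    q_sa_sta: float
    q_ac_exp: float = 0.0
    q_ac_sta: float = 0.0
    y_ps: float = 0.0
    y_px: float = 0.0
    delta_glc: float = 0.0
    sa_final: float = 0.0
    ac_final: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.x0 < self.x_max):
            raise ValueError("require 0 < x0 < x_max")
        if self.mu_max <= 0:
            raise ValueError("mu_max must be positive")
        for name in ("q_glc_exp", "q_glc_sta", "q_sa_exp", "q_sa_sta",
                     "q_ac_exp", "q_ac_sta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhysioParams":
        keys = cls.__dataclass_fields__.keys()
        return cls(**{k: float(d[k]) for k in keys if k in d})


@dataclass
class FitStats:
    """Model-adequacy statistics for one channel.

    error_pct = 100*SSE/SSEP; r2 = squared Pearson coefficient of the
    model-vs-experiment regression; spd = slope percent deviation,
    100*|slope-1|; p_value from the regression t statistic (n-2 df).
    """

    sse: float
    error_pct: float
    r2: float
    spd: float
    p_value: float
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def logistic_biomass(t, x0: float, x_max: float, mu_max: float):
    """Logistic biomass curve X(t) = X0*exp(mu*t) / (1 - X0/Xmax*(1-exp(mu*t)))."""
    if not np.all(np.isfinite([x0, x_max, mu_max])):
        raise ValueError("non-finite logistic parameters")
    if x0 <= 0 or x0 > x_max:
        raise ValueError("require 0 < x0 <= x_max")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time")
    # algebraically identical to the exp(mu t) form but overflow-safe
    e = np.exp(-mu_max * t)
    out = x0 * x_max / (x_max * e + x0 * (1.0 - e))
    return out if out.ndim else float(out)


def _phase_integrals(params: PhysioParams, times: np.ndarray, dt: float):
    """Cumulative exponential- and stationary-phase loadings at sample times.

    Steps the discrete recursion on a fine grid of spacing dt and reads the
    two cumulative sums A(t) = sum X*dt*(1-X/Xmax) and B(t) = sum X*dt*(X/Xmax)
    at each requested time; any trajectory of the integrated models is then
    S0 -/+ (q_exp*A + q_sta*B).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t_end = float(times[-1])
    grid = np.arange(0.0, t_end + dt / 2, dt)
    x = logistic_biomass(grid, params.x0, params.x_max, params.mu_max)
    w_exp = 1.0 - x / params.x_max
    inc_a = x * dt * w_exp
    inc_b = x * dt * (1.0 - w_exp)
    cum_a = np.concatenate([[0.0], np.cumsum(inc_a[1:])])
    cum_b = np.concatenate([[0.0], np.cumsum(inc_b[1:])])
    a = np.interp(times, grid, cum_a)
    b = np.interp(times, grid, cum_b)
    return a, b


def simulate_consumption(params: PhysioParams, s0: float,
                         times: Sequence[float], dt: float = 0.01) -> np.ndarray:
    """Glucose trajectory of the integrated two-rate consumption model.

    S(t) = S(t-dt) - q_exp*X*dt*(1-X/Xmax) - q_sta*X*dt*(X/Xmax), clipped at 0.
    """
    if s0 < 0:
        raise ValueError("s0 must be nonnegative")
    if params.q_glc_exp < 0 or params.q_glc_sta < 0:
        raise ValueError("negative rates")
    times = np.asarray(times, dtype=float)
    a, b = _phase_integrals(params, times, dt)
    return np.clip(s0 - params.q_glc_exp * a - params.q_glc_sta * b, 0.0, None)


def simulate_production(params: PhysioParams, p0: float,
                        times: Sequence[float], dt: float = 0.01) -> np.ndarray:
    """Shikimate trajectory of the integrated two-rate production model."""
    if p0 < 0:
        raise ValueError("p0 must be nonnegative")
    if params.q_sa_exp < 0 or params.q_sa_sta < 0:
        raise ValueError("negative rates")
    times = np.asarray(times, dtype=float)
    a, b = _phase_integrals(params, times, dt)
    return p0 + params.q_sa_exp * a + params.q_sa_sta * b


def fit_statistics(model_values, experimental_values) -> FitStats:
    """Adequacy statistics of model values against paired experimental values."""
    m = np.asarray(model_values, dtype=float)
    e = np.asarray(experimental_values, dtype=float)
    if m.shape != e.shape:
        raise ValueError("model and experimental vectors must have equal length")
    n = len(e)
    if n < 3:
        raise ValueError("need at least 3 paired points")
    sse = float(np.sum((m - e) ** 2))
    ssep = float(np.sum(e ** 2))
    error_pct = 100.0 * sse / ssep if ssep > 0 else np.inf
    flags: list[str] = []
    if np.ptp(e) == 0 or np.ptp(m) == 0:
        return FitStats(sse=sse, error_pct=error_pct, r2=np.nan, spd=np.nan,
                        p_value=np.nan, flags=["zero-variance channel"])
    reg = stats.linregress(e, m)
    r2 = float(reg.rvalue ** 2)
    spd = 100.0 * abs(reg.slope - 1.0)
    p_value = float(reg.pvalue)
    return FitStats(sse=sse, error_pct=error_pct, r2=r2, spd=spd,
                    p_value=p_value, flags=flags)


def _fit_logistic(times: np.ndarray, biomass: np.ndarray, seed: int = 0,
                  n_starts: int = 5, fix_x0: float | None = None):
    """SSE-minimising logistic fit by multi-start Nelder-Mead simplex."""
    x_max0 = max(float(np.max(biomass)), 1e-3)
    x00 = max(float(biomass[0]), 0.01) if fix_x0 is None else fix_x0
    # crude slope heuristic for the growth-rate start
    pos = biomass > max(0.05 * x_max0, 1e-6)
    mu0 = 0.5
    if pos.sum() >= 2:
        grow = biomass[pos] < 0.8 * x_max0
        if grow.sum() >= 2:
            tt, xx = times[pos][grow], biomass[pos][grow]
            sl = np.polyfit(tt, np.log(xx), 1)[0]
            if np.isfinite(sl) and sl > 1e-3:
                mu0 = sl

    def unpack(z):
        if fix_x0 is None:
            return np.exp(z[0]), np.exp(z[1]), np.exp(z[2])
        return fix_x0, np.exp(z[0]), np.exp(z[1])

    def sse(z):
        x0, xm, mu = unpack(z)
        if x0 > xm or x0 < 0.01:
            return 1e12
        pred = logistic_biomass(times, x0, xm, mu)
        return float(np.sum((pred - biomass) ** 2))

    rng = np.random.default_rng(seed)
    base = (np.log([x00, x_max0, mu0]) if fix_x0 is None
            else np.log([x_max0, mu0]))
    best = None
    for k in range(n_starts):
        z0 = base if k == 0 else base + rng.normal(0, 0.3, size=base.size)
        res = optimize.minimize(sse, z0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 4000})
        cand = (res.fun, float(np.sum(res.x ** 2)), res.x)
        if best is None or cand[:2] < best[:2]:
            best = cand
    x0, xm, mu = unpack(best[2])
    return float(x0), float(xm), float(mu)


def _fit_two_rates(series_values: np.ndarray, c0: float, a: np.ndarray,
                   b: np.ndarray, sign: float, polish: bool = True):
    """Fit (q_exp, q_sta) of an integrated model; linear LSQ then simplex polish.

    sign = -1 for consumption, +1 for production.  The model is linear in the
    two rates, so the least-squares solution on the uncensored samples is
    exact; substrate points at the zero floor (post-depletion) are excluded
    from the linear solve and handled by the clipped model in the polish.
    """
    design = sign * np.column_stack([a, b])
    rhs = series_values - c0
    if sign < 0:
        floor = 1e-6 * max(c0, 1.0)
        mask = series_values > floor
        if mask.sum() < 3:
            mask = np.ones_like(series_values, dtype=bool)
    else:
        mask = np.ones_like(series_values, dtype=bool)
    coef, *_ = np.linalg.lstsq(design[mask], rhs[mask], rcond=None)
    coef = np.clip(coef, 0.0, None)
    if polish:
        def sse(z):
            q = np.exp(z)
            model = c0 + design @ q
            if sign < 0:
                model = np.clip(model, 0.0, None)
            return float(np.sum((model - series_values) ** 2))
        z0 = np.log(np.clip(coef, 1e-8, None))
        res = optimize.minimize(sse, z0, method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14})
        if res.fun <= sse(z0):
            coef = np.exp(res.x)
    return float(coef[0]), float(coef[1])


def fit_physio(series: TimeSeries, dt: float = 0.01, seed: int = 0,
               fit_acetate: bool = True,
               x0_fixed: float | None = None) -> tuple[PhysioParams, dict]:
    """Two-stage physiological fit: logistic biomass first, then the
    phase-blended glucose and shikimate rates by SSE against the integrated
    models with the logistic held fixed.

    Returns the fitted parameter vector and a dict of per-channel FitStats.
    """
    if len(series) < 6:
        raise ValueError("need at least 6 time points")
    times = series.times
    flags: list[str] = []
    x0, x_max, mu_max = _fit_logistic(times, series.biomass, seed=seed,
                                      fix_x0=x0_fixed)
    frac = series.biomass / max(x_max, 1e-9)
    if np.all(frac > 0.8):
        flags.append("all-stationary data; wide confidence")
    if np.all(frac < 0.8):
        flags.append("no stationary phase observed; wide confidence")

    shell = PhysioParams(x0=x0, x_max=x_max, mu_max=mu_max,
                         q_glc_exp=0, q_glc_sta=0, q_sa_exp=0, q_sa_sta=0)
    a, b = _phase_integrals(shell, times, dt)
    q_glc_exp, q_glc_sta = _fit_two_rates(series.glucose, series.glucose[0],
                                          a, b, sign=-1.0)
    q_sa_exp, q_sa_sta = _fit_two_rates(series.shikimate, series.shikimate[0],
                                        a, b, sign=+1.0)

    q_ac_exp = q_ac_sta = 0.0
    if fit_acetate and series.acetate is not None:
        try:
            q_ac_exp, q_ac_sta = acetate_rates(series, mu_max, x_max)
        except ValueError as exc:  # too few points in a phase window
            flags.append(f"acetate rates skipped: {exc}")

    params = PhysioParams(
        x0=x0, x_max=x_max, mu_max=mu_max,
        q_glc_exp=q_glc_exp, q_glc_sta=q_glc_sta,
        q_sa_exp=q_sa_exp, q_sa_sta=q_sa_sta,
        q_ac_exp=q_ac_exp, q_ac_sta=q_ac_sta,
    )
    glc_model = simulate_consumption(params, series.glucose[0], times, dt)
    sa_model = simulate_production(params, series.shikimate[0], times, dt)
    x_model = logistic_biomass(times, x0, x_max, mu_max)
    params.delta_glc = float(series.glucose[0] - glc_model[-1])
    params.sa_final = float(sa_model[-1])
    if series.acetate is not None:
        params.ac_final = float(series.acetate[-1])
    y_ps, y_px = estimate_yields(params, s0=series.glucose[0],
                                 p0=series.shikimate[0], t_end=times[-1], dt=dt)
    params.y_ps, params.y_px = y_ps, y_px

    stats_out = {
        "biomass": fit_statistics(x_model, series.biomass),
        "glucose": fit_statistics(glc_model, series.glucose),
        "shikimate": fit_statistics(sa_model, series.shikimate),
    }
    for st in stats_out.values():
        st.flags.extend(flags)
    return params, stats_out


def acetate_rates(series: TimeSeries, mu_max: float, x_max: float,
                  n_points: int = 3) -> tuple[float, float]:
    """Approximated acetate specific rates from early-phase regressions.

    q_ac_exp = mu_max * Y_ac/x where Y is the AC-vs-biomass regression slope
    over the first ``n_points`` exponential samples; q_ac_sta = Q_sta / X_max
    where Q_sta is the AC-vs-time slope over the first ``n_points`` stationary
    samples.
    """
    if series.acetate is None:
        raise ValueError("series has no acetate channel")
    frac = series.biomass / x_max
    exp_idx = np.where(frac < 0.5)[0]
    sta_idx = np.where(frac >= 0.95)[0]
    if len(exp_idx) < n_points:
        raise ValueError("fewer than 3 points in the early-exponential window")
    if len(sta_idx) < n_points:
        raise ValueError("fewer than 3 points in the early-stationary window")
    exp_idx = exp_idx[:n_points]
    sta_idx = sta_idx[:n_points]
    y_acx = stats.linregress(series.biomass[exp_idx],
                             series.acetate[exp_idx]).slope
    q_vol = stats.linregress(series.times[sta_idx],
                             series.acetate[sta_idx]).slope
    return max(mu_max * float(y_acx), 0.0), max(float(q_vol) / x_max, 0.0)


def estimate_yields(params: PhysioParams, s0: float, p0: float, t_end: float,
                    dt: float = 0.01,
                    y_px_definition: str = "dp_over_xmax") -> tuple[float, float]:
    """Product/substrate and product/biomass yields from the model curves.

    Y_ps = (P_final - P0)/(S0 - S_final) on the integrated model trajectories,
    evaluated at substrate exhaustion when that happens before t_end (the
    decoupled production model would otherwise keep producing without
    substrate).  Y_px is a configurable definition; the default divides the
    product formed by the maximum biomass.
    """
    grid = np.linspace(0.0, t_end, 361)
    s_traj = simulate_consumption(params, s0, grid, dt)
    depleted = np.flatnonzero(s_traj <= 0)
    t_stop = grid[depleted[0]] if len(depleted) else t_end
    times = np.array([0.0, max(t_stop, grid[1])])
    s_final = simulate_consumption(params, s0, times, dt)[-1]
    p_final = simulate_production(params, p0, times, dt)[-1]
    consumed = s0 - s_final
    dp = p_final - p0
    if dp == 0:
        return 0.0, 0.0
    if consumed <= 0:
        raise ValueError("zero substrate consumption; Y_ps undefined")
    y_ps = dp / consumed
    if y_px_definition == "dp_over_xmax":
        y_px = dp / params.x_max
    elif y_px_definition == "dp_over_dx":
        y_px = dp / max(params.x_max - params.x0, 1e-12)
    else:
        raise ValueError(f"unknown y_px definition {y_px_definition!r}")
    return float(y_ps), float(y_px)
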