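"""Synthetic fermentation data with the statistical structure the analysis assumes.

Emulates a 3x3 central composite design over initial glucose (75/100/125 g/L)
and yeast extract (15/30/45 g/L) with the central point in triplicate, the
batch sampling schedule (every 2 h to 12 h, then every 4 h to 36 h), and
multiplicative per-channel measurement noise.

The "truth" physiological parameter field is a smooth (quadratic) function of
the initial condition, anchored exactly at the central-point mean parameters
and encoding the qualitative response-surface trends of the study system:
maximum biomass increases with yeast extract, the exponential glucose uptake
rate has a saddle at (96, 37) g/L, the growth rate a minimum at (105, 21) g/L
and final shikimate a maximum at (110, 40) g/L.  Off-center coefficients are
fixture constants of this package, not measured values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .physio import PhysioParams, TimeSeries, logistic_biomass, \
    simulate_consumption, simulate_production

__all__ = [
    "DesignPoint",
    "NoiseSpec",
    "SamplingSchedule",
    "CENTRAL_POINT",
    "make_design_grid",
    "default_truth_params",
    "acetate_truth_curve",
    "simulate_experiment",
    "write_timeseries_csv",
    "read_timeseries_csv",
]

CENTRAL_POINT = (100.0, 30.0)

#: Table-style central-point anchor values (g/L, 1/h, g/gX/h, g/g).
CENTRAL_MEANS = {
    "x_max": 12.80, "delta_glc": 99.82, "sa_final": 32.80, "ac_final": 9.24,
    "mu_max": 0.58, "q_glc_exp": 1.24, "q_sa_exp": 0.35, "q_glc_sta": 0.45,
    "q_sa_sta": 0.13, "y_ps": 0.36, "y_px": 0.76, "q_ac_exp": 0.52,
    "q_ac_sta": 0.50,
}

_X0_DEFAULT = 0.25  # g/L inoculum, constant across the design


@dataclass(frozen=True)
class DesignPoint:
    """One experimental condition: initial GLC and YE (g/L) plus replicate index."""

    glc0: float
    ye0: float
    replicate: int = 1

    def __post_init__(self):
        if self.glc0 <= 0 or self.ye0 <= 0:
            raise ValueError("initial concentrations must be positive")
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative Gaussian noise: observed = truth * (1 + cv*eps), clipped at 0."""

    cv: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")


@dataclass(frozen=True)
class SamplingSchedule:
    """Strictly increasing sample times in hours."""

    times: tuple

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if len(t) == 0 or t[0] < 0:
            raise ValueError("schedule must start at t >= 0")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")

    @classmethod
    def default(cls, t_end: float = 36.0) -> "SamplingSchedule":
        """Every 2 h to 12 h, then every 4 h until t_end."""
        early = np.arange(0.0, 12.0 + 1e-9, 2.0)
        late = np.arange(16.0, t_end + 1e-9, 4.0)
        return cls(times=tuple(np.concatenate([early, late])))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)


def make_design_grid(glc_levels, ye_levels, central_replicates: int = 1):
    """Full factorial of the level lists with the central combination replicated.

    The central combination is the middle element of each (sorted) level list;
    total count is |glc|*|ye| + (central_replicates - 1).
    """
    if len(glc_levels) == 0 or len(ye_levels) == 0:
        raise ValueError("level lists must be non-empty")
    if any(g <= 0 for g in glc_levels) or any(y <= 0 for y in ye_levels):
        raise ValueError("levels must be positive")
    if central_replicates < 1:
        raise ValueError("central_replicates must be >= 1")
    gs = sorted(float(g) for g in glc_levels)
    ys = sorted(float(y) for y in ye_levels)
    central = (gs[len(gs) // 2], ys[len(ys) // 2])
    points = []
    for g in gs:
        for y in ys:
            reps = central_replicates if (g, y) == central else 1
            for r in range(1, reps + 1):
                points.append(DesignPoint(glc0=g, ye0=y, replicate=r))
    return points


def _field(g: float, y: float) -> dict:
    """Quadratic truth fields over (GLC0, YE0); anchored at the central means."""
    dg, dy = g - 100.0, y - 30.0
    return {
        "x_max": 12.80 + 0.12 * dy + 0.01 * dg - 2e-4 * dy ** 2,
        "mu_max": 0.56585 + 8e-5 * (g - 105.0) ** 2 + 1.5e-4 * (y - 21.0) ** 2,
        "q_glc_exp": 1.24 - 4.9e-4 * (g - 96.0) ** 2 + 1.6e-4 * (y - 37.0) ** 2,
        "q_sa_exp": 0.35 - 0.004 * dy - 5e-6 * dg ** 2,
        "q_glc_sta": 0.45 + 0.002 * dg + 0.003 * dy,
        "q_sa_sta": 0.13 - 8e-4 * dg + 1e-3 * dy,
        "q_ac_exp": 0.52 + 0.004 * dg + 0.006 * dy,
        "q_ac_sta": 0.50 + 0.003 * dg - 0.004 * dy,
        "delta_glc": 99.82 + 0.9 * dg + 0.25 * dy - 0.01 * dg * dy,
        "sa_final": 33.80 - 0.004 * (g - 110.0) ** 2 - 0.006 * (y - 40.0) ** 2,
        "ac_final": 9.24 + 0.15 * dg - 0.12 * dy,
        "y_ps": 0.36 - 1e-3 * dg + 5e-4 * dy,
        "y_px": 0.76,
    }


def default_truth_params(point: DesignPoint) -> PhysioParams:
    """Ground-truth physiological parameters at a design point.

    Defined on the design rectangle [75,125]x[15,45] g/L extended by 20% of
    each span; at the central point (100, 30) the values equal the
    central-point anchor means exactly.
    """
    g, y = point.glc0, point.ye0
    if not (65.0 <= g <= 135.0 and 9.0 <= y <= 51.0):
        raise ValueError(f"design point ({g}, {y}) outside the supported domain")
    f = _field(g, y)
    return PhysioParams(
        x0=_X0_DEFAULT, x_max=f["x_max"], mu_max=f["mu_max"],
        q_glc_exp=f["q_glc_exp"], q_glc_sta=f["q_glc_sta"],
        q_sa_exp=f["q_sa_exp"], q_sa_sta=f["q_sa_sta"],
        q_ac_exp=f["q_ac_exp"], q_ac_sta=f["q_ac_sta"],
        y_ps=f["y_ps"], y_px=f["y_px"], delta_glc=f["delta_glc"],
        sa_final=f["sa_final"], ac_final=f["ac_final"],
    )


def _phase_breakpoints(params: PhysioParams, t_end: float):
    """(t_mex, t_sta): second-derivative maximum of the logistic curve and
    stationary onset (X >= 0.95 X_max), both in hours."""
    # logistic: d2X/dt2 maximal at X/Xmax = 1/2 - sqrt(3)/6
    frac_mex = 0.5 - np.sqrt(3.0) / 6.0

    def t_at_frac(frac):
        x = frac * params.x_max
        # invert the logistic closed form
        return float(np.log(x * (params.x_max - params.x0)
                            / (params.x0 * (params.x_max - x))) / params.mu_max)

    t_mex = min(t_at_frac(frac_mex), t_end)
    t_sta = min(t_at_frac(0.95), t_end)
    return t_mex, t_sta


def acetate_truth_curve(params: PhysioParams, times: np.ndarray,
                        ac0: float = 0.0) -> np.ndarray:
    """Piecewise acetate profile: production during early growth, consumption
    until stationary onset, then renewed linear production.

    Early-exponential acetate tracks biomass with yield q_ac_exp/mu_max, so a
    regression of AC on X over that window recovers the construction; the
    stationary segment has volumetric slope q_ac_sta * X_max.
    """
    times = np.asarray(times, dtype=float)
    t_mex, t_sta = _phase_breakpoints(params, t_end=max(times[-1], 1.0))
    y_acx = params.q_ac_exp / params.mu_max
    x = logistic_biomass(times, params.x0, params.x_max, params.mu_max)
    x_mex = logistic_biomass(t_mex, params.x0, params.x_max, params.mu_max)
    ac_peak = ac0 + y_acx * (x_mex - params.x0)
    ac_low = 0.05 * ac_peak
    ac = np.empty_like(times)
    m1 = times <= t_mex
    ac[m1] = ac0 + y_acx * (x[m1] - params.x0)
    m2 = (times > t_mex) & (times < t_sta)
    span = max(t_sta - t_mex, 1e-9)
    ac[m2] = ac_peak + (ac_low - ac_peak) * (times[m2] - t_mex) / span
    m3 = times >= t_sta
    ac[m3] = ac_low + params.q_ac_sta * params.x_max * (times[m3] - t_sta)
    return np.clip(ac, 0.0, None)


def simulate_experiment(params: PhysioParams, schedule: SamplingSchedule,
                        noise: NoiseSpec, glc0: float | None = None,
                        dt: float = 0.01) -> TimeSeries:
    """Forward-simulate the physiological models at the schedule times and
    apply multiplicative measurement noise (same seed -> identical output)."""
    if noise.cv < 0:
        raise ValueError("cv must be nonnegative")
    t = schedule.as_array()
    s0 = params.delta_glc if glc0 is None else glc0
    x = logistic_biomass(t, params.x0, params.x_max, params.mu_max)
    glc = simulate_consumption(params, s0, t, dt)
    sa = simulate_production(params, 0.0, t, dt)
    ac = acetate_truth_curve(params, t)
    if noise.cv > 0:
        rng = np.random.default_rng(noise.seed)
        channels = []
        for truth in (x, glc, sa, ac):
            eps = rng.standard_normal(len(t))
            channels.append(np.clip(truth * (1.0 + noise.cv * eps), 0.0, None))
        x, glc, sa, ac = channels
    return TimeSeries(times=t, biomass=x, glucose=glc, shikimate=sa, acetate=ac)


CSV_HEADER = ["time_h", "biomass_gL", "glc_gL", "sa_gL", "ac_gL"]


def write_timeseries_csv(series: TimeSeries, path, point: DesignPoint | None = None,
                         seed: int | None = None,
                         truth: PhysioParams | None = None) -> None:
    """Write a series as CSV; optional JSON sidecar with provenance metadata."""
    path = Path(path)
    df = pd.DataFrame({
        "time_h": series.times, "biomass_gL": series.biomass,
        "glc_gL": series.glucose, "sa_gL": series.shikimate,
        "ac_gL": series.acetate if series.acetate is not None
        else np.full(len(series), np.nan),
    })
    df.to_csv(path, index=False)
    if point is not None or seed is not None or truth is not None:
        meta = {}
        if point is not None:
            meta["design_point"] = asdict(point)
        if seed is not None:
            meta["seed"] = seed
        if truth is not None:
            meta["truth_params"] = truth.to_dict()
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_timeseries_csv(path) -> TimeSeries:
    df = pd.read_csv(path)
    missing = [c for c in CSV_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    ac = df["ac_gL"].to_numpy()
    return TimeSeries(times=df["time_h"].to_numpy(),
                      biomass=df["biomass_gL"].to_numpy(),
                      glucose=df["glc_gL"].to_numpy(),
                      shikimate=df["sa_gL"].to_numpy(),
                      acetate=None if np.all(np.isnan(ac)) else ac)
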