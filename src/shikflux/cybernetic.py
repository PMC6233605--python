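"""Cybernetic dynamic metabolic flux model over reduced elementary-mode families.

Each elementary mode i carries a Michaelis-Menten uptake kinetic

    r_i = k_max,i * [GLC]/(K_m,i + [GLC]) * (1 + [AC]/K_I)^-1 * w_i

where the phase weight w_i is (1 - X/X_max) for the exponential (mixed
glucose + yeast-extract) family and X/X_max for the stationary (glucose-only)
family.  The realized specific glucose uptake through mode i is
q_i = e_i * v_i * r_i with e_i a relative enzyme level and v_i the cybernetic
activity variable; enzyme synthesis is allocated by the cybernetic variable
u_i.  Both are set each instant by the matching law over per-mode returns.

Extracellular balances follow the mode yield vectors (per mmol glucose
uptake):  dC/dt = sum_i y_C,i * q_i * X.  Glucose and acetate enter the rate
laws in mM; biomass in g/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .efm import ElementaryMode, EMFamily

__all__ = [
    "MOLAR_MASS_G_PER_MMOL",
    "CyberneticParams",
    "CyberneticModel",
    "Trajectory",
    "FluxSnapshot",
    "mode_rate",
    "matching_law",
    "integrate",
    "reconstruct_fluxes",
    "phase_times",
    "flux_surfaces",
]

#: g per mmol used to convert between model mmol units and g/L observables.
#: BIOMASS and YE are pseudo-species with fixture molar masses.
MOLAR_MASS_G_PER_MMOL = {
    "GLC": 0.18016, "SA": 0.17415, "AC": 0.06005,
    "BIOMASS": 0.130, "YE": 0.150,
}

#: carbon atoms carried per mmol of each external species (fixture values)
CARBON_PER_MMOL = {"GLC": 6.0, "SA": 7.0, "AC": 2.0, "BIOMASS": 5.29,
                   "YE": 6.0, "MAINT": 0.0}


@dataclass
class CyberneticParams:
    """Kinetic and regulatory constants of the cybernetic model.

    k_max in mmol GLC per gX per h, K_m and K_I_ac in mM.  alpha, beta and
    k_e are the constitutive synthesis, decay and inducible synthesis rates
    of the relative enzyme levels (1/h).
    """

    k_max: np.ndarray
    k_m: np.ndarray
    k_i_ac: float = 100.0
    alpha: float = 0.001
    beta: float = 0.05
    k_e: float = 1.0
    e0: np.ndarray | None = None
    x_max: float = 12.80

    def __post_init__(self):
        self.k_max = np.asarray(self.k_max, dtype=float)
        self.k_m = np.asarray(self.k_m, dtype=float)
        if self.k_max.shape != self.k_m.shape:
            raise ValueError("k_max and k_m must have equal length")
        if np.any(self.k_max < 0) or np.any(self.k_m <= 0):
            raise ValueError("kinetic constants must be positive (k_max >= 0)")
        if self.k_i_ac <= 0:
            raise ValueError("k_i_ac must be positive")
        if self.e0 is not None:
            self.e0 = np.asarray(self.e0, dtype=float)
            if np.any((self.e0 <= 0) | (self.e0 > 1)):
                raise ValueError("e0 entries must lie in (0, 1]")

    @property
    def n_modes(self) -> int:
        return len(self.k_max)


def default_e0(n_m: int, n_g: int) -> np.ndarray:
    """Initial relative enzyme levels: 0.95 for the first exponential-family
    mode, 0.5 for the remaining exponential modes, 0.1 for stationary modes."""
    e0 = np.concatenate([np.full(n_m, 0.5), np.full(n_g, 0.1)])
    if n_m:
        e0[0] = 0.95
    return e0


def mode_rate(glc_mm: float, ac_mm: float, x: float, k_max: float, k_m: float,
              k_i_ac: float, x_max: float, family: str) -> float:
    """Single-mode kinetic rate (Michaelis-Menten, acetate-inhibited, phase
    weighted); family 'M' weights by 1-X/Xmax, 'G' by X/Xmax."""
    if family not in ("M", "G"):
        raise ValueError("family must be 'M' or 'G'")
    frac = np.clip(x / x_max, 0.0, 1.0)
    w = (1.0 - frac) if family == "M" else frac
    monod = k_max * glc_mm / (k_m + glc_mm) if glc_mm > 0 else 0.0
    return monod / (1.0 + max(ac_mm, 0.0) / k_i_ac) * w


def matching_law(returns) -> tuple[np.ndarray, np.ndarray]:
    """Cybernetic allocation variables from nonnegative per-mode returns:
    u_i = p_i / sum(p), v_i = p_i / max(p); uniform u and unit v when all
    returns vanish."""
    p = np.asarray(returns, dtype=float)
    if np.any(p < 0):
        raise ValueError("returns must be nonnegative")
    total = p.sum()
    if total <= 0:
        m = len(p)
        return np.full(m, 1.0 / m), np.ones(m)
    return p / total, p / p.max()


@dataclass
class Trajectory:
    times: np.ndarray
    glc_mm: np.ndarray
    ac_mm: np.ndarray
    sa_mm: np.ndarray
    ye_mm: np.ndarray
    biomass: np.ndarray          # g/L
    e: np.ndarray                # (n_t, m)
    u: np.ndarray                # (n_t, m)
    v: np.ndarray                # (n_t, m)
    q: np.ndarray                # realized specific uptakes (n_t, m)

    def state_at(self, t: float) -> dict:
        def interp(arr):
            if arr.ndim == 1:
                return float(np.interp(t, self.times, arr))
            return np.array([np.interp(t, self.times, arr[:, j])
                             for j in range(arr.shape[1])])
        return {"glc_mm": interp(self.glc_mm), "ac_mm": interp(self.ac_mm),
                "sa_mm": interp(self.sa_mm), "ye_mm": interp(self.ye_mm),
                "biomass": interp(self.biomass), "e": interp(self.e),
                "q": interp(self.q)}


@dataclass
class FluxSnapshot:
    phase: str                      # IEx | MEx | MSt
    time: float
    fluxes: dict                    # reaction id -> mmol/gX/h
    percent: dict | None            # reaction id -> % of glucose uptake
    flags: list = field(default_factory=list)


class CyberneticModel:
    """Reduced-family cybernetic model bound to a metabolic network."""

    def __init__(self, network, families, params: CyberneticParams,
                 objective: str = "carbon"):
        self.network = network
        self.families = list(families)
        self.modes = [m for fam in self.families for m in fam.modes]
        self.phases = [fam.phase for fam in self.families for _ in fam.modes]
        if params.n_modes != len(self.modes):
            raise ValueError("params length != number of modes")
        self.params = params
        self.objective = objective
        # yield matrix on tracked externals, per mmol glucose uptake
        self._ext = ["GLC", "AC", "SA", "YE", "BIOMASS"]
        self.yields = np.array([[m.yields.get(e, 0.0) for e in self._ext]
                                for m in self.modes])  # (m, 5)
        self._is_m = np.array([ph == "M" for ph in self.phases])
        self._roi_weight = self._objective_weights(objective)

    def _objective_weights(self, objective: str) -> np.ndarray:
        if objective == "carbon":
            # total carbon uptake per mmol glucose through the mode
            w = np.zeros(len(self.modes))
            for i, m in enumerate(self.modes):
                up = 0.0
                for sp in ("GLC", "YE"):
                    y = m.yields.get(sp, 0.0)
                    if y < 0:
                        up += -y * CARBON_PER_MMOL[sp]
                w[i] = up
            return w
        if objective == "biomass":
            return np.clip(self.yields[:, self._ext.index("BIOMASS")], 0, None)
        if objective == "sa":
            return np.clip(self.yields[:, self._ext.index("SA")], 0, None)
        raise ValueError(f"unknown objective {objective!r}")

    # ---- instantaneous quantities ------------------------------------

    def kinetic_rates(self, glc_mm, ac_mm, x) -> np.ndarray:
        p = self.params
        frac = min(max(x / p.x_max, 0.0), 1.0)
        w = np.where(self._is_m, 1.0 - frac, frac)
        monod = p.k_max * glc_mm / (p.k_m + glc_mm) if glc_mm > 0 \
            else np.zeros(p.n_modes)
        return monod / (1.0 + max(ac_mm, 0.0) / p.k_i_ac) * w

    def allocation(self, e, r):
        returns = e * r * self._roi_weight
        return matching_law(returns)

    def _rhs(self, t, state):
        m = len(self.modes)
        glc, ac, sa, ye, x = state[:5]
        glc, ac, sa, ye = (max(glc, 0.0), max(ac, 0.0), max(sa, 0.0),
                           max(ye, 0.0))
        x = max(x, 1e-12)
        e = np.clip(state[5:5 + m], 1e-9, None)
        r = self.kinetic_rates(glc, ac, x)
        u, v = self.allocation(e, r)
        q = e * v * r  # mmol GLC / gX / h per mode
        if ye <= 0:  # mixed modes stall without yeast extract
            q = np.where(self._is_m, 0.0, q)
        rates = self.yields.T @ (q * x)  # per external, mM/h (biomass mmol/L/h)
        d_glc, d_ac, d_sa, d_ye, d_bio = rates
        mu = rates[4] * MOLAR_MASS_G_PER_MMOL["BIOMASS"] / x  # 1/h
        monod = glc / (self.params.k_m + glc) if glc > 0 else np.zeros(m)
        de = (self.params.alpha + self.params.k_e * u * monod
              - (self.params.beta + mu) * e)
        dx = mu * x
        return np.concatenate([[d_glc, d_ac, d_sa, d_ye, dx], de])

    # ---- integration --------------------------------------------------

    def simulate(self, initial: dict, t_end: float, n_out: int = 181,
                 method: str = "lsoda", dt: float = 0.05,
                 rtol: float = 1e-7, atol: float = 1e-9,
                 compute_allocation: bool = True) -> Trajectory:
        """Integrate the model from an initial state dict with keys
        glc_mm, ac_mm, sa_mm, ye_mm, biomass (and optional e).

        ``compute_allocation=False`` skips the per-output u/v/q history
        (cheaper inside fitting loops that only need the concentration
        channels)."""
        m = len(self.modes)
        e0 = initial.get("e")
        if e0 is None:
            e0 = self.params.e0 if self.params.e0 is not None \
                else default_e0(sum(1 for p in self.phases if p == "M"),
                                sum(1 for p in self.phases if p == "G"))
        y0 = np.concatenate([[initial["glc_mm"], initial.get("ac_mm", 0.0),
                              initial.get("sa_mm", 0.0), initial["ye_mm"],
                              initial["biomass"]], np.asarray(e0, dtype=float)])
        if np.any(y0[:5] < 0):
            raise ValueError("negative initial concentrations")
        t_eval = np.linspace(0.0, t_end, n_out)
        if method == "rk4":
            if _HAVE_NUMBA_SIM:
                n_steps = max(int(np.ceil(t_end / dt)), 1)
                p = self.params
                dense = _rk4_core(
                    y0, float(t_end), n_steps, p.k_max, p.k_m,
                    float(p.k_i_ac), float(p.x_max), float(p.alpha),
                    float(p.beta), float(p.k_e),
                    self._is_m.astype(np.bool_), self.yields,
                    self._roi_weight,
                    MOLAR_MASS_G_PER_MMOL["BIOMASS"])
                t_dense = np.linspace(0.0, t_end, n_steps + 1)
                ys = np.empty((len(t_eval), len(y0)))
                for j in range(len(y0)):
                    ys[:, j] = np.interp(t_eval, t_dense, dense[:, j])
            else:
                ys = _rk4(self._rhs, y0, t_eval, dt)
        else:
            sol = solve_ivp(self._rhs, (0.0, t_end), y0, method="LSODA",
                            t_eval=t_eval, rtol=rtol, atol=atol)
            if not sol.success:
                raise RuntimeError(f"integration failed: {sol.message}; "
                                   f"last state {sol.y[:, -1] if sol.y.size else y0}")
            ys = sol.y.T
        ys = np.clip(ys, 0.0, None)
        u_hist = np.zeros((len(t_eval), m))
        v_hist = np.zeros((len(t_eval), m))
        q_hist = np.zeros((len(t_eval), m))
        rows = enumerate(ys) if compute_allocation else ()
        for k, row in rows:
            glc, ac, sa, ye, x = row[:5]
            e = row[5:5 + m]
            r = self.kinetic_rates(glc, ac, max(x, 1e-12))
            u, v = self.allocation(np.clip(e, 1e-9, None), r)
            q = np.clip(e, 1e-9, None) * v * r
            if ye <= 0:
                q = np.where(self._is_m, 0.0, q)
            u_hist[k], v_hist[k], q_hist[k] = u, v, q
        return Trajectory(times=t_eval, glc_mm=ys[:, 0], ac_mm=ys[:, 1],
                          sa_mm=ys[:, 2], ye_mm=ys[:, 3], biomass=ys[:, 4],
                          e=ys[:, 5:5 + m], u=u_hist, v=v_hist, q=q_hist)

    def observed_channels(self, traj: Trajectory) -> dict:
        """Trajectory channels converted to the measurement units (g/L)."""
        mm = MOLAR_MASS_G_PER_MMOL
        return {"biomass": traj.biomass,
                "glucose": traj.glc_mm * mm["GLC"],
                "shikimate": traj.sa_mm * mm["SA"],
                "acetate": traj.ac_mm * mm["AC"]}


try:  # compiled fixed-step integrator used by the GA objective
    from numba import njit

    @njit(cache=True)
    def _rhs_core(yy, kmax, km, ki, xmax, alpha, beta, ke, is_m, yields,
                  roi_w, mbio):
        m = kmax.shape[0]
        nvar = 5 + m
        glc = max(yy[0], 0.0)
        ac = max(yy[1], 0.0)
        ye = max(yy[3], 0.0)
        x = max(yy[4], 1e-12)
        frac = x / xmax
        if frac > 1.0:
            frac = 1.0
        inhib = 1.0 / (1.0 + ac / ki)
        r = np.empty(m)
        p = np.empty(m)
        psum = 0.0
        pmax = 0.0
        for i in range(m):
            w = 1.0 - frac if is_m[i] else frac
            e_i = yy[5 + i]
            if e_i < 1e-9:
                e_i = 1e-9
            r[i] = kmax[i] * glc / (km[i] + glc) * inhib * w
            p[i] = e_i * r[i] * roi_w[i]
            psum += p[i]
            if p[i] > pmax:
                pmax = p[i]
        dydt = np.zeros(nvar)
        qx = np.empty(m)
        for i in range(m):
            e_i = yy[5 + i]
            if e_i < 1e-9:
                e_i = 1e-9
            v_i = p[i] / pmax if pmax > 0 else 1.0
            q_i = e_i * v_i * r[i]
            if ye <= 0.0 and is_m[i]:
                q_i = 0.0
            qx[i] = q_i * x
        for j in range(5):
            acc = 0.0
            for i in range(m):
                acc += yields[i, j] * qx[i]
            dydt[j] = acc
        mu = dydt[4] * mbio / x
        dydt[4] = mu * x
        for i in range(m):
            e_i = yy[5 + i]
            u_i = p[i] / psum if psum > 0 else 1.0 / m
            monod = glc / (km[i] + glc) if glc > 0 else 0.0
            dydt[5 + i] = alpha + ke * u_i * monod - (beta + mu) * e_i
        return dydt

    @njit(cache=True)
    def _rk4_core(y0, t_end, n_steps, kmax, km, ki, xmax, alpha, beta, ke,
                  is_m, yields, roi_w, mbio):
        nvar = y0.shape[0]
        h = t_end / n_steps
        out = np.empty((n_steps + 1, nvar))
        y = y0.copy()
        out[0] = y
        for step in range(n_steps):
            k1 = _rhs_core(y, kmax, km, ki, xmax, alpha, beta, ke, is_m,
                           yields, roi_w, mbio)
            k2 = _rhs_core(y + 0.5 * h * k1, kmax, km, ki, xmax, alpha, beta,
                           ke, is_m, yields, roi_w, mbio)
            k3 = _rhs_core(y + 0.5 * h * k2, kmax, km, ki, xmax, alpha, beta,
                           ke, is_m, yields, roi_w, mbio)
            k4 = _rhs_core(y + h * k3, kmax, km, ki, xmax, alpha, beta, ke,
                           is_m, yields, roi_w, mbio)
            y = y + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            for j in range(nvar):
                if y[j] < 0.0:
                    y[j] = 0.0
            out[step + 1] = y
        return out

    _HAVE_NUMBA_SIM = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA_SIM = False


def _rk4(rhs, y0, t_eval, dt):
    """Fixed-step RK4 with nonnegativity clipping, sampled at t_eval."""
    t0, t1 = t_eval[0], t_eval[-1]
    n_steps = max(int(np.ceil((t1 - t0) / dt)), 1)
    h = (t1 - t0) / n_steps
    ts = np.empty(n_steps + 1)
    ys = np.empty((n_steps + 1, len(y0)))
    t, y = t0, np.asarray(y0, dtype=float)
    ts[0], ys[0] = t, y
    for k in range(n_steps):
        k1 = rhs(t, y)
        k2 = rhs(t + h / 2, y + h / 2 * k1)
        k3 = rhs(t + h / 2, y + h / 2 * k2)
        k4 = rhs(t + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        y = np.clip(y, 0.0, None)
        t = t0 + (k + 1) * h
        ts[k + 1], ys[k + 1] = t, y
    out = np.empty((len(t_eval), len(y0)))
    for j in range(len(y0)):
        out[:, j] = np.interp(t_eval, ts, ys[:, j])
    return out


def integrate(network, families, params: CyberneticParams, initial: dict,
              t_end: float, **kw) -> Trajectory:
    """Convenience wrapper: build a CyberneticModel and simulate."""
    return CyberneticModel(network, families, params).simulate(
        initial, t_end, **kw)


def reconstruct_fluxes(model: CyberneticModel, traj: Trajectory, t: float,
                       phase: str = "") -> FluxSnapshot:
    """Reaction-level fluxes at time t: flux_j = sum_i z_ji * q_i with z the
    mode's per-reaction weights; percent normalized to glucose uptake."""
    if not (traj.times[0] <= t <= traj.times[-1]):
        raise ValueError("t outside trajectory span")
    st = traj.state_at(t)
    q = st["q"]
    fluxes: dict = {}
    for qi, mode in zip(q, model.modes):
        for rid, w in mode.net_flux.items():
            fluxes[rid] = fluxes.get(rid, 0.0) + w * qi
    glc_flux = 0.0
    for rid, v in fluxes.items():
        c = model.network.reaction(rid).stoichiometry.get("GLC", 0.0)
        if c * v < 0:
            glc_flux += -c * v
    flags = []
    if glc_flux <= 1e-12:
        percent = None
        flags.append("zero glucose uptake; percent undefined")
    else:
        percent = {rid: 100.0 * v / glc_flux for rid, v in fluxes.items()}
    return FluxSnapshot(phase=phase, time=float(t), fluxes=fluxes,
                        percent=percent, flags=flags)


def phase_times(times, biomass, x_max: float | None = None,
                stationary_frac: float = 0.95) -> dict:
    """Characteristic snapshot times of a growth trajectory.

    MEx is the maximum of the second time derivative of biomass, IEx is
    MEx/2, and MSt is the midpoint between stationary onset (biomass >=
    stationary_frac * X_max) and the end of the run.
    """
    times = np.asarray(times, dtype=float)
    x = np.asarray(biomass, dtype=float)
    if x_max is None:
        x_max = float(x.max())
    d1 = np.gradient(x, times)
    d2 = np.gradient(d1, times)
    # restrict to the growth phase to avoid numerical edge artifacts
    grow = x < 0.9 * x_max
    cand = np.flatnonzero(grow)
    if len(cand) == 0:
        cand = np.arange(len(times))
    mex = float(times[cand[np.argmax(d2[cand])]])
    out = {"IEx": mex / 2.0, "MEx": mex, "MSt": None, "flags": []}
    onset = np.flatnonzero(x >= stationary_frac * x_max)
    if len(onset) == 0:
        out["flags"].append("no stationary phase reached; MSt undefined")
    else:
        t_on = float(times[onset[0]])
        out["MSt"] = (t_on + float(times[-1])) / 2.0
    return out


def flux_surfaces(snapshots: dict, phase: str, reaction_ids=None):
    """Per-reaction response surfaces of percent flux over the design grid.

    ``snapshots`` maps (glc0, ye0) -> FluxSnapshot for the given phase.
    Returns {reaction_id: (QuadraticSurface, FitStats)}.
    """
    from .surface import fit_surface

    if len(snapshots) < 6:
        raise ValueError("need snapshots at >= 6 design points")
    if reaction_ids is None:
        reaction_ids = sorted({rid for snap in snapshots.values()
                               if snap.percent
                               for rid in snap.percent})
    out = {}
    for rid in reaction_ids:
        pts = [((g, y), snap.percent.get(rid, 0.0))
               for (g, y), snap in snapshots.items() if snap.percent]
        out[rid] = fit_surface(pts, parameter_name=f"{rid}@{phase}")
    return out
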