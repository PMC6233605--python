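"""End-to-end orchestration: physiology fits -> response surfaces -> EFM
families -> cybernetic GA fits -> flux snapshots/surfaces, plus the
model-guided pseudo-exponential fed-batch feed design.

All stages are deterministic under a fixed seed; artifacts are plain CSV or
JSON files written under one run directory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth, physio, surface, efm, cybernetic, ga
from .network import MetabolicNetwork, load_fixture_network

__all__ = [
    "RunConfig",
    "FeedProfile",
    "run_physio_pipeline",
    "run_flux_pipeline",
    "design_feed",
    "central_yield_targets",
    "write_params_json",
    "read_params_json",
    "write_modes_tsv",
    "read_modes_tsv",
    "write_surfaces_json",
]

#: Table-1 style parameter names whose response surfaces the pipeline builds.
SURFACE_PARAMS = ("x_max", "delta_glc", "sa_final", "ac_final", "mu_max",
                  "q_glc_exp", "q_sa_exp", "q_glc_sta", "q_sa_sta",
                  "q_ac_exp", "q_ac_sta")

#: Held-out validation conditions (GLC0, YE0) in g/L.
VALIDATION_POINTS = ((75.0, 20.0), (80.0, 40.0), (115.0, 45.0))


@dataclass
class RunConfig:
    glc_levels: tuple = (75.0, 100.0, 125.0)
    ye_levels: tuple = (15.0, 30.0, 45.0)
    central_replicates: int = 3
    cv: float = 0.05
    seed: int = 0
    t_end: float = 36.0
    dt: float = 0.01
    out_dir: str | None = None
    # flux-stage knobs
    m_family_size: int = 6
    g_family_size: int = 3
    ga_config: ga.GAConfig | None = None
    sim_dt: float = 0.1


# ---------------------------------------------------------------------------
# physiology + surfaces


def run_physio_pipeline(config: RunConfig) -> dict:
    """Simulate (or load) the design fermentations, fit each experiment,
    build one response surface per parameter and validate at held-out points.
    """
    points = synth.make_design_grid(config.glc_levels, config.ye_levels,
                                    config.central_replicates)
    schedule = synth.SamplingSchedule.default(config.t_end)
    records, failures = [], []
    for k, pt in enumerate(points):
        truth = synth.default_truth_params(pt)
        noise = synth.NoiseSpec(cv=config.cv, seed=config.seed * 1009 + k)
        series = synth.simulate_experiment(truth, schedule, noise,
                                           glc0=pt.glc0)
        try:
            params, stats = physio.fit_physio(series, dt=config.dt,
                                              seed=config.seed)
        except ValueError as exc:
            failures.append({"point": asdict(pt), "error": str(exc)})
            continue
        records.append({"point": pt, "params": params, "stats": stats,
                        "series": series})
    if len(records) < 6:
        raise RuntimeError(f"only {len(records)} successful fits (< 6); "
                           f"failures: {failures}")

    surfaces, surf_stats = {}, {}
    for name in SURFACE_PARAMS:
        pts = [((r["point"].glc0, r["point"].ye0),
                getattr(r["params"], name)) for r in records]
        surfaces[name], surf_stats[name] = surface.fit_surface(
            pts, parameter_name=name)
    criticals = {name: surface.critical_point(s)
                 for name, s in surfaces.items()}

    # central-point replicate spread drives the validation t tests
    central = [r for r in records
               if (r["point"].glc0, r["point"].ye0) == synth.CENTRAL_POINT]
    sigma = {name: float(np.std([getattr(r["params"], name) for r in central],
                                ddof=1)) if len(central) > 1 else np.nan
             for name in SURFACE_PARAMS}

    validation = []
    for (g, y) in VALIDATION_POINTS:
        truth = synth.default_truth_params(synth.DesignPoint(g, y))
        noise = synth.NoiseSpec(cv=config.cv,
                                seed=config.seed * 7919 + int(g * 100 + y))
        series = synth.simulate_experiment(truth, schedule, noise, glc0=g)
        fitted, _ = physio.fit_physio(series, dt=config.dt, seed=config.seed)
        preds, flags = surface.predict_params(surfaces, g, y)
        comp = {}
        for name in SURFACE_PARAMS:
            obs = getattr(fitted, name)
            pred = preds[name]
            p_val = (surface.compare_ttest(pred, obs, sigma[name],
                                           n=len(central))
                     if sigma.get(name, 0) > 0 else np.nan)
            comp[name] = {"observed": obs, "predicted": pred,
                          "p_value": p_val,
                          "similar": bool(p_val > 0.05)
                          if np.isfinite(p_val) else None}
        validation.append({"point": (g, y), "comparison": comp,
                           "flags": flags})

    result = {"records": records, "surfaces": surfaces,
              "surface_stats": surf_stats, "critical_points": criticals,
              "sigma_central": sigma, "validation": validation,
              "failures": failures, "seed": config.seed}
    if config.out_dir:
        _write_physio_outputs(result, Path(config.out_dir))
    return result


def _write_physio_outputs(result: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in result["records"]:
        row = {"glc0": r["point"].glc0, "ye0": r["point"].ye0,
               "replicate": r["point"].replicate}
        row.update(r["params"].to_dict())
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "physio_params.csv", index=False)
    write_surfaces_json(result["surfaces"], out / "surfaces.json",
                        stats=result["surface_stats"])
    crit = {name: {"location": cp.location, "kind": cp.kind,
                   "value": cp.value, "in_domain": cp.in_domain}
            for name, cp in result["critical_points"].items()}
    (out / "critical_points.json").write_text(json.dumps(crit, indent=1))
    (out / "validation.json").write_text(
        json.dumps(result["validation"], indent=1, default=float))


# ---------------------------------------------------------------------------
# flux stage


def central_yield_targets(params: physio.PhysioParams) -> dict:
    """Observed yield targets per mmol glucose for both families, from the
    central-point physiological rates (mass ratios converted to mol/mol)."""
    mm = cybernetic.MOLAR_MASS_G_PER_MMOL
    g = mm["GLC"]

    def per_glc(q, species):
        return q / max(params.q_glc_exp, 1e-9) * g / mm[species]

    def per_glc_sta(q, species):
        return q / max(params.q_glc_sta, 1e-9) * g / mm[species]

    target_m = {"BIOMASS": params.mu_max / max(params.q_glc_exp, 1e-9)
                * g / mm["BIOMASS"],
                "SA": per_glc(params.q_sa_exp, "SA"),
                "AC": per_glc(params.q_ac_exp, "AC")}
    target_g = {"BIOMASS": 0.0,
                "SA": per_glc_sta(params.q_sa_sta, "SA"),
                "AC": per_glc_sta(params.q_ac_sta, "AC")}
    return {"M": target_m, "G": target_g}


def build_reduced_families(network: MetabolicNetwork, targets: dict,
                           dims=("BIOMASS", "SA", "AC"),
                           m_family_size: int = 6, g_family_size: int = 3,
                           modes=None) -> dict:
    """Enumerate -> select families -> hull-reduce (projecting infeasible
    targets) -> expand each family to its configured model size."""
    if modes is None:
        modes = efm.enumerate_efms(network)
    sizes = {"M": m_family_size, "G": g_family_size}
    out = {"n_modes": len(modes), "projected": {}}
    families = {}
    for phase in ("M", "G"):
        fam = efm.select_family(modes, phase)
        tgt, projected = efm.project_to_hull(fam, targets[phase], dims)
        out["projected"][phase] = projected
        reduced = efm.reduce_by_yield_hull(fam, tgt, dims=dims)
        if sizes[phase] > len(reduced):
            expanded = efm.expand_family(fam, reduced, sizes[phase], dims)
        else:
            expanded = reduced
        families[phase] = {"full": fam, "reduced": reduced,
                           "model": expanded}
    out["families"] = families
    out["modes"] = modes
    return out


def fit_cybernetic_experiment(network, families, series: physio.TimeSeries,
                              params: physio.PhysioParams,
                              glc0: float, ye0: float,
                              config: RunConfig) -> dict:
    """GA fit of per-mode kinetic constants against one experiment."""
    fam_m = families["M"]["model"]
    fam_g = families["G"]["model"]
    n_m, n_g = len(fam_m), len(fam_g)
    m = n_m + n_g
    e0 = cybernetic.default_e0(n_m, n_g)
    mm = cybernetic.MOLAR_MASS_G_PER_MMOL
    init = {"glc_mm": glc0 / mm["GLC"], "ye_mm": ye0 / mm["YE"],
            "biomass": params.x0,
            "sa_mm": float(series.shikimate[0]) / mm["SA"],
            "ac_mm": (float(series.acetate[0]) / mm["AC"]
                      if series.acetate is not None else 0.0)}
    t_end = float(series.times[-1])
    data = {"biomass": series.biomass, "glucose": series.glucose,
            "shikimate": series.shikimate}
    if series.acetate is not None:
        data["acetate"] = series.acetate

    def channels_of(theta):
        p = cybernetic.CyberneticParams(
            k_max=theta[:m], k_m=theta[m:], x_max=params.x_max, e0=e0)
        model = cybernetic.CyberneticModel(network, [fam_m, fam_g], p)
        traj = model.simulate(init, t_end, n_out=73, method="rk4",
                              dt=config.sim_dt, compute_allocation=False)
        ch = model.observed_channels(traj)
        return {k: np.interp(series.times, traj.times, v)
                for k, v in ch.items() if k in data}

    objective = ga.sse_objective(channels_of, data)
    cfg = config.ga_config or ga.GAConfig(seed=config.seed)
    theta, trace = ga.run_ga(objective, m, cfg)
    p = cybernetic.CyberneticParams(k_max=theta[:m], k_m=theta[m:],
                                    x_max=params.x_max, e0=e0)
    model = cybernetic.CyberneticModel(network, [fam_m, fam_g], p)
    traj = model.simulate(init, t_end, n_out=181, method="rk4",
                          dt=config.sim_dt / 2)
    return {"theta": theta, "trace": trace, "model": model, "traj": traj,
            "init": init}


def run_flux_pipeline(config: RunConfig, physio_result: dict | None = None,
                      network: MetabolicNetwork | None = None,
                      experiments: list | None = None,
                      modes: list | None = None) -> dict:
    """Flux stage over the design: reduced families, per-experiment GA fits,
    IEx/MEx/MSt snapshots and per-reaction flux surfaces.

    ``experiments`` restricts the fitted subset (list of record indices);
    surfaces need at least 6 fitted design points.
    """
    network = network or load_fixture_network()
    physio_result = physio_result or run_physio_pipeline(config)
    records = physio_result["records"]
    central = [r for r in records
               if (r["point"].glc0, r["point"].ye0) == synth.CENTRAL_POINT]
    targets = central_yield_targets(central[0]["params"])
    fam_info = build_reduced_families(network, targets,
                                      m_family_size=config.m_family_size,
                                      g_family_size=config.g_family_size,
                                      modes=modes)
    chosen = experiments if experiments is not None else range(len(records))
    fits, snapshots = {}, {"IEx": {}, "MEx": {}, "MSt": {}}
    for idx in chosen:
        rec = records[idx]
        pt = rec["point"]
        fit = fit_cybernetic_experiment(
            network, fam_info["families"], rec["series"], rec["params"],
            pt.glc0, pt.ye0, config)
        fits[(pt.glc0, pt.ye0, pt.replicate)] = fit
        # onset relative to the trajectory's own plateau: the fitted model
        # may approach its ceiling more slowly than the logistic fit
        times = cybernetic.phase_times(fit["traj"].times,
                                       fit["traj"].biomass)
        for phase in ("IEx", "MEx", "MSt"):
            t = times[phase]
            if t is None:
                continue
            snap = cybernetic.reconstruct_fluxes(fit["model"], fit["traj"],
                                                 t, phase=phase)
            snapshots[phase][(pt.glc0, pt.ye0)] = snap
    flux_surf = {}
    for phase, snaps in snapshots.items():
        if len(snaps) >= 6:
            flux_surf[phase] = cybernetic.flux_surfaces(snaps, phase)
    return {"families": fam_info, "fits": fits, "snapshots": snapshots,
            "flux_surfaces": flux_surf,
            "reduced_sizes": {p: len(fam_info["families"][p]["reduced"])
                              for p in ("M", "G")},
            "model_sizes": {p: len(fam_info["families"][p]["model"])
                            for p in ("M", "G")}}


# ---------------------------------------------------------------------------
# fed-batch feed design


@dataclass
class FeedProfile:
    times: np.ndarray          # h, one entry per hold interval start
    rate_glc: np.ndarray       # L/h
    rate_ye: np.ndarray        # L/h
    feed_conc: tuple           # (GLC, YE) g/L in the two feed solutions
    setpoints: tuple           # (GLC, YE) g/L
    window: tuple              # (start, stop) h
    trajectory: pd.DataFrame | None = None
    mass_balance_error: float = np.nan


def design_feed(setpoints: tuple, feed_conc: tuple,
                params: physio.PhysioParams, window: tuple = (3.0, 18.0),
                interval: float = 0.25, v0: float = 0.5, t_end: float = 24.0,
                ye_per_biomass: float = 2.3, feedback: bool = False,
                feedback_tau: float = 1.0,
                sim_dt: float = 0.005) -> FeedProfile:
    """Open-loop pseudo-exponential feed holding both substrates near their
    setpoints.

    Every ``interval`` hours the two pump rates are recomputed as
    F_s = q_s * X * V / (C_feed,s - C_set,s) from the physiological model
    (zero-order hold in between), with q_s * X evaluated as the model's
    average consumption rate over the upcoming hold so the tank returns to
    the setpoint at every interval boundary under model-perfect operation.
    Yeast extract demand is approximated as ``ye_per_biomass`` grams YE per
    gram of new biomass.  With ``feedback`` enabled, each hold additionally
    corrects the measured setpoint deviation over ``feedback_tau`` hours
    (mimicking manual rate adjustment from samples); open-loop operation
    accumulates the pre-window deficit and the cross-dilution by the other
    feed.  The returned profile includes the simulated tank trajectory and
    the closing mass-balance error.
    """
    c_set_glc, c_set_ye = setpoints
    c_feed_glc, c_feed_ye = feed_conc
    if c_feed_glc <= c_set_glc or c_feed_ye <= c_set_ye:
        raise ValueError("feed concentration must exceed the setpoint")
    t0, t1 = window
    if not (0 <= t0 < t1 <= t_end):
        raise ValueError("feed window must lie within the simulation span")
    n_holds = int(round((t1 - t0) / interval))
    hold_times = t0 + interval * np.arange(n_holds)

    def q_glc(x):
        frac = min(x / params.x_max, 1.0)
        return params.q_glc_exp * (1 - frac) + params.q_glc_sta * frac

    grid = np.arange(0.0, t_end + sim_dt / 2, sim_dt)
    x_curve = physio.logistic_biomass(grid, params.x0, params.x_max,
                                      params.mu_max)
    mu_curve = np.gradient(x_curve, grid) / np.clip(x_curve, 1e-9, None)
    q_glc_curve = np.array([q_glc(x) for x in x_curve])

    v = v0
    m_glc = c_set_glc * v0   # grams in tank
    m_ye = c_set_ye * v0
    fed_glc = fed_ye = 0.0
    cons_glc = cons_ye = 0.0
    rate_g = np.zeros(n_holds)
    rate_y = np.zeros(n_holds)
    rows = []
    f_g = f_y = 0.0
    hold_idx = -1
    for k, t in enumerate(grid[:-1]):
        x = x_curve[k]
        mu = max(mu_curve[k], 0.0)
        nxt = np.searchsorted(hold_times, t + 1e-12, side="right") - 1
        if 0 <= nxt < n_holds and nxt != hold_idx:
            hold_idx = nxt
            # average model consumption over the upcoming hold interval
            sel = (grid >= t) & (grid < t + interval)
            qx_avg = float(np.mean(q_glc_curve[sel] * x_curve[sel])) \
                if sel.any() else q_glc(x) * x
            mux_avg = float(np.mean(np.clip(mu_curve[sel], 0, None)
                                    * x_curve[sel])) if sel.any() else mu * x
            f_g = qx_avg * v / (c_feed_glc - c_set_glc)
            f_y = ye_per_biomass * mux_avg * v / (c_feed_ye - c_set_ye)
            if feedback:
                f_g += (c_set_glc - m_glc / v) * v / (
                    (c_feed_glc - c_set_glc) * feedback_tau)
                f_y += (c_set_ye - m_ye / v) * v / (
                    (c_feed_ye - c_set_ye) * feedback_tau)
                f_g, f_y = max(f_g, 0.0), max(f_y, 0.0)
            rate_g[hold_idx], rate_y[hold_idx] = f_g, f_y
        if not (t0 <= t < t1):
            f_g = f_y = 0.0
        dm_glc_cons = q_glc(x) * x * v * sim_dt
        dm_ye_cons = ye_per_biomass * mu * x * v * sim_dt
        m_glc = max(m_glc + f_g * c_feed_glc * sim_dt - dm_glc_cons, 0.0)
        m_ye = max(m_ye + f_y * c_feed_ye * sim_dt - dm_ye_cons, 0.0)
        cons_glc += dm_glc_cons
        cons_ye += dm_ye_cons
        fed_glc += f_g * c_feed_glc * sim_dt
        fed_ye += f_y * c_feed_ye * sim_dt
        v += (f_g + f_y) * sim_dt
        rows.append((t + sim_dt, v, m_glc / v, m_ye / v, x))
    traj = pd.DataFrame(rows, columns=["time_h", "volume_L", "glc_gL",
                                       "ye_gL", "biomass_gL"])
    balance = abs((c_set_glc * v0 + fed_glc) - (cons_glc + m_glc))
    scale = max(c_set_glc * v0 + fed_glc, 1e-9)
    return FeedProfile(times=hold_times, rate_glc=rate_g, rate_ye=rate_y,
                       feed_conc=feed_conc, setpoints=setpoints,
                       window=window, trajectory=traj,
                       mass_balance_error=balance / scale)


# ---------------------------------------------------------------------------
# io helpers


def write_params_json(params: physio.PhysioParams, path,
                      stats: dict | None = None) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=1))
    if stats is not None:
        Path(path).with_suffix(".stats.json").write_text(json.dumps(
            {k: v.to_dict() for k, v in stats.items()}, indent=1,
            default=float))


def read_params_json(path) -> physio.PhysioParams:
    return physio.PhysioParams.from_dict(json.loads(Path(path).read_text()))


def write_modes_tsv(modes, network, path) -> None:
    """Mode x reaction net-flux table plus a sibling yields TSV."""
    rids = network.reaction_ids
    rows = [[m.net_flux.get(r, 0.0) for r in rids] for m in modes]
    df = pd.DataFrame(rows, columns=rids)
    df.insert(0, "mode", [m.index for m in modes])
    df.to_csv(path, sep="\t", index=False)
    ext = [mt.id for mt in network.external_metabolites]
    ydf = pd.DataFrame([[m.yields.get(e, 0.0) for e in ext] for m in modes],
                       columns=ext)
    ydf.insert(0, "mode", [m.index for m in modes])
    ydf.to_csv(Path(path).with_suffix(".yields.tsv"), sep="\t", index=False)


def read_modes_tsv(path, network) -> list:
    df = pd.read_csv(path, sep="\t")
    ypath = Path(path).with_suffix(".yields.tsv")
    ydf = pd.read_csv(ypath, sep="\t") if ypath.exists() else None
    ext = [mt.id for mt in network.external_metabolites]
    modes = []
    for k, row in df.iterrows():
        net = {c: float(row[c]) for c in df.columns
               if c != "mode" and abs(float(row[c])) > 1e-12}
        if ydf is not None:
            yields = {e: float(ydf.iloc[k][e]) for e in ext}
        else:
            yields = efm._mode_yields(network, net, ext)
        modes.append(efm.ElementaryMode(net_flux=net, yields=yields,
                                        support=frozenset(net),
                                        index=int(row["mode"])))
    return modes


def write_surfaces_json(surfaces: dict, path, stats: dict | None = None):
    payload = {}
    for name, s in surfaces.items():
        payload[name] = {"coefficients": s.coefficients.tolist(),
                         "domain": s.domain}
        if stats and name in stats:
            payload[name]["stats"] = stats[name].to_dict()
    Path(path).write_text(json.dumps(payload, indent=1, default=float))
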