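"""Genetic-algorithm estimation of per-mode Michaelis-Menten constants.

Each generation perturbs one parameter at a time of the incumbent set (one
candidate per k_max and per K_m of every mode, so 2m candidates; 18 for a
nine-mode model), refines every candidate with a bounded derivative-free
SSE minimization capped at a fixed number of objective evaluations, then
crosses the best candidate with the runner-up by copying the runner-up's
perturbed parameter into the best set.  Cycling stops when the best SSE
plateaus, after which a final unconstrained-length polish is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .cybernetic import CyberneticModel, CyberneticParams

__all__ = [
    "GAConfig",
    "GATrace",
    "Candidate",
    "perturb_generation",
    "local_refine",
    "crossover",
    "run_ga",
    "sse_objective",
]


@dataclass
class GAConfig:
    kmax_init: float = 1.0
    km_init: float = 10.0
    local_steps: int = 200
    max_cycles: int = 20
    plateau_tol: float = 1e-3
    sse_floor: float = 1e-6
    factor_low: float = 0.5
    factor_high: float = 2.0
    seed: int = 0
    final_polish_steps: int = 400

    def __post_init__(self):
        if self.local_steps < 1 or self.max_cycles < 1:
            raise ValueError("local_steps and max_cycles must be >= 1")
        if self.plateau_tol <= 0:
            raise ValueError("plateau_tol must be positive")


@dataclass
class GATrace:
    best_sse: list = field(default_factory=list)       # per cycle
    crossed_param: list = field(default_factory=list)  # per cycle
    cycles: int = 0
    final_sse: float = np.inf


@dataclass
class Candidate:
    """Parameter vector (log-space view of k_max then K_m) plus the index of
    the single coordinate perturbed relative to its parent generation."""

    theta: np.ndarray      # concatenated [k_max, k_m], natural scale
    perturbed: int | None  # coordinate index, None for the incumbent
    sse: float = np.inf

    def params_like(self, template: CyberneticParams) -> CyberneticParams:
        m = template.n_modes
        return replace(template, k_max=self.theta[:m].copy(),
                       k_m=self.theta[m:].copy())


def sse_objective(model_factory, data_channels: dict, normalize: bool = True):
    """Build a total-SSE objective over observed channels.

    ``model_factory(theta)`` must return {channel: model values}; channels
    are normalized by their experimental sum of squares so differently
    scaled channels weigh comparably.
    """
    norms = {}
    for name, obs in data_channels.items():
        ssep = float(np.sum(np.asarray(obs) ** 2))
        norms[name] = ssep if (normalize and ssep > 0) else 1.0

    def objective(theta) -> float:
        try:
            channels = model_factory(theta)
        except Exception:
            return np.inf
        total = 0.0
        for name, obs in data_channels.items():
            mod = np.asarray(channels[name], dtype=float)
            if not np.all(np.isfinite(mod)):
                return np.inf
            total += float(np.sum((mod - np.asarray(obs)) ** 2)) / norms[name]
        return total

    return objective


def perturb_generation(base: Candidate, rng: np.random.Generator,
                       config: GAConfig) -> list:
    """2m candidates, each differing from base in exactly one coordinate by a
    log-uniform factor in [factor_low, factor_high]."""
    n = len(base.theta)
    if n == 0:
        raise ValueError("no parameters to perturb")
    out = []
    for j in range(n):
        factor = np.exp(rng.uniform(np.log(config.factor_low),
                                    np.log(config.factor_high)))
        theta = base.theta.copy()
        theta[j] *= factor
        out.append(Candidate(theta=theta, perturbed=j))
    return out


def local_refine(candidate: Candidate, objective, steps: int = 200) -> Candidate:
    """Bounded simplex refinement in log-parameter space, capped at ``steps``
    objective evaluations; the result never has higher SSE than the input."""
    sse_in = objective(candidate.theta)
    if not np.isfinite(sse_in):
        return replace(candidate, sse=np.inf)
    z0 = np.log(np.clip(candidate.theta, 1e-12, None))

    def f(z):
        return objective(np.exp(z))

    res = optimize.minimize(f, z0, method="Nelder-Mead",
                            options={"maxfev": steps, "xatol": 1e-8,
                                     "fatol": 1e-12})
    if np.isfinite(res.fun) and res.fun < sse_in:
        return replace(candidate, theta=np.exp(res.x), sse=float(res.fun))
    return replace(candidate, sse=float(sse_in))


def crossover(best: Candidate, second: Candidate) -> Candidate:
    """Best set with the runner-up's perturbed coordinate substituted."""
    if second.perturbed is None:
        raise ValueError("runner-up lacks a perturbation record")
    theta = best.theta.copy()
    theta[second.perturbed] = second.theta[second.perturbed]
    return Candidate(theta=theta, perturbed=best.perturbed)


def run_ga(objective, n_modes: int, config: GAConfig | None = None,
           callback=None) -> tuple[np.ndarray, GATrace]:
    """Cycle perturb -> refine -> select -> crossover until the best SSE is
    constant (relative change < plateau_tol) or max_cycles is reached, then
    apply a final polish.  Fully reproducible under a fixed seed.

    Returns (theta_best = [k_max..., k_m...], trace).
    """
    config = config or GAConfig()
    rng = np.random.default_rng(config.seed)
    theta0 = np.concatenate([np.full(n_modes, config.kmax_init),
                             np.full(n_modes, config.km_init)])
    incumbent = Candidate(theta=theta0, perturbed=None,
                          sse=float(objective(theta0)))
    trace = GATrace()
    prev_best = incumbent.sse
    for cycle in range(1, config.max_cycles + 1):
        candidates = perturb_generation(incumbent, rng, config)
        refined = [local_refine(c, objective, config.local_steps)
                   for c in candidates]
        refined.sort(key=lambda c: c.sse)
        if not np.isfinite(refined[0].sse):
            trace.cycles = cycle
            trace.final_sse = incumbent.sse
            raise RuntimeError("all candidates infeasible; aborting GA")
        best, second = refined[0], refined[1]
        hybrid = crossover(best, second)
        hybrid.sse = float(objective(hybrid.theta))
        pool = [incumbent, best, hybrid]
        pool.sort(key=lambda c: c.sse)
        incumbent = pool[0]
        trace.best_sse.append(incumbent.sse)
        trace.crossed_param.append(second.perturbed)
        trace.cycles = cycle
        if callback is not None:
            callback(cycle, incumbent)
        # plateau: relative change below tolerance, or the (normalized) SSE
        # already negligible -- relative change is ill-defined as SSE -> 0
        # on noise-free self-consistent data
        if incumbent.sse < config.sse_floor:
            break
        if prev_best > 0 and abs(prev_best - incumbent.sse) / prev_best \
                < config.plateau_tol:
            break
        prev_best = incumbent.sse
    polished = local_refine(incumbent, objective, config.final_polish_steps)
    if polished.sse <= incumbent.sse:
        incumbent = polished
    trace.final_sse = incumbent.sse
    return incumbent.theta, trace
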