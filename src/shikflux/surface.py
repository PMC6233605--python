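"""Second-order bivariate response surfaces over initial (GLC, YE) conditions.

f(G, Y) = b0 + b1*G + b2*Y + b3*G^2 + b4*Y^2 + b5*G*Y, fitted by ordinary
least squares in natural units so that critical-point coordinates read
directly in g/L.  Coordinates are always ordered (GLC, YE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .physio import FitStats, fit_statistics

__all__ = [
    "QuadraticSurface",
    "CriticalPoint",
    "fit_surface",
    "evaluate",
    "critical_point",
    "predict_params",
    "compare_ttest",
    "zone_map",
]


@dataclass
class QuadraticSurface:
    coefficients: np.ndarray  # b0..b5
    domain: tuple = ((75.0, 125.0), (15.0, 45.0))  # ((Gmin,Gmax),(Ymin,Ymax))
    parameter_name: str = ""

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (6,):
            raise ValueError("need exactly 6 coefficients b0..b5")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite coefficients")
        (g0, g1), (y0, y1) = self.domain
        if g0 >= g1 or y0 >= y1:
            raise ValueError("degenerate domain")

    def __call__(self, g, y):
        return evaluate(self, g, y)

    def hessian(self) -> np.ndarray:
        b = self.coefficients
        return np.array([[2 * b[3], b[5]], [b[5], 2 * b[4]]])

    def in_domain(self, g: float, y: float) -> bool:
        (g0, g1), (y0, y1) = self.domain
        return g0 <= g <= g1 and y0 <= y <= y1


@dataclass
class CriticalPoint:
    location: tuple | None  # (G, Y) g/L, None when degenerate
    kind: str               # minimum | maximum | saddle | degenerate
    value: float | None
    in_domain: bool


def _design_matrix(g: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(g), g, y, g ** 2, y ** 2, g * y])


def fit_surface(points, values=None, parameter_name: str = "",
                domain=None) -> tuple[QuadraticSurface, FitStats]:
    """OLS fit of the 6-term quadratic basis.

    ``points`` is either a list of ((G, Y), value) pairs or an (n, 2) array of
    coordinates with ``values`` given separately.  Requires >= 6 points with a
    full-rank quadratic design.
    """
    if values is None:
        coords = np.array([p[0] for p in points], dtype=float)
        vals = np.array([p[1] for p in points], dtype=float)
    else:
        coords = np.asarray(points, dtype=float)
        vals = np.asarray(values, dtype=float)
    if coords.shape[0] < 6:
        raise ValueError("need at least 6 points for a quadratic surface")
    dm = _design_matrix(coords[:, 0], coords[:, 1])
    rank = np.linalg.matrix_rank(dm)
    if rank < 6:
        raise ValueError(
            f"rank-deficient quadratic design (rank {rank} < 6); "
            "points are collinear or replicate too few distinct conditions")
    coef, *_ = np.linalg.lstsq(dm, vals, rcond=None)
    if domain is None:
        domain = ((float(coords[:, 0].min()), float(coords[:, 0].max())),
                  (float(coords[:, 1].min()), float(coords[:, 1].max())))
    surf = QuadraticSurface(coefficients=coef, domain=domain,
                            parameter_name=parameter_name)
    st = fit_statistics(dm @ coef, vals)
    return surf, st


def evaluate(surface: QuadraticSurface, g, y):
    """Polynomial value at (G, Y); extrapolation outside the domain is allowed."""
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(g)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite evaluation point")
    b = surface.coefficients
    out = b[0] + b[1] * g + b[2] * y + b[3] * g ** 2 + b[4] * y ** 2 + b[5] * g * y
    return out if out.ndim else float(out)


def critical_point(surface: QuadraticSurface, tol: float = 1e-10) -> CriticalPoint:
    """Solve grad f = 0 and classify by the Hessian eigenvalue signs."""
    b = surface.coefficients
    h = surface.hessian()
    det = float(np.linalg.det(h))
    scale = max(np.max(np.abs(h)), 1.0) ** 2
    if abs(det) < tol * scale:
        return CriticalPoint(location=None, kind="degenerate", value=None,
                             in_domain=False)
    loc = np.linalg.solve(h, -np.array([b[1], b[2]]))
    eigs = np.linalg.eigvalsh(h)
    if eigs[0] > 0:
        kind = "minimum"
    elif eigs[1] < 0:
        kind = "maximum"
    else:
        kind = "saddle"
    g, y = float(loc[0]), float(loc[1])
    return CriticalPoint(location=(g, y), kind=kind,
                         value=evaluate(surface, g, y),
                         in_domain=surface.in_domain(g, y))


def predict_params(surfaces: dict, glc0: float, ye0: float,
                   rate_names=("mu_max", "q_glc_exp", "q_glc_sta",
                               "q_sa_exp", "q_sa_sta", "q_ac_exp",
                               "q_ac_sta")) -> tuple[dict, list[str]]:
    """Evaluate one surface per parameter at (GLC0, YE0).

    Negative predictions for rate-like parameters are clipped at zero and
    flagged.  Returns (predictions, flags).
    """
    preds, flags = {}, []
    for name, surf in surfaces.items():
        v = evaluate(surf, glc0, ye0)
        if name in rate_names and v < 0:
            flags.append(f"{name} predicted negative ({v:.4g}); clipped to 0")
            v = 0.0
        if not surf.in_domain(glc0, ye0):
            flags.append(f"{name} evaluated outside fitted domain")
        preds[name] = float(v)
    return preds, flags


def compare_ttest(predicted: float, observed: float, sigma_central: float,
                  n: int = 3) -> float:
    """Two-tailed t test of predicted vs observed using the central-point
    replicate standard deviation; statistic (pred-obs)/(sigma*sqrt(1+1/n)),
    df = n - 1.  Values are 'similar' when p > 0.05."""
    if sigma_central <= 0:
        raise ValueError("sigma_central must be positive")
    if n < 2:
        raise ValueError("need n >= 2 replicates")
    t = (predicted - observed) / (sigma_central * np.sqrt(1.0 + 1.0 / n))
    return float(2.0 * stats.t.sf(abs(t), df=n - 1))


def zone_map(surfaces: dict, grid_g: np.ndarray, grid_y: np.ndarray):
    """Label each grid cell with the surface whose z-scored value is maximal.

    ``surfaces`` maps a zone label (e.g. 'sa', 'ac', 'biomass') to a
    QuadraticSurface.  Returns (labels array of shape (len(grid_y), len(grid_g)),
    ordered label list).  Z-scoring over the grid removes unit effects.
    """
    grid_g = np.asarray(grid_g, dtype=float)
    grid_y = np.asarray(grid_y, dtype=float)
    if grid_g.size == 0 or grid_y.size == 0:
        raise ValueError("empty grid")
    if not surfaces:
        raise ValueError("no surfaces given")
    gg, yy = np.meshgrid(grid_g, grid_y)
    names = list(surfaces)
    stack = []
    for name in names:
        z = evaluate(surfaces[name], gg, yy)
        sd = z.std()
        stack.append((z - z.mean()) / sd if sd > 0 else np.zeros_like(z))
    # round so floating noise cannot flip exact ties; argmax then breaks
    # residual ties by insertion order
    winners = np.argmax(np.round(np.stack(stack), 9), axis=0)
    return winners, names
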