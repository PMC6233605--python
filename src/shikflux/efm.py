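"""Elementary flux mode enumeration and yield-space model reduction.

Enumeration uses the double-description (Schuster tableau) algorithm on the
split-reversible network: every reversible reaction contributes a forward and
a backward nonnegative column, metabolite balance constraints are imposed one
row at a time, and candidate rays produced by combining a positive with a
negative ray survive only if no third ray's support is contained in the
union of the parents' supports (rank-free adjacency/minimality test).
Spurious two-cycles arising from the reversible split are removed at the end.

Model reduction follows yield analysis: each mode is summarised by its
external-species yields per unit glucose uptake, and a family of modes is
reduced to the smallest subset whose convex hull in yield space still
contains an experimentally observed yield point (exhaustive search for small
families, greedy backward elimination beyond).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, QhullError

from .network import MetabolicNetwork, stoichiometric_matrix

__all__ = [
    "ElementaryMode",
    "EMFamily",
    "enumerate_efms",
    "select_family",
    "reduce_by_yield_hull",
    "in_hull",
    "project_to_hull",
    "expand_family",
    "pgi_g6pdh_scan",
]

_TOL = 1e-9


@dataclass
class ElementaryMode:
    """One elementary mode of the split-reversible network.

    ``net_flux`` maps reaction id -> net rate (forward minus backward);
    ``yields`` maps external metabolite id -> production rate, normalized to
    unit glucose uptake whenever glucose is in the support.
    """

    net_flux: dict
    yields: dict
    support: frozenset
    index: int = -1

    def yield_vector(self, dims) -> np.ndarray:
        return np.array([self.yields.get(d, 0.0) for d in dims])


@dataclass
class EMFamily:
    phase: str  # "M" (exponential, mixed substrate) or "G" (stationary, glucose only)
    modes: list

    def __len__(self):
        return len(self.modes)

    def yield_matrix(self, dims) -> np.ndarray:
        return np.array([m.yield_vector(dims) for m in self.modes])


# ---------------------------------------------------------------------------
# enumeration


def _split_network(network: MetabolicNetwork):
    """Split reversible reactions; returns (S_split, column metadata).

    Metadata per column is a list of (reaction_id, direction, weight) terms;
    after chain compression a column may represent several reactions.
    """
    s = stoichiometric_matrix(network)
    cols, meta = [], []
    for j, r in enumerate(network.reactions):
        cols.append(s[:, j])
        meta.append([(r.id, +1, 1.0)])
        if r.reversible:
            cols.append(-s[:, j])
            meta.append([(r.id, -1, 1.0)])
    return (np.column_stack(cols) if cols else s), meta


def _compress(s: np.ndarray, meta: list):
    """Lossless pre-processing: drop flux-forced-zero columns and merge the
    two columns around any internal metabolite with exactly one producer and
    one consumer.  Both transformations preserve the elementary-mode set
    (modes are re-expanded to original reactions afterwards)."""
    s = s.copy()
    meta = [list(m) for m in meta]
    changed = True
    while changed:
        changed = False
        # dead-end metabolites force their columns to zero flux
        for i in range(s.shape[0]):
            row = s[i]
            pos = np.flatnonzero(row > _TOL)
            neg = np.flatnonzero(row < -_TOL)
            if (len(pos) == 0) != (len(neg) == 0):
                drop = np.concatenate([pos, neg])
                keep = np.setdiff1d(np.arange(s.shape[1]), drop)
                s = s[:, keep]
                meta = [meta[k] for k in keep]
                changed = True
                break
        if changed:
            continue
        # merge across single-producer/single-consumer metabolites
        for i in range(s.shape[0]):
            row = s[i]
            pos = np.flatnonzero(row > _TOL)
            neg = np.flatnonzero(row < -_TOL)
            if len(pos) == 1 and len(neg) == 1:
                jp, jn = int(pos[0]), int(neg[0])
                # never merge the two split directions of one reaction
                rids_p = {t[0] for t in meta[jp]}
                rids_n = {t[0] for t in meta[jn]}
                if rids_p & rids_n:
                    continue
                a, b = row[jp], -row[jn]
                merged_col = b * s[:, jp] + a * s[:, jn]
                merged_meta = ([(r, d, w * b) for r, d, w in meta[jp]]
                               + [(r, d, w * a) for r, d, w in meta[jn]])
                keep = [k for k in range(s.shape[1]) if k not in (jp, jn)]
                s = np.column_stack([s[:, keep], merged_col]) \
                    if keep else merged_col[:, None]
                meta = [meta[k] for k in keep] + [merged_meta]
                changed = True
                break
    # drop all-zero balance rows
    nz = np.any(np.abs(s) > _TOL, axis=1)
    return s[nz], meta


def _subset_counts_numpy(packed, union):
    sub = np.all((packed[:, None, :] & ~union[None, :, :]) == 0, axis=2)
    return sub.sum(axis=0)


try:  # compiled adjacency test; falls back to numpy when numba is absent
    from numba import njit

    @njit(cache=True)
    def _adjacent_pairs(packed, pos_idx, neg_idx):
        n, nw = packed.shape
        out = []
        for ii in range(pos_idx.shape[0]):
            pi = pos_idx[ii]
            for jj in range(neg_idx.shape[0]):
                nj = neg_idx[jj]
                cnt = 0
                ok = True
                for k in range(n):
                    is_sub = True
                    for w in range(nw):
                        u = packed[pi, w] | packed[nj, w]
                        if packed[k, w] & ~u != np.uint64(0):
                            is_sub = False
                            break
                    if is_sub:
                        cnt += 1
                        if cnt > 2:
                            ok = False
                            break
                if ok:
                    out.append(pi * np.int64(1 << 32) + nj)
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _pack_supports(bools: np.ndarray) -> np.ndarray:
    """Pack a (n, k) boolean support matrix into (n, ceil(k/64)) uint64 words."""
    n, k = bools.shape
    nw = max((k + 63) // 64, 1)
    padded = np.zeros((n, nw * 64), dtype=bool)
    padded[:, :k] = bools
    bits = np.packbits(padded, axis=1, bitorder="little")
    return bits.reshape(n, nw, 8).view(np.uint64).reshape(n, nw)


def _double_description(s: np.ndarray, max_rays: int = 2_000_000) -> np.ndarray:
    """Extreme rays of {v >= 0 : S v = 0} by iterative constraint processing."""
    n_rows, n_cols = s.shape
    rays = np.eye(n_cols)
    remaining = list(range(n_rows))
    while remaining:
        # greedy row order: fewest pos*neg combinations first
        d_all = s[remaining] @ rays.T
        costs = [(np.sum(d > _TOL) * np.sum(d < -_TOL), i)
                 for i, d in zip(remaining, d_all)]
        _, row = min(costs)
        remaining.remove(row)
        d = s[row] @ rays.T
        zero = np.abs(d) <= _TOL
        pos_idx = np.flatnonzero(d > _TOL)
        neg_idx = np.flatnonzero(d < -_TOL)
        kept = rays[zero]
        if len(pos_idx) == 0 or len(neg_idx) == 0:
            rays = kept
            if len(rays) == 0:
                return rays
            continue
        packed = _pack_supports(rays > _TOL)
        if _HAVE_NUMBA:
            pairs = _adjacent_pairs(packed, pos_idx.astype(np.int64),
                                    neg_idx.astype(np.int64))
            pairs = np.asarray(pairs, dtype=np.int64)
            pi = pairs >> 32
            nj = pairs & 0xFFFFFFFF
        else:
            pis, njs = [], []
            for p in pos_idx:
                union = packed[p][None, :] | packed[neg_idx]
                counts = _subset_counts_numpy(packed, union)
                good = neg_idx[counts <= 2]
                pis.extend([p] * len(good))
                njs.extend(good.tolist())
            pi = np.asarray(pis, dtype=np.int64)
            nj = np.asarray(njs, dtype=np.int64)
        if len(pi):
            combo = (d[pi][:, None] * rays[nj]
                     - d[nj][:, None] * rays[pi])
            combo /= np.max(np.abs(combo), axis=1, keepdims=True)
            combo[np.abs(combo) <= _TOL] = 0.0
            rays = np.vstack([kept, combo])
        else:
            rays = kept
        if len(rays) > max_rays:
            raise RuntimeError(
                f"ray count {len(rays)} exceeds max_rays={max_rays}")
    return rays


def enumerate_efms(network: MetabolicNetwork, compress: bool = True) -> list:
    """Complete, duplicate-free elementary mode set of the network.

    Modes are normalized to unit glucose uptake when glucose is in support,
    otherwise to unit L1 norm.  Two-cycles from the reversible split are
    removed.
    """
    s, meta = _split_network(network)
    if s.shape[1] == 0:
        return []
    if compress:
        s, meta = _compress(s, meta)
    if s.shape[1] == 0:
        return []
    rays = _double_description(s)
    ext_ids = [m.id for m in network.external_metabolites]
    modes = []
    seen = set()
    for v in rays:
        sup_cols = np.flatnonzero(v > _TOL)
        # expand compressed columns into per-reaction signed net fluxes
        net: dict = {}
        dirs_used: dict = {}
        for k in sup_cols:
            for rid, direction, weight in meta[k]:
                net[rid] = net.get(rid, 0.0) + direction * weight * v[k]
                dirs_used.setdefault(rid, set()).add(direction)
        # discard modes using both directions of one reversible reaction
        # (includes the spurious 2-cycles from the split)
        if any(len(dset) > 1 for dset in dirs_used.values()):
            continue
        glc_uptake = 0.0
        for rid, val in net.items():
            c = network.reaction(rid).stoichiometry.get("GLC", 0.0)
            if c * val < 0:
                glc_uptake += -c * val
        scale = glc_uptake if glc_uptake > _TOL \
            else sum(abs(x) for x in net.values())
        net = {rid: val / scale for rid, val in net.items()}
        key = frozenset(net)
        if key in seen:
            continue
        seen.add(key)
        yields = _mode_yields(network, net, ext_ids)
        modes.append(ElementaryMode(net_flux=net, yields=yields,
                                    support=frozenset(net)))
    modes.sort(key=lambda m: sorted(m.support))
    for i, m in enumerate(modes):
        m.index = i
    return modes


def _mode_yields(network: MetabolicNetwork, net_flux: dict, ext_ids) -> dict:
    y = {e: 0.0 for e in ext_ids}
    for rid, v in net_flux.items():
        for met, c in network.reaction(rid).stoichiometry.items():
            if met in y:
                y[met] += c * v
    return {k: (0.0 if abs(v) < _TOL else v) for k, v in y.items()}


# ---------------------------------------------------------------------------
# families and reduction


def select_family(modes, phase: str, tol: float = 1e-9) -> EMFamily:
    """Filter modes by the exchange sign pattern of a fermentation phase.

    Phase "M" (exponential): glucose and yeast extract consumed, shikimate
    produced.  Phase "G" (stationary): glucose consumed, shikimate produced,
    no yeast-extract uptake.
    """
    if phase not in ("M", "G"):
        raise ValueError("phase must be 'M' or 'G'")
    selected = []
    for m in modes:
        glc = m.yields.get("GLC", 0.0)
        ye = m.yields.get("YE", 0.0)
        sa = m.yields.get("SA", 0.0)
        if glc >= -tol or sa <= tol:
            continue
        if phase == "M" and ye < -tol:
            selected.append(m)
        elif phase == "G" and abs(ye) <= tol:
            selected.append(m)
    if not selected:
        raise ValueError(
            f"no modes match phase {phase!r}; review the network or the "
            "family constraints")
    return EMFamily(phase=phase, modes=list(selected))


def in_hull(points: np.ndarray, target: np.ndarray, tol: float = 1e-7) -> bool:
    """True when target is a convex combination of the given points."""
    points = np.atleast_2d(points)
    n, d = points.shape
    a_eq = np.vstack([points.T, np.ones(n)])
    b_eq = np.concatenate([target, [1.0]])
    res = linprog(np.zeros(n), A_eq=a_eq, b_eq=b_eq, bounds=[(0, None)] * n,
                  method="highs")
    if not res.success:
        return False
    return bool(np.max(np.abs(a_eq @ res.x - b_eq)) < tol)


def _nearest_hull_point(points: np.ndarray, target: np.ndarray) -> np.ndarray:
    """L1-nearest point of the hull to the target (LP)."""
    n, d = points.shape
    # variables: lambda (n), e+ (d), e- (d)
    c = np.concatenate([np.zeros(n), np.ones(2 * d)])
    a_eq = np.zeros((d + 1, n + 2 * d))
    a_eq[:d, :n] = points.T
    a_eq[:d, n:n + d] = -np.eye(d)
    a_eq[:d, n + d:] = np.eye(d)
    a_eq[d, :n] = 1.0
    b_eq = np.concatenate([target, [1.0]])
    res = linprog(c, A_eq=a_eq, b_eq=b_eq,
                  bounds=[(0, None)] * (n + 2 * d), method="highs")
    if not res.success:
        raise RuntimeError("nearest-point LP failed")
    return points.T @ res.x[:n]


def _subset_volume(points: np.ndarray) -> float:
    """Convex-hull measure of a point subset in its affine dimension."""
    k = len(points)
    if k <= 1:
        return 0.0
    rel = points[1:] - points[0]
    gram = rel @ rel.T
    det = np.linalg.det(gram)
    if det <= 0:
        return 0.0
    vol = np.sqrt(det)
    for i in range(2, k):
        vol /= i
    return float(vol)


def reduce_by_yield_hull(family: EMFamily, target: dict | np.ndarray,
                         dims=("BIOMASS", "SA", "AC"),
                         exhaustive_limit: int = 12) -> EMFamily:
    """Minimal mode subset whose yield-space hull contains the target.

    ``target`` gives the observed yields per unit glucose uptake for the
    chosen dimensions.  Exact exhaustive search up to ``exhaustive_limit``
    family modes; greedy backward elimination (heuristic) beyond.  Equal
    cardinality ties break by smaller hull volume, then lexicographic mode
    index.
    """
    dims = tuple(dims)
    if isinstance(target, dict):
        t = np.array([float(target[d]) for d in dims])
    else:
        t = np.asarray(target, dtype=float)
    y = family.yield_matrix(dims)
    if not in_hull(y, t):
        near = _nearest_hull_point(y, t)
        raise ValueError(
            f"target {t.tolist()} outside the family yield hull; nearest "
            f"hull point {np.round(near, 6).tolist()}")
    n = len(family.modes)
    if n <= exhaustive_limit:
        chosen = _exhaustive_minimal(y, t, range(n))
    else:
        # heuristic for large families: the support of a basic (vertex) LP
        # solution is a Caratheodory subset of at most dim+1 modes; the
        # exhaustive search then minimizes within that support
        a_eq = np.vstack([y.T, np.ones(n)])
        b_eq = np.concatenate([t, [1.0]])
        res = linprog(np.zeros(n), A_eq=a_eq, b_eq=b_eq,
                      bounds=[(0, None)] * n, method="highs")
        if not res.success:
            raise ValueError("containment LP failed on the full family")
        support = np.flatnonzero(res.x > 1e-10).tolist()
        chosen = _exhaustive_minimal(y, t, support)
    return EMFamily(phase=family.phase,
                    modes=[family.modes[i] for i in chosen])


def _exhaustive_minimal(y: np.ndarray, t: np.ndarray, pool) -> list:
    """Smallest subset of ``pool`` whose hull contains t; ties by volume then
    lexicographic index."""
    pool = list(pool)
    for k in range(1, len(pool) + 1):
        cands = []
        for combo in itertools.combinations(pool, k):
            sub = y[list(combo)]
            if in_hull(sub, t):
                cands.append((_subset_volume(sub), combo))
        if cands:
            cands.sort(key=lambda cv: (cv[0], cv[1]))
            return list(cands[0][1])
    raise ValueError("target not contained in the pool hull")


def project_to_hull(family: EMFamily, target, dims=("BIOMASS", "SA", "AC")):
    """Project a yield target onto the family hull (L1-nearest point).

    Returns (target_vector, projected_flag); the input is returned unchanged
    when it is already contained.
    """
    dims = tuple(dims)
    if isinstance(target, dict):
        t = np.array([float(target[d]) for d in dims])
    else:
        t = np.asarray(target, dtype=float)
    y = family.yield_matrix(dims)
    if in_hull(y, t):
        return t, False
    return _nearest_hull_point(y, t), True


def expand_family(family: EMFamily, reduced: EMFamily, size: int,
                  dims=("BIOMASS", "SA", "AC")) -> EMFamily:
    """Deterministically grow a reduced family to ``size`` modes by greedy
    hull-volume maximization in yield space (ties broken by mode index).

    Used to carry a fixed model structure (e.g. the six exponential-family
    modes of the study design) when the minimal containing subset is smaller.
    """
    dims = tuple(dims)
    chosen = [m.index for m in reduced.modes]
    by_index = {m.index: m for m in family.modes}
    if size <= len(chosen):
        return reduced
    pool = sorted(i for i in by_index if i not in chosen)
    while len(chosen) < size and pool:
        best = None
        for i in pool:
            pts = np.array([by_index[j].yield_vector(dims)
                            for j in chosen + [i]])
            vol = _subset_volume(pts)
            if best is None or vol > best[0] + 1e-15:
                best = (vol, i)
        chosen.append(best[1])
        pool.remove(best[1])
    return EMFamily(phase=family.phase,
                    modes=[by_index[i] for i in sorted(chosen)])


# ---------------------------------------------------------------------------
# Pgi / G6Pdh node scan


def pgi_g6pdh_scan(candidates: dict, experimental: dict) -> list:
    """Rank candidate flux-distribution sets against experimental series.

    ``candidates`` maps a ratio label (e.g. 'unconstrained', 0.25 ...) to a
    dict of channel name -> model values, or ``None`` for an infeasible
    constraint.  ``experimental`` maps channel name -> observed values.
    Returns a ranked list of report dicts (best first, stable by insertion
    order on ties); infeasible candidates are flagged and ranked last.
    """
    from .physio import fit_statistics

    reports = []
    for order, (label, channels) in enumerate(candidates.items()):
        if channels is None:
            reports.append({"label": label, "feasible": False, "order": order,
                            "score": np.inf, "stats": {}})
            continue
        stats = {}
        errs = []
        for name, model in channels.items():
            st = fit_statistics(np.asarray(model),
                                np.asarray(experimental[name]))
            stats[name] = st
            errs.append(st.error_pct)
        score = float(np.mean(errs))
        reports.append({"label": label, "feasible": True, "order": order,
                        "score": score, "stats": stats})
    reports.sort(key=lambda r: (not r["feasible"], round(r["score"], 12),
                                r["order"]))
    return reports
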