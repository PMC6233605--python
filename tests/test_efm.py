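"""Elementary-mode enumeration against an exhaustive oracle, plus family
selection and convex-hull yield reduction."""

import itertools

import numpy as np
import pytest
from scipy.linalg import null_space

from shikflux.efm import (ElementaryMode, EMFamily, _double_description,
                          _split_network, enumerate_efms, expand_family,
                          in_hull, pgi_g6pdh_scan, project_to_hull,
                          reduce_by_yield_hull, select_family)
from shikflux.network import MetabolicNetwork, Metabolite, Reaction
from shikflux.network import stoichiometric_matrix


def brute_force_rays(s: np.ndarray) -> set:
    """Exhaustive oracle for the extreme rays of {v >= 0 : S v = 0}.

    A support T is elementary iff the kernel of S restricted to T is
    one-dimensional with a strictly positive representative; minimality is
    enforced by discarding supersets of accepted supports.
    """
    n = s.shape[1]
    found = []
    for size in range(1, n + 1):
        for cols in itertools.combinations(range(n), size):
            if any(set(f) < set(cols) for f in found):
                continue
            ker = null_space(s[:, cols])
            if ker.shape[1] != 1:
                continue
            v = ker[:, 0]
            if np.all(v > 1e-10) or np.all(v < -1e-10):
                found.append(cols)
    return {frozenset(f) for f in found}


def dd_supports(s: np.ndarray) -> set:
    rays = _double_description(s)
    return {frozenset(np.flatnonzero(r > 1e-9).tolist()) for r in rays}


class TestEnumerationOracle:
    def test_chain_single_mode(self):
        s = np.array([[1., -1, 0], [0, 1, -1]])
        assert dd_supports(s) == brute_force_rays(s) == {frozenset({0, 1, 2})}

    def test_diamond_two_modes(self):
        # A -> B -> D and A -> C -> D with source/sink exchanges
        # cols: in, ab, bd, ac, cd, out ; rows A,B,C,D
        s = np.array([
            [1., -1, 0, -1, 0, 0],
            [0, 1, -1, 0, 0, 0],
            [0, 0, 0, 1, -1, 0],
            [0, 0, 1, 0, 1, -1],
        ])
        modes = dd_supports(s)
        assert modes == brute_force_rays(s)
        assert len(modes) == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_random_networks_match_oracle(self, seed):
        """Random 6x9 stoichiometries: double description equals the
        exhaustive support-search oracle."""
        rng = np.random.default_rng(seed)
        s = rng.choice([-1, 0, 0, 1], size=(6, 9)).astype(float)
        assert dd_supports(s) == brute_force_rays(s)

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(5)
        s = rng.choice([-1, 0, 0, 1], size=(5, 8)).astype(float)
        base = dd_supports(s)
        perm = rng.permutation(8)
        permuted = dd_supports(s[:, perm])
        mapped = {frozenset(int(perm[i]) for i in sup) for sup in permuted}
        assert mapped == base


def tiny_network(reversible_pgi=False):
    """GLC -> A -> (B -> SA | C -> AC) toy with optional reversible step."""
    mets = [Metabolite("GLC", external=True), Metabolite("SA", external=True),
            Metabolite("AC", external=True), Metabolite("A"),
            Metabolite("B"), Metabolite("C")]
    rxns = [
        Reaction("upt", {"GLC": -1, "A": 1}),
        Reaction("ab", {"A": -1, "B": 1}, reversible=reversible_pgi),
        Reaction("ac", {"A": -1, "C": 1}),
        Reaction("bs", {"B": -1, "SA": 1}),
        Reaction("ca", {"C": -1, "AC": 1}),
    ]
    return MetabolicNetwork(metabolites=mets, reactions=rxns)


class TestEnumerateEfms:
    def test_toy_modes_and_normalization(self):
        modes = enumerate_efms(tiny_network())
        assert len(modes) == 2
        for m in modes:
            assert m.yields["GLC"] == pytest.approx(-1.0)
        assert {frozenset(m.support) for m in modes} == {
            frozenset({"upt", "ab", "bs"}), frozenset({"upt", "ac", "ca"})}

    def test_reversible_two_cycle_removed(self):
        modes = enumerate_efms(tiny_network(reversible_pgi=True))
        # the forward/backward pair of 'ab' must not appear as a mode
        assert all(len(m.support) > 1 for m in modes)
        assert len(modes) == 2

    def test_steady_state_and_nonnegativity(self, fixture_network,
                                            fixture_modes):
        """Every enumerated fixture mode satisfies S v = 0 (internal rows)
        to 1e-9 and uses each reversible reaction in one direction only."""
        s = stoichiometric_matrix(fixture_network)
        rids = fixture_network.reaction_ids
        idx = {r: j for j, r in enumerate(rids)}
        v = np.zeros((len(fixture_modes), len(rids)))
        for i, m in enumerate(fixture_modes):
            for rid, val in m.net_flux.items():
                v[i, idx[rid]] = val
        resid = np.abs(s @ v.T).max()
        assert resid < 1e-9
        rev_ok = [not r.reversible for r in fixture_network.reactions]
        assert np.all(v[:, rev_ok] >= -1e-12)

    def test_compression_agrees_with_plain_enumeration(self):
        net = tiny_network()
        a = {frozenset(m.support) for m in enumerate_efms(net, compress=True)}
        b = {frozenset(m.support) for m in enumerate_efms(net,
                                                          compress=False)}
        assert a == b


def fake_mode(index, yields, support=None):
    return ElementaryMode(net_flux={f"r{index}": 1.0}, yields=yields,
                          support=support or frozenset({f"r{index}"}),
                          index=index)


class TestFamilySelection:
    def make_modes(self):
        return [
            fake_mode(0, {"GLC": -1, "YE": -0.2, "SA": 0.4, "AC": 0.1}),
            fake_mode(1, {"GLC": -1, "YE": 0.0, "SA": 0.6, "AC": 0.2}),
            fake_mode(2, {"GLC": 0.0, "YE": -1.0, "SA": 0.5, "AC": 0.0}),
            fake_mode(3, {"GLC": -1, "YE": -0.1, "SA": 0.0, "AC": 0.3}),
        ]

    def test_sign_patterns(self):
        modes = self.make_modes()
        fam_m = select_family(modes, "M")
        fam_g = select_family(modes, "G")
        assert [m.index for m in fam_m.modes] == [0]
        assert [m.index for m in fam_g.modes] == [1]

    def test_ye_only_mode_excluded(self):
        modes = self.make_modes()
        for fam in (select_family(modes, "M"), select_family(modes, "G")):
            assert 2 not in [m.index for m in fam.modes]

    def test_empty_family_raises(self):
        with pytest.raises(ValueError, match="phase"):
            select_family([fake_mode(0, {"GLC": -1, "SA": 0.0})], "G")

    def test_fixture_families_nonempty(self, fixture_modes):
        assert len(select_family(fixture_modes, "M")) > 0
        assert len(select_family(fixture_modes, "G")) > 0


class TestHullReduction:
    dims = ("SA", "AC")

    def square_family(self):
        corners = [(0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0)]
        modes = [fake_mode(i, {"SA": sa, "AC": ac})
                 for i, (sa, ac) in enumerate(corners)]
        return EMFamily(phase="G", modes=modes)

    def test_target_on_vertex_single_mode(self):
        fam = self.square_family()
        red = reduce_by_yield_hull(fam, {"SA": 1.0, "AC": 0.0},
                                   dims=self.dims)
        assert len(red) == 1 and red.modes[0].index == 1

    def test_square_centroid_on_diagonal_two_modes(self):
        # the exact centroid sits on the square's diagonal, so the
        # exhaustive search (and the reduction) finds a 2-mode segment
        fam = self.square_family()
        red = reduce_by_yield_hull(fam, {"SA": 0.5, "AC": 0.5},
                                   dims=self.dims)
        assert len(red) == 2
        assert in_hull(red.yield_matrix(self.dims), np.array([0.5, 0.5]))

    def test_square_interior_three_mode_triangle(self):
        # an interior point off both diagonals needs a 3-mode triangle,
        # matching the exhaustive subset search
        fam = self.square_family()
        target = np.array([0.5, 0.4])
        red = reduce_by_yield_hull(fam, dict(zip(self.dims, target)),
                                   dims=self.dims)
        assert len(red) == 3
        for combo in itertools.combinations(fam.modes, 2):
            pts = np.array([m.yield_vector(self.dims) for m in combo])
            assert not in_hull(pts, target)

    def test_outside_target_reports_nearest(self):
        fam = self.square_family()
        with pytest.raises(ValueError, match="nearest"):
            reduce_by_yield_hull(fam, {"SA": 2.0, "AC": 0.5}, dims=self.dims)

    def test_reduction_contract_random(self):
        """Reduction never grows the family and always preserves target
        containment (random 3-D families)."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            pts = rng.uniform(0, 1, size=(8, 3))
            modes = [fake_mode(i, dict(zip(("BIOMASS", "SA", "AC"), p)))
                     for i, p in enumerate(pts)]
            fam = EMFamily(phase="M", modes=modes)
            target = pts.mean(axis=0)
            red = reduce_by_yield_hull(fam, dict(zip(("BIOMASS", "SA", "AC"),
                                                     target)))
            assert len(red) <= len(fam)
            y = red.yield_matrix(("BIOMASS", "SA", "AC"))
            assert in_hull(y, target)

    def test_large_family_heuristic_path(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 1, size=(30, 2))
        modes = [fake_mode(i, {"SA": p[0], "AC": p[1]})
                 for i, p in enumerate(pts)]
        fam = EMFamily(phase="G", modes=modes)
        red = reduce_by_yield_hull(fam, {"SA": 0.5, "AC": 0.5},
                                   dims=self.dims, exhaustive_limit=12)
        assert len(red) <= 3
        assert in_hull(red.yield_matrix(self.dims), np.array([0.5, 0.5]))

    def test_projection_helper(self):
        fam = self.square_family()
        t, proj = project_to_hull(fam, {"SA": 2.0, "AC": 0.5},
                                  dims=self.dims)
        assert proj and in_hull(fam.yield_matrix(self.dims), t)
        t2, proj2 = project_to_hull(fam, {"SA": 0.5, "AC": 0.5},
                                    dims=self.dims)
        assert not proj2 and tuple(t2) == (0.5, 0.5)

    def test_expand_family_deterministic(self):
        fam = self.square_family()
        red = reduce_by_yield_hull(fam, {"SA": 1.0, "AC": 0.0},
                                   dims=self.dims)
        grown = expand_family(fam, red, 3, dims=self.dims)
        grown2 = expand_family(fam, red, 3, dims=self.dims)
        assert [m.index for m in grown.modes] == [m.index for m in
                                                  grown2.modes]
        assert len(grown) == 3


class TestPgiScan:
    def test_perfect_candidate_ranked_first(self):
        exp = {"glc": np.array([1.0, 2.0, 3.0])}
        cands = {
            "unconstrained": {"glc": np.array([1.1, 2.2, 3.3])},
            0.25: {"glc": np.array([1.0, 2.0, 3.0])},
            0.5: None,
        }
        ranked = pgi_g6pdh_scan(cands, exp)
        assert ranked[0]["label"] == 0.25
        assert ranked[-1]["label"] == 0.5 and not ranked[-1]["feasible"]

    def test_tie_break_stable(self):
        exp = {"glc": np.array([1.0, 2.0, 3.0])}
        same = {"glc": np.array([1.0, 2.0, 3.1])}
        ranked = pgi_g6pdh_scan({"a": same, "b": dict(same)}, exp)
        assert [r["label"] for r in ranked] == ["a", "b"]
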