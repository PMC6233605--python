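"""Cybernetic rate laws, matching-law allocation, integration and flux
reconstruction."""

import numpy as np
import pytest

from shikflux import cybernetic as cyb
from shikflux.cybernetic import (CARBON_PER_MMOL, CyberneticModel,
                                 CyberneticParams, default_e0, matching_law,
                                 mode_rate, phase_times, reconstruct_fluxes)
from shikflux.efm import ElementaryMode, EMFamily
from shikflux.network import MetabolicNetwork, Metabolite, Reaction
from shikflux.physio import logistic_biomass


class TestModeRate:
    def test_saturation_limit(self):
        r = mode_rate(glc_mm=1e9, ac_mm=0.0, x=0.0, k_max=5.0, k_m=20.0,
                      k_i_ac=100.0, x_max=10.0, family="M")
        assert r == pytest.approx(5.0, rel=1e-6)

    def test_half_saturation(self):
        # [GLC] = K_m puts the Monod factor at exactly one half
        half = mode_rate(20.0, 0.0, 0.0, 5.0, 20.0, 100.0, 10.0, "M")
        assert half == pytest.approx(2.5, rel=1e-12)

    def test_inhibition_halves_rate(self):
        base = mode_rate(50.0, 0.0, 2.0, 5.0, 20.0, 100.0, 10.0, "G")
        inhib = mode_rate(50.0, 100.0, 2.0, 5.0, 20.0, 100.0, 10.0, "G")
        assert inhib == pytest.approx(base / 2, rel=1e-12)

    def test_phase_weights_complementary(self):
        m = mode_rate(50.0, 0.0, 4.0, 5.0, 20.0, 100.0, 10.0, "M")
        g = mode_rate(50.0, 0.0, 4.0, 5.0, 20.0, 100.0, 10.0, "G")
        sat = mode_rate(50.0, 0.0, 0.0, 5.0, 20.0, 100.0, 10.0, "M")
        assert m + g == pytest.approx(sat, rel=1e-12)

    def test_weight_clipped_beyond_xmax(self):
        r = mode_rate(50.0, 0.0, 15.0, 5.0, 20.0, 100.0, 10.0, "M")
        assert r == 0.0


class TestMatchingLaw:
    def test_single_mode(self):
        u, v = matching_law([3.0])
        assert u.tolist() == [1.0] and v.tolist() == [1.0]

    def test_two_to_one(self):
        u, v = matching_law([2.0, 1.0])
        np.testing.assert_allclose(u, [2 / 3, 1 / 3])
        np.testing.assert_allclose(v, [1.0, 0.5])

    def test_equal_returns_symmetric(self):
        u, v = matching_law([0.7] * 5)
        np.testing.assert_allclose(u, 0.2)
        np.testing.assert_allclose(v, 1.0)

    def test_all_zero_uniform(self):
        u, v = matching_law([0.0, 0.0])
        np.testing.assert_allclose(u, 0.5)
        np.testing.assert_allclose(v, 1.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            matching_law([1.0, -0.1])


def two_mode_setup(fixture_network, fixture_modes):
    from shikflux.efm import select_family

    fam_m = select_family(fixture_modes, "M")
    fam_g = select_family(fixture_modes, "G")
    # highest-biomass M mode and highest-SA G mode give a clean 2-mode model
    m_best = max(fam_m.modes, key=lambda m: m.yields.get("BIOMASS", 0))
    g_best = max(fam_g.modes, key=lambda m: m.yields.get("SA", 0))
    fams = [EMFamily(phase="M", modes=[m_best]),
            EMFamily(phase="G", modes=[g_best])]
    return fams


class TestIntegration:
    init = {"glc_mm": 555.0, "ye_mm": 200.0, "biomass": 0.25}

    def test_null_dynamics(self, fixture_network, fixture_modes):
        fams = two_mode_setup(fixture_network, fixture_modes)
        p = CyberneticParams(k_max=[0.0, 0.0], k_m=[10.0, 10.0], x_max=12.8,
                             e0=[0.5, 0.5])
        model = CyberneticModel(fixture_network, fams, p)
        traj = model.simulate(self.init, 10.0, n_out=11)
        np.testing.assert_allclose(traj.glc_mm, 555.0, rtol=1e-8)
        np.testing.assert_allclose(traj.biomass, 0.25, rtol=1e-8)

    def test_cybernetic_variable_invariants(self, fixture_network,
                                            fixture_modes):
        fams = two_mode_setup(fixture_network, fixture_modes)
        p = CyberneticParams(k_max=[6.0, 3.0], k_m=[20.0, 25.0], x_max=12.8,
                             e0=[0.95, 0.1])
        model = CyberneticModel(fixture_network, fams, p)
        traj = model.simulate(self.init, 30.0, n_out=61)
        np.testing.assert_allclose(traj.u.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(traj.v.max(axis=1), 1.0, atol=1e-9)
        assert np.all((traj.u >= 0) & (traj.u <= 1 + 1e-12))
        assert np.all((traj.v >= -1e-12) & (traj.v <= 1 + 1e-12))

    def test_external_balance_identity(self, fixture_network, fixture_modes):
        """dC/dt equals the yield-weighted sum of mode uptakes, by
        construction of the model equations."""
        fams = two_mode_setup(fixture_network, fixture_modes)
        p = CyberneticParams(k_max=[6.0, 3.0], k_m=[20.0, 25.0], x_max=12.8,
                             e0=[0.95, 0.1])
        model = CyberneticModel(fixture_network, fams, p)
        state = np.array([400.0, 5.0, 30.0, 100.0, 4.0, 0.7, 0.4])
        deriv = model._rhs(0.0, state)
        e = state[5:]
        r = model.kinetic_rates(400.0, 5.0, 4.0)
        _, v = model.allocation(e, r)
        q = e * v * r
        expect = model.yields.T @ (q * 4.0)
        np.testing.assert_allclose(deriv[:4], expect[:4], rtol=1e-12)

    def test_carbon_closure_along_trajectory(self, fixture_network,
                                             fixture_modes):
        """Carbon consumed from glucose and yeast extract equals carbon in
        biomass, shikimate, acetate and the vented sink (balanced network,
        audited through mode yields)."""
        for m in fixture_modes[::500]:
            total = sum(m.yields.get(sp, 0.0) * CARBON_PER_MMOL.get(sp, 0.0)
                        for sp in ("GLC", "YE", "SA", "AC", "BIOMASS"))
            maint_c = _mode_co2_carbon(fixture_network, m)
            assert abs(total + maint_c) < 1e-6

    def test_stationary_family_silenced(self, fixture_network,
                                        fixture_modes):
        """With the glucose-only family switched off, nothing changes after
        biomass reaches its maximum."""
        fams = two_mode_setup(fixture_network, fixture_modes)
        p = CyberneticParams(k_max=[8.0, 0.0], k_m=[20.0, 25.0], x_max=6.0,
                             e0=[0.95, 0.1])
        model = CyberneticModel(fixture_network, fams, p)
        traj = model.simulate(self.init, 40.0, n_out=81)
        plateau = traj.biomass >= 0.999 * traj.biomass[-1]
        late = np.flatnonzero(plateau)[2:]
        if len(late) > 2:
            assert np.ptp(traj.glc_mm[late]) < 1e-3 * max(traj.glc_mm[0], 1)
            assert np.ptp(traj.sa_mm[late]) < 1e-3 * max(traj.sa_mm[-1], 1)

    def test_solver_tolerance_refinement(self, fixture_network,
                                         fixture_modes):
        fams = two_mode_setup(fixture_network, fixture_modes)
        p = CyberneticParams(k_max=[6.0, 3.0], k_m=[20.0, 25.0], x_max=12.8,
                             e0=[0.95, 0.1])
        model = CyberneticModel(fixture_network, fams, p)
        a = model.simulate(self.init, 36.0, rtol=1e-6, atol=1e-8)
        b = model.simulate(self.init, 36.0, rtol=1e-7, atol=1e-9)
        for ca, cb in ((a.glc_mm[-1], b.glc_mm[-1]),
                       (a.sa_mm[-1], b.sa_mm[-1]),
                       (a.biomass[-1], b.biomass[-1])):
            assert abs(ca - cb) <= 1e-3 * max(abs(cb), 1.0)

    def test_negative_initial_rejected(self, fixture_network, fixture_modes):
        fams = two_mode_setup(fixture_network, fixture_modes)
        p = CyberneticParams(k_max=[1.0, 1.0], k_m=[10.0, 10.0])
        model = CyberneticModel(fixture_network, fams, p)
        with pytest.raises(ValueError):
            model.simulate({"glc_mm": -5.0, "ye_mm": 1.0, "biomass": 0.1},
                           10.0)


def _mode_co2_carbon(network, mode):
    """Carbon vented as CO2 by a mode (flux through the CO2 sink)."""
    return mode.net_flux.get("CO2out", 0.0)


class TestFluxReconstruction:
    def test_single_mode_percents_match_stoichiometry(self, fixture_network,
                                                      fixture_modes):
        fams = two_mode_setup(fixture_network, fixture_modes)
        only_m = [EMFamily(phase="M", modes=fams[0].modes)]
        mode = fams[0].modes[0]
        p = CyberneticParams(k_max=[5.0], k_m=[20.0], x_max=12.8, e0=[0.9])
        model = CyberneticModel(fixture_network, only_m, p)
        # short horizon: the mixed mode stalls once yeast extract runs out
        traj = model.simulate({"glc_mm": 500.0, "ye_mm": 200.0,
                               "biomass": 0.3}, 2.0, n_out=17)
        snap = reconstruct_fluxes(model, traj, 0.25, phase="IEx")
        assert snap.percent is not None
        galp = mode.net_flux["GalP"]
        for rid, w in mode.net_flux.items():
            assert snap.percent[rid] == pytest.approx(100.0 * w / galp,
                                                      rel=1e-9)
        assert snap.percent["GalP"] == pytest.approx(100.0)

    def test_two_mode_mixture_arithmetic(self, fixture_network,
                                         fixture_modes):
        fams = two_mode_setup(fixture_network, fixture_modes)
        p = CyberneticParams(k_max=[6.0, 3.0], k_m=[20.0, 25.0], x_max=12.8,
                             e0=[0.95, 0.1])
        model = CyberneticModel(fixture_network, fams, p)
        traj = model.simulate({"glc_mm": 555.0, "ye_mm": 200.0,
                               "biomass": 0.25}, 20.0, n_out=41)
        t = 10.0
        snap = reconstruct_fluxes(model, traj, t)
        st = traj.state_at(t)
        q = st["q"]
        hand = {}
        for qi, mode in zip(q, model.modes):
            for rid, w in mode.net_flux.items():
                hand[rid] = hand.get(rid, 0.0) + w * qi
        for rid, val in hand.items():
            assert snap.fluxes[rid] == pytest.approx(val, rel=1e-9)

    def test_zero_uptake_flagged(self, fixture_network, fixture_modes):
        fams = two_mode_setup(fixture_network, fixture_modes)
        p = CyberneticParams(k_max=[0.0, 0.0], k_m=[10.0, 10.0])
        model = CyberneticModel(fixture_network, fams, p)
        traj = model.simulate({"glc_mm": 100.0, "ye_mm": 10.0,
                               "biomass": 0.2}, 5.0, n_out=6)
        snap = reconstruct_fluxes(model, traj, 2.0)
        assert snap.percent is None and snap.flags


class TestPhaseTimes:
    def test_logistic_second_derivative_maximum(self):
        """For a pure logistic the acceleration peaks where X/Xmax =
        1/2 - sqrt(3)/6 (analytic maximization)."""
        x0, xm, mu = 0.25, 12.8, 0.58
        t = np.linspace(0, 36, 3601)
        x = logistic_biomass(t, x0, xm, mu)
        out = phase_times(t, x, x_max=xm)
        frac = 0.5 - np.sqrt(3) / 6
        x_at = frac * xm
        t_expect = np.log(x_at * (xm - x0) / (x0 * (xm - x_at))) / mu
        assert out["MEx"] == pytest.approx(t_expect, abs=0.05)
        assert out["IEx"] == pytest.approx(out["MEx"] / 2, rel=1e-12)

    def test_mst_midpoint(self):
        x0, xm, mu = 0.25, 10.0, 0.6
        t = np.linspace(0, 40, 4001)
        x = logistic_biomass(t, x0, xm, mu)
        out = phase_times(t, x, x_max=xm)
        onset = t[np.flatnonzero(x >= 0.95 * xm)[0]]
        assert out["MSt"] == pytest.approx((onset + 40.0) / 2, abs=0.02)

    def test_no_stationary_flagged(self):
        t = np.linspace(0, 5, 100)
        x = logistic_biomass(t, 0.25, 10.0, 0.3)
        out = phase_times(t, x, x_max=10.0)
        assert out["MSt"] is None and out["flags"]


class TestFluxSurfaces:
    def test_constant_field_flat(self, fixture_network, fixture_modes):
        from shikflux.cybernetic import FluxSnapshot, flux_surfaces

        snaps = {}
        for g in (75, 100, 125):
            for y in (15, 30, 45):
                snaps[(g, y)] = FluxSnapshot(
                    phase="IEx", time=3.0, fluxes={"GalP": 1.0},
                    percent={"GalP": 100.0, "Pgi": 20.0})
        out = flux_surfaces(snaps, "IEx")
        surf, _ = out["Pgi"]
        np.testing.assert_allclose(surf.coefficients[1:], 0.0, atol=1e-8)
        assert surf.coefficients[0] == pytest.approx(20.0, abs=1e-6)
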