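import numpy as np
import pytest

from shikflux import synth, physio, pipeline
from shikflux.network import load_fixture_network
from shikflux.efm import enumerate_efms


@pytest.fixture(scope="session")
def fixture_network():
    return load_fixture_network()


@pytest.fixture(scope="session")
def fixture_modes(fixture_network):
    """Full elementary-mode set of the packaged network (enumerated once)."""
    return enumerate_efms(fixture_network)


@pytest.fixture(scope="session")
def central_truth():
    return synth.default_truth_params(synth.DesignPoint(100.0, 30.0))


@pytest.fixture(scope="session")
def central_series_clean(central_truth):
    sched = synth.SamplingSchedule.default()
    return synth.simulate_experiment(central_truth, sched,
                                     synth.NoiseSpec(cv=0.0, seed=0),
                                     glc0=100.0)


@pytest.fixture(scope="session")
def reduced_families(fixture_network, fixture_modes, central_truth):
    """Pipeline-reduced model families (6 exponential + 3 stationary modes)."""
    targets = pipeline.central_yield_targets(central_truth)
    return pipeline.build_reduced_families(fixture_network, targets,
                                           modes=fixture_modes)


@pytest.fixture(scope="session")
def ga_recovery(fixture_network, reduced_families):
    """One zero-noise GA self-recovery experiment shared across tests.

    Generates a trajectory from a known 9-mode parameter set, fits it with
    the genetic algorithm from the standard initial values, and returns the
    truth, the fit and the per-channel adequacy statistics.
    """
    from shikflux import cybernetic, ga

    fam_m = reduced_families["families"]["M"]["model"]
    fam_g = reduced_families["families"]["G"]["model"]
    n_m, n_g = len(fam_m), len(fam_g)
    m = n_m + n_g
    true_kmax = np.concatenate([np.linspace(4.0, 8.0, n_m),
                                np.linspace(1.5, 3.0, n_g)])
    true_km = np.concatenate([np.linspace(15.0, 40.0, n_m),
                              np.linspace(10.0, 30.0, n_g)])
    e0 = cybernetic.default_e0(n_m, n_g)
    mm = cybernetic.MOLAR_MASS_G_PER_MMOL
    init = {"glc_mm": 100.0 / mm["GLC"], "ye_mm": 30.0 / mm["YE"],
            "biomass": 0.25}
    sample_t = synth.SamplingSchedule.default().as_array()

    def channels_of(theta):
        p = cybernetic.CyberneticParams(k_max=theta[:m], k_m=theta[m:],
                                        x_max=12.80, e0=e0)
        model = cybernetic.CyberneticModel(fixture_network, [fam_m, fam_g], p)
        traj = model.simulate(init, 36.0, n_out=73, method="rk4",
                              dt=0.1, compute_allocation=False)
        ch = model.observed_channels(traj)
        return {k: np.interp(sample_t, traj.times, v) for k, v in ch.items()}

    theta_true = np.concatenate([true_kmax, true_km])
    truth_channels = channels_of(theta_true)
    objective = ga.sse_objective(channels_of, truth_channels)
    theta_fit, trace = ga.run_ga(objective, m, ga.GAConfig(seed=11))
    fit_channels = channels_of(theta_fit)
    stats = {name: physio.fit_statistics(fit_channels[name],
                                         truth_channels[name])
             for name in truth_channels}
    return {"m": m, "theta_true": theta_true, "theta_fit": theta_fit,
            "trace": trace, "stats": stats}
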