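"""Simulator: integration quality, fold-change mapping, prediction bands."""
import numpy as np
import pytest

from pistar import (
    EnvironmentProtocol,
    ModelVariant,
    ObservableConfig,
    Trajectory,
    default_parameters,
    prediction_intervals,
    simulate,
    to_fold_change,
)
from pistar.simulate import TARGETS, fold_change_frame


@pytest.fixture(scope="module")
def pstr_rp_params():
    return default_parameters(ModelVariant("PSTR", rp=True))


def test_plus_pi_curves_are_flat(piom, piom_params):
    protocol = EnvironmentProtocol.plus_pi(264.0)
    traj = simulate(piom_params, piom, protocol, np.linspace(0, 264, 9))
    curves = to_fold_change(traj)
    for target in TARGETS:
        assert np.abs(curves[target].fold_change - 1.0).max() < 0.01


def test_ips1_monotone_and_tolerance_insensitive(pstr_rp_params):
    """Starved IPS1 rises monotonically; halving the integrator tolerance
    changes the reported fold changes by < 1e-4 relative."""
    variant = ModelVariant("PSTR", rp=True)
    protocol = EnvironmentProtocol.starvation(264.0)
    grid = np.linspace(0, 264, 23)
    t1 = simulate(pstr_rp_params, variant, protocol, grid, rtol=1e-8)
    t2 = simulate(pstr_rp_params, variant, protocol, grid, rtol=5e-9)
    c1, c2 = to_fold_change(t1), to_fold_change(t2)
    assert np.all(np.diff(c1["IPS1"].fold_change) > 0)
    for target in TARGETS:
        rel = np.abs(c1[target].fold_change / c2[target].fold_change - 1.0)
        assert rel.max() < 1e-4


def test_fold_change_identity_and_homogeneity(piom, piom_params, piom_steady_state):
    protocol = EnvironmentProtocol.plus_pi(10.0)
    traj = simulate(piom_params, piom, protocol, np.array([0.0, 5.0, 10.0]),
                    y0=piom_steady_state)
    same = to_fold_change(traj, reference=traj)
    for target in TARGETS:
        assert np.allclose(same[target].fold_change, 1.0, atol=1e-8)
    doubled = Trajectory(traj.time, 2.0 * traj.states, traj.variant,
                         traj.protocol, traj.species)
    ratio = to_fold_change(doubled, reference=traj.states[0])
    for target in TARGETS:
        assert np.allclose(ratio[target].fold_change, 2.0 * same[target].fold_change,
                           rtol=1e-10)


def test_pho2_halves_by_264h_of_starvation(pstr_rp_params):
    """Calibration target: PHO2 mRNA at ~half its +Pi level after 11 days."""
    variant = ModelVariant("PSTR", rp=True)
    traj = simulate(pstr_rp_params, variant, EnvironmentProtocol.starvation(264.0),
                    np.array([0.0, 264.0]))
    fold = to_fold_change(traj)["PHO2"].fold_change[-1]
    assert 0.35 < fold < 0.65


def test_observable_config_switches_complex_inclusion(pstr_rp_params):
    variant = ModelVariant("PSTR", rp=True)
    traj = simulate(pstr_rp_params, variant, EnvironmentProtocol.starvation(72.0),
                    np.array([0.0, 72.0]))
    total = to_fold_change(traj, config=ObservableConfig(True, True))
    free = to_fold_change(traj, config=ObservableConfig(False, False))
    # under starvation nearly all miR399 is sequestered in the complex
    assert total["miR399"].fold_change[-1] > free["miR399"].fold_change[-1]


def test_rp_repletion_collapses_ips1(pstr_rp_params):
    variant = ModelVariant("PSTR", rp=True)
    protocol = EnvironmentProtocol.repletion(264.0, 292.0)
    grid = np.array([0.0, 263.9, 288.0])
    curves = to_fold_change(simulate(pstr_rp_params, variant, protocol, grid))
    pre, post = curves["IPS1"].fold_change[1], curves["IPS1"].fold_change[2]
    assert post < 0.1 * pre


def test_grid_outside_horizon_rejected(piom, piom_params):
    with pytest.raises(ValueError, match="horizon"):
        simulate(piom_params, piom, EnvironmentProtocol.plus_pi(10.0),
                 np.array([0.0, 20.0]))


# ---------------------------------------------------------------------------
# prediction intervals
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def interval_inputs(pstr_rp_params):
    variant = ModelVariant("PSTR", rp=True)
    protocol = EnvironmentProtocol.starvation(120.0)
    grid = np.array([0.0, 24.0, 72.0, 120.0])
    sd = {"d2": 0.1 * pstr_rp_params.value("d2"), "k_m": 0.1 * pstr_rp_params.value("k_m")}
    return pstr_rp_params, variant, protocol, grid, sd


def test_zero_sd_bands_collapse_to_mean(interval_inputs):
    params, variant, protocol, grid, _ = interval_inputs
    sd = {"d2": 0.0, "k_m": 0.0}
    bands = prediction_intervals((params, sd), variant, protocol, grid,
                                 levels=(80, 100), n_samples=100, seed=1)
    assert np.allclose(bands["lower"], bands["upper"], rtol=1e-12)
    assert np.allclose(bands["lower"], bands["mean"], rtol=1e-12)


def test_band_nesting_and_reproducibility(interval_inputs):
    params, variant, protocol, grid, sd = interval_inputs
    kw = dict(levels=(80, 95, 100), n_samples=120, seed=3)
    bands = prediction_intervals((params, sd), variant, protocol, grid, **kw)
    again = prediction_intervals((params, sd), variant, protocol, grid, **kw)
    assert bands.equals(again)  # bit-reproducible given the seed
    wide = bands.pivot_table(index=["target", "time_h"], columns="level",
                             values=["lower", "upper"])
    assert (wide[("lower", 100)] <= wide[("lower", 95)] + 1e-12).all()
    assert (wide[("lower", 95)] <= wide[("lower", 80)] + 1e-12).all()
    assert (wide[("upper", 80)] <= wide[("upper", 95)] + 1e-12).all()
    assert (wide[("upper", 95)] <= wide[("upper", 100)] + 1e-12).all()


def test_band_coverage_close_to_nominal(interval_inputs):
    """Trajectories drawn from the fitted parameter distribution should fall
    inside the 80% band about 80% of the time (pointwise)."""
    params, variant, protocol, grid, sd = interval_inputs
    bands = prediction_intervals((params, sd), variant, protocol, grid,
                                 levels=(80,), n_samples=250, seed=11)
    rng = np.random.default_rng(5)
    from pistar.simulate import to_fold_change as tfc, simulate as sim_fn

    hits, total = 0, 0
    b80 = bands.set_index(["target", "time_h"])
    for _ in range(150):
        draws = {k: rng.normal(params.value(k), s) for k, s in sd.items()}
        draws = {k: float(np.clip(v, params[k].lower, params[k].upper))
                 for k, v in draws.items()}
        curves = tfc(sim_fn(params.with_values(**draws), variant, protocol, grid,
                            rtol=1e-6, atol=1e-9))
        for target in TARGETS:
            for j, t in enumerate(grid[1:], start=1):
                lo = b80.loc[(target, t), "lower"]
                hi = b80.loc[(target, t), "upper"]
                hits += int(lo <= curves[target].fold_change[j] <= hi)
                total += 1
    coverage = hits / total
    assert 0.70 <= coverage <= 0.90


def test_interval_input_validation(interval_inputs):
    params, variant, protocol, grid, sd = interval_inputs
    with pytest.raises(ValueError, match="n_samples"):
        prediction_intervals((params, sd), variant, protocol, grid, n_samples=10)


def test_fold_change_frame_is_tidy(piom, piom_params):
    traj = simulate(piom_params, piom, EnvironmentProtocol.plus_pi(5.0),
                    np.array([0.0, 5.0]))
    df = fold_change_frame(to_fold_change(traj))
    assert list(df.columns) == ["time_h", "target", "fold_change"]
    assert set(df["target"]) == set(TARGETS)
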