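"""Core model: right-hand sides, variants, protocols, steady states."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import affine_ode_solution
from pistar import (
    EnvironmentProtocol,
    ModelVariant,
    Param,
    ParameterSet,
    default_parameters,
    external_pi,
    initial_steady_state,
    neutral_overrides,
    rhs,
    rp_degradation,
    simulate,
    variant_terms,
)
from pistar.model import EXTRA_FREE_PARAMETERS, SPECIES, make_rhs, variant_parameter_count
from scipy.integrate import solve_ivp

ALL_HYPOTHESES = ["PDTA", "PDRP", "PSMD", "PSTR", "PSRA"]


# ---------------------------------------------------------------------------
# steady state and basic contracts
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("hypothesis,rp", [("PIOM", False), ("PSTR", True), ("PDRP", False)])
def test_steady_state_is_fixed_point_and_persists(hypothesis, rp):
    """Under constant +Pi the fitted steady state neither moves (||rhs|| small)
    nor drifts more than 1% over 264 h of integration."""
    variant = ModelVariant(hypothesis, rp=rp)
    params = default_parameters(variant)
    ss = initial_steady_state(params, variant)
    protocol = EnvironmentProtocol.plus_pi(264.0)
    assert np.max(np.abs(rhs(ss, 0.0, params, variant, protocol))) < 1e-6
    traj = simulate(params, variant, protocol, np.linspace(0, 264, 12), y0=ss)
    drift = np.abs(traj.states / ss - 1.0)
    assert drift.max() < 0.01


def test_rhs_contract_violations(piom, piom_params):
    protocol = EnvironmentProtocol.plus_pi(10.0)
    good = np.ones(10)
    with pytest.raises(ValueError, match="negative"):
        rhs(good - 2.0, 0.0, piom_params, piom, protocol)
    with pytest.raises(ValueError, match="components"):
        rhs(np.ones(9), 0.0, piom_params, piom, protocol)
    bad_params = piom_params.copy()
    bad_params["d7"].value = -0.1
    with pytest.raises(ValueError, match="positive"):
        rhs(good, 0.0, bad_params, piom, protocol)


def test_imc_decays_by_mass_action_without_partners(piom, piom_params):
    """With no free IPS1 or miR399, the complex can only dissociate/decay:
    d(IMC)/dt = -(k_off + d7)·IMC."""
    state = np.zeros(10)
    state[SPECIES.index("IMC")] = 2.0
    state[SPECIES.index("CytoPi")] = piom_params.value("CytoPi0")
    dy = rhs(state, 0.0, piom_params, piom, EnvironmentProtocol.plus_pi(10.0))
    expected = -(piom_params.value("k7_rev") + piom_params.value("d7")) * 2.0
    assert dy[SPECIES.index("IMC")] == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def test_reduced_binding_subsystem_matches_matrix_exponential(piom, piom_params):
    """The (IPS1, IMC) subsystem with clamped miR399 and PHR2a is linear;
    the model's algebra must agree with the closed-form solution."""
    v = piom_params.values_dict()
    M, phr2a, C = 0.8, 0.05, v["CytoPi0"]
    k7h = v["k7"] * 3600.0
    synth = v["m8"] * phr2a ** v["r"] / (v["K8"] ** v["r"] + phr2a ** v["r"])
    A = np.array([
        [-(v["d7"] + k7h * M), v["k7_rev"]],
        [k7h * M, -(v["k7_rev"] + v["d7"])],
    ])
    b = np.array([synth, 0.0])
    z0 = np.array([3.0, 0.5])

    f_full = make_rhs(piom_params, piom, ext_level=320.0)

    def g(t, z):
        y = np.zeros(10)
        y[SPECIES.index("PHR2a")] = phr2a
        y[SPECIES.index("miR399")] = M
        y[SPECIES.index("CytoPi")] = C
        y[SPECIES.index("IPS1")], y[SPECIES.index("IMC")] = z
        dy = f_full(t, y)
        return [dy[SPECIES.index("IPS1")], dy[SPECIES.index("IMC")]]

    t_end = 12.0
    sol = solve_ivp(g, (0.0, t_end), z0, rtol=1e-12, atol=1e-14, dense_output=False,
                    t_eval=[t_end])
    exact = affine_ode_solution(A, b, z0, t_end)
    assert np.allclose(sol.y[:, -1], exact, rtol=1e-8)


def test_psmd_regulator_decays_to_repressed_level_monotonically():
    """At high constant CytoPi the PsMD binder Z relaxes monotonically to its
    repressed steady state; the model row must match the scalar closed form."""
    variant = ModelVariant("PSMD")
    params = default_parameters(variant)
    v = params.values_dict()
    C, P = 50.0, 1.0  # CytoPi >> K_zc, clamped PHO2m
    f_full = make_rhs(params, variant, ext_level=320.0)

    def dz(t, z):
        y = np.zeros(11)
        y[SPECIES.index("PHO2m")] = P
        y[SPECIES.index("CytoPi")] = C
        y[10] = z[0]
        return [f_full(t, y)[10]]

    lam = v["d_z"] + v["k_zm"] * P / (1.0 + P / v["K_mz"])
    hill = v["K_zc"] ** v["h_zc"] / (v["K_zc"] ** v["h_zc"] + C ** v["h_zc"])
    z_ss = (v["m_z0"] + v["m_z"] * hill) / lam
    z0 = 1.0
    t_eval = np.linspace(0.0, 10.0, 30)
    sol = solve_ivp(dz, (0.0, 10.0), [z0], rtol=1e-11, atol=1e-13, t_eval=t_eval)
    exact = z_ss + (z0 - z_ss) * np.exp(-lam * t_eval)
    assert np.allclose(sol.y[0], exact, rtol=1e-7, atol=1e-10)
    assert np.all(np.diff(sol.y[0]) < 0)  # monotone decay toward z_ss < z0


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("hypothesis", ALL_HYPOTHESES)
def test_variant_with_neutral_extras_reproduces_base_model(hypothesis):
    variant = ModelVariant(hypothesis)
    params = neutral_overrides(variant, default_parameters(variant))
    base = ModelVariant("PIOM")
    base_params = default_parameters(base)
    grid = np.array([0.0, 3.0, 12.0, 48.0, 120.0, 264.0])
    protocol = EnvironmentProtocol.starvation(264.0)
    t_var = simulate(params, variant, protocol, grid)
    t_base = simulate(base_params, base, protocol, grid)
    core = t_var.states[:, :10]
    assert np.allclose(core, t_base.states, rtol=1e-6, atol=1e-9)


@pytest.mark.parametrize(
    "hypothesis,k", [(h, k) for h, k in EXTRA_FREE_PARAMETERS.items() if h != "PIOM"]
)
def test_extra_free_parameter_counts(hypothesis, k):
    variant = ModelVariant(hypothesis)
    base = ModelVariant("PIOM")
    assert variant_parameter_count(variant) - variant_parameter_count(base) == k


def test_pstr_synthesis_reduces_to_basal_when_unrepressed():
    """With Z = 0 and TA at its unrepressed steady state the PsTR promoter
    term equals the base model's basal PHO2 synthesis."""
    variant = ModelVariant("PSTR")
    params = neutral_overrides(variant, default_parameters(variant))
    v = params.values_dict()
    state = np.zeros(12)
    state[SPECIES.index("CytoPi")] = v["CytoPi0"]
    state[10] = v["m_ta"] / v["d_ta"]  # unrepressed TA steady state
    state[11] = 0.0  # no repressor
    delta = variant_terms("PSTR", state, params, ext_level=320.0)
    assert delta[SPECIES.index("PHO2m")] == pytest.approx(0.0, abs=1e-10)


def test_variant_terms_rejects_base_model(piom_params):
    with pytest.raises(ValueError):
        variant_terms("PIOM", np.zeros(10), piom_params)
    with pytest.raises(ValueError):
        ModelVariant("NOPE")


# ---------------------------------------------------------------------------
# conservation and non-negativity
# ---------------------------------------------------------------------------

def test_binding_subsystem_conservation(piom):
    """With synthesis and decay of IPS1/miR399/IMC switched off, the sums
    IPS1+IMC and miR399+IMC are conserved along the trajectory."""
    params = default_parameters(piom).with_values(
        m3=1e-30, m3b=1e-30, m8=1e-30, d3=1e-30, d7=1e-30
    )
    y0 = initial_steady_state(default_parameters(piom), piom)
    y0[SPECIES.index("IPS1")] = 1.0
    y0[SPECIES.index("miR399")] = 0.8
    y0[SPECIES.index("IMC")] = 0.3
    traj = simulate(params, piom, EnvironmentProtocol.starvation(50.0),
                    np.linspace(0, 50, 11), y0=y0)
    ips1_tot = traj["IPS1"] + traj["IMC"]
    mir_tot = traj["miR399"] + traj["IMC"]
    assert np.allclose(ips1_tot, ips1_tot[0], rtol=1e-7)
    assert np.allclose(mir_tot, mir_tot[0], rtol=1e-7)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_trajectories_stay_non_negative_under_perturbed_parameters(seed, pstr_rp):
    rng = np.random.default_rng(seed)
    params = default_parameters(pstr_rp)
    factors = {n: float(np.exp(rng.normal(0.0, 0.2)))
               for n in params if n not in ("q", "r", "h2", "h9", "h10",
                                            "h_ta", "h_zc", "h_zr", "h_r", "h_za")}
    perturbed = params.with_values(**{n: params.value(n) * f for n, f in factors.items()})
    protocol = EnvironmentProtocol.repletion(120.0, 200.0)
    traj = simulate(perturbed, pstr_rp, protocol, np.linspace(0, 200, 41), rtol=1e-8)
    assert traj.states.min() >= -1e-9


# ---------------------------------------------------------------------------
# RP modification and protocols
# ---------------------------------------------------------------------------

def test_rp_degradation_normalisation_and_limits():
    assert rp_degradation(0.1, 10.0, 10.0) == pytest.approx(0.1)
    assert rp_degradation(0.1, 10.0, 0.0) == 0.0
    assert rp_degradation(0.1, 10.0, 5.0) == pytest.approx(0.05)
    with pytest.raises(ValueError):
        rp_degradation(0.1, 0.0, 5.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    d7=st.floats(1e-3, 10.0),
    c0=st.floats(1e-2, 100.0),
    c_hi=st.floats(0.0, 200.0),
    drop=st.floats(0.0, 1.0),
)
def test_rp_degradation_monotone_in_cytopi(d7, c0, c_hi, drop):
    """Lowering cytosolic Pi never increases the effective IPS1 decay rate."""
    c_lo = c_hi * drop
    assert rp_degradation(d7, c0, c_lo) <= rp_degradation(d7, c0, c_hi) + 1e-15


def test_external_pi_schedules_and_boundaries():
    starve = EnvironmentProtocol.starvation(264.0)
    assert external_pi(starve, 100.0) == 0.0
    repl = EnvironmentProtocol.repletion(264.0, 312.0)
    assert external_pi(repl, 270.0) == 320.0
    assert external_pi(repl, 264.0) == 320.0  # right-open boundary
    assert external_pi(repl, 263.999) == 0.0
    with pytest.raises(ValueError, match="horizon"):
        external_pi(repl, 400.0)
    with pytest.raises(ValueError, match="contiguous"):
        EnvironmentProtocol(((0.0, 10.0, 0.0), (11.0, 20.0, 320.0)))
    with pytest.raises(ValueError):
        EnvironmentProtocol(((0.0, 10.0, -5.0),))


# ---------------------------------------------------------------------------
# parameter container
# ---------------------------------------------------------------------------

def test_parameter_validation_rules():
    with pytest.raises(ValueError, match="positive"):
        ParameterSet({"m1": Param(-1.0)})
    with pytest.raises(ValueError, match="Hill"):
        ParameterSet({"q": Param(0.5, lower=0.1, upper=2.0)})
    ps = default_parameters()
    with pytest.raises(ValueError, match="fixed"):
        ps.set_free(["U"])
    with pytest.raises(KeyError):
        ps.set_free(["not_a_parameter"])
    round_trip = ParameterSet.from_dict(ps.to_dict())
    assert round_trip.values_dict() == ps.values_dict()
    assert round_trip.free_names() == ps.free_names()
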