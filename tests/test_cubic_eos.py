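"""PR EoS engine: pure parameters, volume roots, fugacities, equifugacity."""

import math

import numpy as np
import pytest

import sccosol as s
from sccosol import cubic_eos as ce
from sccosol import synthetic as sy
from sccosol.constants import P_ATM, R_GAS


# --- pure-component parameters ---------------------------------------------

def test_alpha_is_one_at_critical_point(study):
    card = study.solvent
    p = ce.pure_pr_params(card, card.critical_temperature)
    a_expected = 0.45724 * R_GAS**2 * card.critical_temperature**2 / (
        card.critical_pressure * 1e6
    )
    assert p.attraction == pytest.approx(a_expected, rel=1e-12)
    assert p.covolume == pytest.approx(
        0.07780 * R_GAS * card.critical_temperature / (card.critical_pressure * 1e6),
        rel=1e-12,
    )


def test_alpha_grows_with_acentric_factor(study):
    lo = s.SolventPropertyCard(44.0, 304.21, 7.383, 0.0)
    hi = s.SolventPropertyCard(44.0, 304.21, 7.383, 0.5)
    assert (
        ce.pure_pr_params(hi, 280.0).attraction
        > ce.pure_pr_params(lo, 280.0).attraction
    )
    assert ce.pure_pr_params(hi, 280.0).covolume == ce.pure_pr_params(lo, 280.0).covolume


def test_pure_params_positive_at_study_conditions(study):
    for t in study.temperatures:
        for card in (study.solvent, study.solute):
            p = ce.pure_pr_params(card, t)
            assert p.attraction > 0 and p.covolume > 0


# --- volume roots -----------------------------------------------------------

def test_roots_satisfy_pressure_equation(study):
    for rec in study:
        p = ce.pure_pr_params(study.solvent, rec.temperature)
        for v, _ in ce.solve_volume(
            rec.temperature, rec.pressure * 1e6, p.attraction, p.covolume
        ):
            back = R_GAS * rec.temperature / (v - p.covolume) - p.attraction / (
                v * (v + p.covolume) + p.covolume * (v - p.covolume)
            )
            assert back == pytest.approx(rec.pressure * 1e6, rel=1e-8)


def test_ideal_gas_limit(study):
    p = ce.pure_pr_params(study.solvent, 600.0)
    roots = ce.solve_volume(600.0, 1e3, p.attraction, p.covolume)
    assert len(roots) == 1
    v, label = roots[0]
    assert label == "fluid"
    assert 1e3 * v / (R_GAS * 600.0) == pytest.approx(1.0, abs=1e-3)


def test_co2_density_within_pr_bias_band(study):
    # PR underestimates dense-CO2 density; stay within 10% of the reference 769
    p = ce.pure_pr_params(study.solvent, 308.0)
    v = ce.solve_volume(308.0, 12e6, p.attraction, p.covolume)[0][0]
    rho = study.solvent.molar_mass * 1e-3 / v
    assert rho == pytest.approx(769.0, rel=0.10)


def test_three_root_region_labels(study):
    # subcritical CO2 below its vapor pressure shape: 280 K, 3 MPa
    p = ce.pure_pr_params(study.solvent, 280.0)
    roots = ce.solve_volume(280.0, 3e6, p.attraction, p.covolume)
    if len(roots) == 3:
        labels = [lab for _, lab in roots]
        assert labels == ["liquid", "unstable", "vapor"]
        vols = [v for v, _ in roots]
        assert vols == sorted(vols)


# --- fugacity coefficients --------------------------------------------------

def _fd_lnphi(temperature, pressure, x, ai, bi, rule, h=1e-6):
    a, b = ce.mixture_params(temperature, x, ai, bi, rule)
    v = ce.solve_volume(temperature, pressure, a, b)[0][0]
    z = pressure * v / (R_GAS * temperature)
    out = np.empty(2)
    for i in range(2):
        npp, nmm = x.copy(), x.copy()
        npp[i] += h
        nmm[i] -= h
        fp = ce._residual_helmholtz(temperature, v, npp, ai, bi, rule)
        fm = ce._residual_helmholtz(temperature, v, nmm, ai, bi, rule)
        out[i] = (fp - fm) / (2 * h) - math.log(z)
    return out


@pytest.mark.parametrize("x2", [1e-5, 0.01, 0.2])
def test_vdw_closed_form_matches_fd_oracle(study, pr_pair, x2):
    ai, bi = pr_pair
    rule = ce.MixingRuleSpec(kind="vdw", k12=-0.05)
    x = np.array([1.0 - x2, x2])
    closed = ce.fugacity_coefficients(308.0, 12e6, x, rule, ai, bi)
    fd = _fd_lnphi(308.0, 12e6, x, ai, bi, rule)
    assert np.abs(closed - fd).max() < 1e-6


def test_identical_components_indistinguishable(study):
    p = ce.pure_pr_params(study.solvent, 320.0)
    ai = np.array([p.attraction, p.attraction])
    bi = np.array([p.covolume, p.covolume])
    rule = ce.MixingRuleSpec(kind="vdw", k12=0.0)
    lnphi = ce.fugacity_coefficients(320.0, 10e6, np.array([0.3, 0.7]), rule, ai, bi)
    ln_f, v = ce.pure_fluid_state(study.solvent, 320.0, 10e6)
    pure_lnphi = ln_f - math.log(10e6)
    assert lnphi[0] == pytest.approx(pure_lnphi, abs=1e-9)
    assert lnphi[1] == pytest.approx(pure_lnphi, abs=1e-9)


@pytest.mark.parametrize("kind", ["vdw", "wong_sandler", "huron_vidal"])
def test_solvent_fugacity_reduces_to_pure_at_dilution(study, pr_pair, kind):
    ai, bi = pr_pair
    if kind == "vdw":
        rule = ce.MixingRuleSpec(kind="vdw", k12=0.02)
    else:
        rule = ce.MixingRuleSpec(
            kind=kind, ge_model=ce.GEModelSpec(kind="wilson", u12=500.0, u21=800.0)
        )
    x = np.array([1.0 - 1e-9, 1e-9])
    lnphi = ce.fugacity_coefficients(308.0, 12e6, x, rule, ai, bi)
    ln_f, _ = ce.pure_fluid_state(study.solvent, 308.0, 12e6)
    assert lnphi[0] == pytest.approx(ln_f - math.log(12e6), abs=1e-5)


def test_wilson_null_interaction_is_ideal():
    ge = ce.GEModelSpec(kind="wilson", u12=0.0, u21=0.0)
    assert ge.excess_gibbs(308.0, np.array([0.4, 0.6])) == 0.0


def test_ws_is_not_vdw(study, pr_pair):
    # regression guard: the two rules only coincide for identical components
    ai, bi = pr_pair
    x = np.array([0.95, 0.05])
    vdw = ce.fugacity_coefficients(
        308.0, 12e6, x, ce.MixingRuleSpec(kind="vdw", k12=0.0), ai, bi
    )
    ws = ce.fugacity_coefficients(
        308.0, 12e6, x,
        ce.MixingRuleSpec(kind="wong_sandler", ge_model=ce.GEModelSpec(kind="ideal")),
        ai, bi,
    )
    assert abs(vdw[1] - ws[1]) > 0.1


@pytest.mark.parametrize("kind", ["vdw", "wong_sandler"])
def test_gibbs_duhem(study, pr_pair, kind):
    # sum_i x_i d(ln phi_i)/dx2 = 0 at fixed T, P
    ai, bi = pr_pair
    rule = (
        ce.MixingRuleSpec(kind="vdw", k12=0.05)
        if kind == "vdw"
        else ce.MixingRuleSpec(
            kind="wong_sandler", ge_model=ce.GEModelSpec(kind="wilson", u12=300.0, u21=900.0)
        )
    )
    x2, dx = 0.05, 1e-5
    lo = ce.fugacity_coefficients(318.0, 15e6, np.array([1 - x2 + dx, x2 - dx]), rule, ai, bi)
    hi = ce.fugacity_coefficients(318.0, 15e6, np.array([1 - x2 - dx, x2 + dx]), rule, ai, bi)
    d = (hi - lo) / (2 * dx)
    gd = (1 - x2) * d[0] + x2 * d[1]
    scale = max(abs(d[0]), abs(d[1]), 1.0)
    assert abs(gd) / scale < 1e-3


def test_composition_must_sum_to_one(pr_pair):
    ai, bi = pr_pair
    with pytest.raises(ValueError):
        ce.fugacity_coefficients(
            308.0, 12e6, np.array([0.5, 0.6]), ce.MixingRuleSpec(kind="vdw"), ai, bi
        )


# --- solid fugacity ---------------------------------------------------------

def test_solid_equals_liquid_at_melting_point(study):
    card = study.solute
    vl = card.solid_molar_volume * 1e-6  # V_s = V_L kills the Poynting term
    f_l = 123.456
    f_s = ce.solid_fugacity(card, card.melt_temperature, 12e6, f_l, vl)
    assert f_s == pytest.approx(f_l, rel=1e-12)


def test_solid_below_liquid_below_melting(study):
    card = study.solute
    vl = card.solid_molar_volume * 1e-6
    f_s = ce.solid_fugacity(card, 308.0, 12e6, 1.0, vl)
    assert f_s < 1.0


def test_solid_fugacity_hand_substitution(study):
    card = study.solute
    t, p, f_l, vl = 308.0, 12e6, 2.5e-6, 5.2e-4
    dhm, tm = card.fusion_enthalpy * 1e3, card.melt_temperature
    hand = f_l * math.exp(
        dhm / (R_GAS * tm) * (1 - tm / t)
        + (card.solid_molar_volume * 1e-6 - vl) * (p - P_ATM) / (R_GAS * t)
    )
    assert ce.solid_fugacity(card, t, p, f_l, vl) == pytest.approx(hand, rel=1e-12)


# --- equifugacity solve -----------------------------------------------------

def test_fixed_point_property(study):
    rule = ce.MixingRuleSpec(kind="vdw", k12=0.085)
    res = ce.solve_solubility(study.solute, study.solvent, 308.0, 12.0, rule)
    assert res.converged
    assert 0 < res.mole_fraction < 1
    assert math.log(res.fluid_fugacity) == pytest.approx(
        math.log(res.solid_fugacity), abs=1e-7
    )


def test_brute_force_scan_agrees_with_solver(study, pr_pair):
    ai, bi = pr_pair
    rule = ce.MixingRuleSpec(kind="vdw", k12=0.085)
    res = ce.solve_solubility(study.solute, study.solvent, 308.0, 12.0, rule)
    ln_fs = math.log(res.solid_fugacity)
    ys = np.logspace(-9, -2, 600)

    def mismatch(y):
        lnphi = ce.fugacity_coefficients(308.0, 12e6, np.array([1 - y, y]), rule, ai, bi)
        return abs(math.log(y) + lnphi[1] + math.log(12e6) - ln_fs)

    best = ys[int(np.argmin([mismatch(y) for y in ys]))]
    # agreement within one grid spacing (factor 10^(7/599))
    assert abs(math.log(best) - math.log(res.mole_fraction)) < math.log(10) * 7 / 599 * 1.5


def test_solubility_continuous_in_pressure(study, vdw_fit):
    # solubility rises with the initial density gain and stays continuous:
    # adjacent pressures never differ by an unbounded jump in ln y
    ys = [
        ce.solve_solubility(
            study.solute, study.solvent, 308.0, p, vdw_fit.mixing_rule
        ).mole_fraction
        for p in (12.0, 15.0, 18.0, 21.0, 24.0, 27.0)
    ]
    assert ys[1] > ys[0]
    steps = [abs(math.log(hi / lo)) for lo, hi in zip(ys, ys[1:])]
    assert max(steps) < 1.0


def test_k12_recovery_from_self_generated_data(study):
    truth = ce.MixingRuleSpec(kind="vdw", k12=0.08)
    spec = sy.SyntheticSpec(truth_model=truth, noise_sigma=0.0, replicates=1, seed=2)
    ds, _ = sy.generate(spec)
    fit = ce.fit_eos(ds, ce.MixingRuleSpec(kind="vdw"))
    assert abs(fit.mixing_rule.k12 - 0.08) < 1e-4
    assert fit.ald_y < 1e-5  # perfect predictor limit


def test_ald_perfect_predictor():
    y = np.array([1e-6, 5e-6, 2e-5])
    assert ce.ald(y, y) == 0.0
    assert ce.ald(y, 10.0 * y) == pytest.approx(1.0, rel=1e-12)


# --- Huron-Vidal pluggable excess-Gibbs suite -------------------------------

def test_hv_ideal_equals_wilson_null(study):
    ideal = ce.MixingRuleSpec(kind="huron_vidal", ge_model=ce.GEModelSpec(kind="ideal"))
    null = ce.MixingRuleSpec(
        kind="huron_vidal", ge_model=ce.GEModelSpec(kind="wilson", u12=0.0, u21=0.0)
    )
    y_a = ce.solve_solubility(study.solute, study.solvent, 318.0, 15.0, ideal)
    y_b = ce.solve_solubility(study.solute, study.solvent, 318.0, 15.0, null)
    assert y_a.mole_fraction == pytest.approx(y_b.mole_fraction, rel=1e-9)


def test_hv_accepts_user_callback(study):
    wilson = ce.GEModelSpec(kind="wilson", u12=1000.0, u21=2000.0)
    plugged = ce.GEModelSpec(
        kind="pluggable", function=lambda t, x: wilson.excess_gibbs(t, x)
    )
    a = ce.solve_solubility(
        study.solute, study.solvent, 318.0, 15.0,
        ce.MixingRuleSpec(kind="huron_vidal", ge_model=wilson),
    )
    b = ce.solve_solubility(
        study.solute, study.solvent, 318.0, 15.0,
        ce.MixingRuleSpec(kind="huron_vidal", ge_model=plugged),
    )
    assert a.mole_fraction == pytest.approx(b.mole_fraction, rel=1e-9)


def test_hv_solubility_is_finite_over_study_grid(study):
    rule = ce.MixingRuleSpec(
        kind="huron_vidal", ge_model=ce.GEModelSpec(kind="wilson", u12=500.0, u21=1500.0)
    )
    for rec in list(study)[::6]:
        res = ce.solve_solubility(
            study.solute, study.solvent, rec.temperature, rec.pressure, rule
        )
        assert res.converged and 0 < res.mole_fraction < 1
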