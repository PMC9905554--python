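"""Peng-Robinson solid-fluid equilibrium for solute solubility in ScCO2.

The solubility y2 of a heavy solid in supercritical CO2 follows from
equifugacity between the pure solid and the supercritical solution,

    y2 * phi2(T, P, y) * P = f_solid(T, P),

with the solid fugacity referenced to the hypothetical subcooled liquid:

    ln(f_S / f_L) = dH_m/(R T_m) (1 - T_m/T) + (V_s - V_L)(P - P_atm)/(R T).

The subcooled-liquid fugacity f_L and molar volume V_L come from the
liquid-like root of the pure-solute PR EoS at (T, P).  The supercritical
phase is described by the PR EoS with one of three mixing rules:

* van der Waals one-fluid (quadratic a with one binary parameter k12,
  linear b) -- fugacity coefficients in closed form;
* Wong-Sandler coupled to an excess-Gibbs model (C_WS = ln(sqrt(2)-1)/sqrt(2));
* Huron-Vidal coupled to an excess-Gibbs model (C_HV = ln 2, linear b).

For the excess-Gibbs-coupled rules the fugacity coefficients are obtained
from central finite differences of the total residual Helmholtz energy with
respect to mole numbers at fixed (T, V) -- numerically exact partial molar
properties validated against the closed-form vdW case.  The packaged excess
Gibbs models are Wilson (Lambda_ij = exp(-u_ij/RT), no molar-volume
prefactor) and ideal (G_E = 0); any callable g_e(T, x) can be plugged in.

All pressures in this module are Pa and volumes m^3/mol; the property-card
units (MPa, cm^3/mol, kJ/mol) are converted on entry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .constants import P_ATM, R_GAS
from .core_data import Dataset, SolutePropertyCard, SolventPropertyCard

SQRT2 = math.sqrt(2.0)
C_WS = math.log(SQRT2 - 1.0) / SQRT2  # ~ -0.62323
C_HV = math.log(2.0)


class ThermodynamicStateError(RuntimeError):
    """No physically admissible volume root at the requested state."""


class ConvergenceError(RuntimeError):
    """Equifugacity iteration did not converge; carries the iterate history."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


@dataclass(frozen=True)
class PurePRParams:
    """PR pure-component parameters at one temperature."""

    attraction: float  # a_i(T), Pa m^6 mol^-2
    covolume: float  # b_i, m^3 mol^-1


@dataclass(frozen=True)
class GEModelSpec:
    """Excess-Gibbs model for the WS/HV mixing rules."""

    kind: str = "wilson"  # "wilson", "ideal", or "pluggable"
    u12: float = 0.0  # J/mol
    u21: float = 0.0  # J/mol
    function: Callable[[float, np.ndarray], float] | None = None  # pluggable

    def excess_gibbs(self, temperature: float, x: np.ndarray) -> float:
        """Molar excess Gibbs energy, J/mol."""
        if self.kind == "ideal":
            return 0.0
        if self.kind == "pluggable":
            if self.function is None:
                raise ValueError("pluggable GE model needs a callable")
            return self.function(temperature, x)
        rt = R_GAS * temperature
        lam12 = math.exp(-self.u12 / rt)
        lam21 = math.exp(-self.u21 / rt)
        s1 = x[0] + x[1] * lam12
        s2 = x[1] + x[0] * lam21
        if s1 <= 0 or s2 <= 0:
            raise ThermodynamicStateError(
                "Wilson excess-Gibbs model evaluated outside its composition domain"
            )
        return -rt * (x[0] * math.log(s1) + x[1] * math.log(s2))


@dataclass(frozen=True)
class MixingRuleSpec:
    """Mixing-rule choice with its binary parameters."""

    kind: str  # "vdw", "wong_sandler", "huron_vidal"
    k12: float = 0.0
    ge_model: GEModelSpec | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("vdw", "wong_sandler", "huron_vidal"):
            raise ValueError(f"unknown mixing rule {self.kind!r}")
        if self.kind != "vdw" and self.ge_model is None:
            object.__setattr__(self, "ge_model", GEModelSpec(kind="wilson"))


@dataclass
class EquifugacityResult:
    mole_fraction: float
    solid_fugacity: float  # Pa
    fluid_fugacity: float  # Pa, solute fugacity in the SCF at the solution
    subcooled_liquid_fugacity: float  # Pa
    liquid_molar_volume: float  # m^3/mol
    iterations: int
    converged: bool


@dataclass
class EoSFit:
    mixing_rule: MixingRuleSpec
    aard_percent: float
    ald_y: float
    predictions: np.ndarray
    n_failed: int = 0
    optimizer_report: dict = field(default_factory=dict)


def kappa_pr(acentric_factor: float) -> float:
    """The 1976 PR kappa(omega) polynomial."""
    w = acentric_factor
    return 0.37464 + 1.54226 * w - 0.26992 * w * w


def pure_pr_params(
    card: SolutePropertyCard | SolventPropertyCard, temperature: float
) -> PurePRParams:
    """Standard PR a_i(T), b_i from critical constants and acentric factor."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    tc = card.critical_temperature
    pc = card.critical_pressure * 1e6  # MPa -> Pa
    if tc <= 0 or pc <= 0:
        raise ValueError("critical constants must be positive")
    alpha = (1.0 + kappa_pr(card.acentric_factor) * (1.0 - math.sqrt(temperature / tc))) ** 2
    a = 0.45724 * R_GAS**2 * tc**2 / pc * alpha
    b = 0.07780 * R_GAS * tc / pc
    return PurePRParams(attraction=a, covolume=b)


def solve_volume(
    temperature: float, pressure: float, a: float, b: float
) -> list[tuple[float, str]]:
    """Real molar-volume roots (m^3/mol) of the PR cubic at (T, P), with labels.

    Roots are ascending; with three roots the smallest is liquid-like and the
    largest vapor-like (the middle root is mechanically unstable).  Each root
    satisfies the pressure equation to 1e-8 relative.
    """
    if pressure <= 0:
        raise ValueError("pressure must be > 0")
    rt = R_GAS * temperature
    A = a * pressure / rt**2
    B = b * pressure / rt
    coeffs = [1.0, -(1.0 - B), A - 3.0 * B * B - 2.0 * B, -(A * B - B * B - B**3)]
    roots = np.roots(coeffs)
    zs = sorted(
        float(z.real)
        for z in roots
        if abs(z.imag) < 1e-9 * max(1.0, abs(z.real)) and z.real > B
    )
    if not zs:
        raise ThermodynamicStateError(
            f"no volume root above the covolume at T={temperature} K, P={pressure} Pa"
        )
    vols = [z * rt / pressure for z in zs]
    for v in vols:
        p_back = rt / (v - b) - a / (v * (v + b) + b * (v - b))
        if abs(p_back - pressure) > 1e-8 * pressure:
            raise ThermodynamicStateError(
                f"volume root failed the pressure residual check at T={temperature}"
            )
    if len(vols) == 1:
        return [(vols[0], "fluid")]
    labels = ["liquid"] + ["unstable"] * (len(vols) - 2) + ["vapor"]
    return list(zip(vols, labels))


def _lnphi_pure(temperature: float, pressure: float, a: float, b: float, volume: float) -> float:
    rt = R_GAS * temperature
    A = a * pressure / rt**2
    B = b * pressure / rt
    Z = pressure * volume / rt
    return (
        (Z - 1.0)
        - math.log(Z - B)
        - A / (2.0 * SQRT2 * B) * math.log((Z + (1 + SQRT2) * B) / (Z + (1 - SQRT2) * B))
    )


def pure_fluid_state(
    card, temperature: float, pressure: float, root: str = "stable"
) -> tuple[float, float]:
    """(ln fugacity [ln Pa], molar volume) of a pure fluid at (T, P).

    ``root`` selects "liquid" (smallest), "vapor" (largest) or "stable"
    (lowest Gibbs energy).
    """
    p = pure_pr_params(card, temperature)
    roots = solve_volume(temperature, pressure, p.attraction, p.covolume)
    candidates = [
        (v, _lnphi_pure(temperature, pressure, p.attraction, p.covolume, v))
        for v, lab in roots
        if lab != "unstable"
    ]
    if root == "liquid":
        v, lnphi = candidates[0]
    elif root == "vapor":
        v, lnphi = candidates[-1]
    else:
        v, lnphi = min(candidates, key=lambda c: c[1])
    return lnphi + math.log(pressure), v


def mixture_params(
    temperature: float,
    x: np.ndarray,
    ai: np.ndarray,
    bi: np.ndarray,
    rule: MixingRuleSpec,
) -> tuple[float, float]:
    """Mixture (a, b) under the selected mixing rule."""
    x = np.asarray(x, dtype=float)
    if rule.kind == "vdw":
        k = np.array([[0.0, rule.k12], [rule.k12, 0.0]])
        aij = np.sqrt(np.outer(ai, ai)) * (1.0 - k)
        a = float(x @ aij @ x)
        b = float(x @ bi)
        return a, b
    rt = R_GAS * temperature
    ge = rule.ge_model.excess_gibbs(temperature, x)
    if rule.kind == "huron_vidal":
        b = float(x @ bi)
        a = b * (float(x @ (ai / bi)) + ge / C_HV)
        return a, b
    # Wong-Sandler
    bij = 0.5 * (bi[:, None] + bi[None, :]) - np.sqrt(np.outer(ai, ai)) / rt
    q = float(x @ bij @ x)
    denom = 1.0 - float(x @ (ai / (bi * rt))) - ge / (C_WS * rt)
    b = q / denom
    if b <= 0:
        raise ThermodynamicStateError("Wong-Sandler covolume became non-positive")
    a = b * (float(x @ (ai / bi)) + ge / C_WS)
    return a, b


def _residual_helmholtz(
    temperature: float, volume_total: float, n: np.ndarray,
    ai: np.ndarray, bi: np.ndarray, rule: MixingRuleSpec,
) -> float:
    """A_res(T, V, n)/RT for the PR EoS under the mixing rule (extensive)."""
    ntot = float(np.sum(n))
    x = np.asarray(n, dtype=float) / ntot
    a, b = mixture_params(temperature, x, ai, bi, rule)
    bt = ntot * b
    at = ntot * ntot * a
    rt = R_GAS * temperature
    if volume_total <= bt:
        raise ThermodynamicStateError("total volume below mixture covolume")
    return float(
        -ntot * math.log((volume_total - bt) / volume_total)
        + at
        / (2.0 * SQRT2 * bt * rt)
        * math.log((volume_total + (1 - SQRT2) * bt) / (volume_total + (1 + SQRT2) * bt))
    )


def _lnphi_vdw_closed(
    temperature: float, pressure: float, x: np.ndarray,
    ai: np.ndarray, bi: np.ndarray, k12: float, volume: float,
) -> np.ndarray:
    rt = R_GAS * temperature
    k = np.array([[0.0, k12], [k12, 0.0]])
    aij = np.sqrt(np.outer(ai, ai)) * (1.0 - k)
    a = float(x @ aij @ x)
    b = float(x @ bi)
    A = a * pressure / rt**2
    B = b * pressure / rt
    Z = pressure * volume / rt
    term = math.log((Z + (1 + SQRT2) * B) / (Z + (1 - SQRT2) * B))
    return (
        bi / b * (Z - 1.0)
        - math.log(Z - B)
        - A / (2.0 * SQRT2 * B) * (2.0 * (aij @ x) / a - bi / b) * term
    )


def fugacity_coefficients(
    temperature: float,
    pressure: float,
    composition: Sequence[float],
    rule: MixingRuleSpec,
    ai: np.ndarray,
    bi: np.ndarray,
    fd_step: float = 1e-6,
) -> np.ndarray:
    """ln phi_i of each component in the mixture at (T, P, x).

    When the cubic admits several roots the one with the lowest total Gibbs
    energy (sum x_i ln phi_i) is used.  vdW uses the closed form; WS/HV use
    central finite differences of the residual Helmholtz energy at fixed
    (T, V) with step ``fd_step`` times total moles.
    """
    x = np.asarray(composition, dtype=float)
    if abs(float(x.sum()) - 1.0) > 1e-12:
        raise ValueError("composition must sum to 1")
    a, b = mixture_params(temperature, x, ai, bi, rule)
    roots = [v for v, lab in solve_volume(temperature, pressure, a, b) if lab != "unstable"]

    def lnphi_at(volume: float) -> np.ndarray:
        if rule.kind == "vdw":
            return _lnphi_vdw_closed(temperature, pressure, x, ai, bi, rule.k12, volume)
        n = x.copy()
        h = fd_step * float(n.sum())
        z = pressure * volume / (R_GAS * temperature * float(n.sum()))
        out = np.empty(2)
        for i in range(2):
            np_, nm = n.copy(), n.copy()
            np_[i] += h
            nm[i] -= h
            fp = _residual_helmholtz(temperature, volume, np_, ai, bi, rule)
            if nm[i] > 0:
                fm = _residual_helmholtz(temperature, volume, nm, ai, bi, rule)
                out[i] = (fp - fm) / (2.0 * h) - math.log(z)
            else:
                # trace component: one-sided difference stays in the
                # excess-Gibbs composition domain
                f0 = _residual_helmholtz(temperature, volume, n, ai, bi, rule)
                out[i] = (fp - f0) / h - math.log(z)
        return out

    best = None
    for v in roots:
        lnphi = lnphi_at(v)
        g = float(x @ lnphi)
        if best is None or g < best[0]:
            best = (g, lnphi)
    return best[1]


def solid_fugacity(
    card: SolutePropertyCard,
    temperature: float,
    pressure: float,
    subcooled_liquid_fugacity: float,
    liquid_molar_volume: float,
) -> float:
    """Pure-solid fugacity (Pa) from the subcooled-liquid reference.

    ``pressure`` in Pa, ``liquid_molar_volume`` in m^3/mol.
    """
    return math.exp(
        _ln_solid_over_liquid(card, temperature, pressure, liquid_molar_volume)
    ) * subcooled_liquid_fugacity


def _ln_solid_over_liquid(
    card: SolutePropertyCard, temperature: float, pressure: float, vl: float
) -> float:
    dhm = card.fusion_enthalpy * 1e3  # kJ/mol -> J/mol
    tm = card.melt_temperature
    vs = card.solid_molar_volume * 1e-6  # cm^3/mol -> m^3/mol
    fusion = dhm / (R_GAS * tm) * (1.0 - tm / temperature)
    poynting = (vs - vl) * (pressure - P_ATM) / (R_GAS * temperature)
    return fusion + poynting


def solve_solubility(
    solute: SolutePropertyCard,
    solvent: SolventPropertyCard,
    temperature: float,
    pressure_mpa: float,
    rule: MixingRuleSpec,
    y_initial: float = 1e-5,
    tol: float = 1e-10,
    max_iterations: int = 200,
    max_step: float = 2.0,
    noise_floor: float = 1e-8,
) -> EquifugacityResult:
    """Solve y2 such that y2 phi2(T, P, y) P = f_solid(T, P).

    Successive substitution in ln y; steps larger than ``max_step`` in ln y
    are damped to that length (the map is a strong contraction near the
    solution because phi2 barely depends on a trace solute, so full steps
    are safe once close).  Converged when |Delta ln y| < ``tol``, or when
    the step has stopped contracting while already below ``noise_floor`` --
    the finite-difference fugacity route for the excess-Gibbs mixing rules
    carries O(1e-9) numerical noise that a pure tolerance test cannot beat.
    """
    pressure = pressure_mpa * 1e6
    p1 = pure_pr_params(solvent, temperature)
    p2 = pure_pr_params(solute, temperature)
    ai = np.array([p1.attraction, p2.attraction])
    bi = np.array([p1.covolume, p2.covolume])
    ln_fl, vl = pure_fluid_state(solute, temperature, pressure, root="liquid")
    ln_fs = ln_fl + _ln_solid_over_liquid(solute, temperature, pressure, vl)

    lny = math.log(y_initial)
    history = [lny]
    converged = False
    iterations = 0
    prev_abs_step = math.inf
    for iterations in range(1, max_iterations + 1):
        y = math.exp(lny)
        lnphi = fugacity_coefficients(
            temperature, pressure, np.array([1.0 - y, y]), rule, ai, bi
        )
        lny_new = ln_fs - float(lnphi[1]) - math.log(pressure)
        step = lny_new - lny
        if abs(step) < tol or (
            abs(step) < noise_floor and abs(step) >= 0.25 * prev_abs_step
        ):
            lny = lny_new
            converged = True
            break
        prev_abs_step = abs(step)
        if abs(step) > max_step:
            step = math.copysign(max_step, step)
        lny = lny + step
        history.append(lny)
    if not converged:
        raise ConvergenceError(
            f"equifugacity did not converge at T={temperature} K, P={pressure_mpa} MPa",
            history,
        )
    y = math.exp(lny)
    return EquifugacityResult(
        mole_fraction=y,
        solid_fugacity=math.exp(ln_fs),
        fluid_fugacity=y * math.exp(float(lnphi[1])) * pressure,
        subcooled_liquid_fugacity=math.exp(ln_fl),
        liquid_molar_volume=vl,
        iterations=iterations,
        converged=converged,
    )


def ald(y_exp: Sequence[float], y_cal: Sequence[float]) -> float:
    """Average absolute deviation of log10 mole fraction."""
    y_exp = np.asarray(y_exp, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    if y_exp.shape != y_cal.shape:
        raise ValueError("y_exp and y_cal must have equal length")
    return float(np.mean(np.abs(np.log10(y_exp) - np.log10(y_cal))))


def predict_dataset(
    dataset: Dataset, rule: MixingRuleSpec, **solver_kwargs
) -> tuple[np.ndarray, int]:
    """Model mole fraction at every record; failures yield NaN and are counted."""
    out = np.full(len(dataset), np.nan)
    failed = 0
    for i, rec in enumerate(dataset):
        try:
            out[i] = solve_solubility(
                dataset.solute, dataset.solvent, rec.temperature, rec.pressure,
                rule, **solver_kwargs,
            ).mole_fraction
        except (ThermodynamicStateError, ConvergenceError) as exc:
            failed += 1
            warnings.warn(f"equifugacity failure, record {i} excluded: {exc}")
    return out, failed


@dataclass
class EoSOptimizerConfig:
    k12_bounds: tuple[float, float] = (-0.5, 0.5)
    u_bounds: tuple[float, float] = (-1e5, 1e5)
    restarts: int = 8  # multistart count for the 2-D Wilson search
    seed: int = 20230207
    xatol: float = 1e-7  # k12 search
    nm_maxiter: int = 200
    nm_fatol: float = 1e-5
    nm_xatol: float = 1.0  # J/mol scale


def fit_eos(
    dataset: Dataset,
    rule_template: MixingRuleSpec,
    config: EoSOptimizerConfig | None = None,
) -> EoSFit:
    """Regress the binary parameters of a mixing rule against ALD-y.

    vdW: bounded scalar search for k12.  WS/HV with a Wilson excess-Gibbs
    model: seeded multistart Nelder-Mead over (u12, u21).  Records where the
    equifugacity solve fails are excluded from the objective with a warning
    and reported in the fit.
    """
    config = config or EoSOptimizerConfig()
    if len(dataset) < 2:
        raise ValueError("need at least 2 records to regress binary parameters")
    y_exp = np.array([r.mole_fraction for r in dataset])

    def objective_rule(rule: MixingRuleSpec) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            y_cal, failed = predict_dataset(dataset, rule)
        ok = np.isfinite(y_cal) & (y_cal > 0)
        if not np.any(ok):
            return 1e6
        return ald(y_exp[ok], y_cal[ok]) + 10.0 * failed / len(dataset)

    if rule_template.kind == "vdw":
        res = optimize.minimize_scalar(
            lambda k: objective_rule(replace(rule_template, k12=float(k))),
            bounds=config.k12_bounds,
            method="bounded",
            options=dict(xatol=config.xatol),
        )
        best_rule = replace(rule_template, k12=float(res.x))
        report = dict(objective="ald_y", evaluations=int(res.nfev))
    else:
        if rule_template.ge_model is None or rule_template.ge_model.kind != "wilson":
            raise ValueError("binary-parameter regression needs a Wilson GE model")

        def with_u(u: np.ndarray) -> MixingRuleSpec:
            u = np.clip(u, *config.u_bounds)
            return replace(
                rule_template,
                ge_model=replace(rule_template.ge_model, u12=float(u[0]), u21=float(u[1])),
            )

        rng = np.random.default_rng(config.seed)
        lo, hi = config.u_bounds
        starts = [np.zeros(2)]
        starts += [rng.uniform(lo, hi, size=2) for _ in range(config.restarts - 1)]
        best = None
        for s in starts:
            res = optimize.minimize(
                lambda u: objective_rule(with_u(u)),
                s,
                method="Nelder-Mead",
                options=dict(
                    maxiter=config.nm_maxiter,
                    fatol=config.nm_fatol,
                    xatol=config.nm_xatol,
                ),
            )
            if best is None or res.fun < best.fun:
                best = res
        best_rule = with_u(best.x)
        report = dict(
            objective="ald_y", restarts=len(starts), seed=config.seed,
            evaluations=int(best.nfev),
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        y_cal, failed = predict_dataset(dataset, best_rule)
    ok = np.isfinite(y_cal) & (y_cal > 0)
    return EoSFit(
        mixing_rule=best_rule,
        aard_percent=float(np.mean(np.abs(y_exp[ok] - y_cal[ok]) / y_exp[ok]) * 100.0),
        ald_y=ald(y_exp[ok], y_cal[ok]),
        predictions=y_cal,
        n_failed=failed,
        optimizer_report=report,
    )
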