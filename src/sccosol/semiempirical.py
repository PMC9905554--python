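"""Density-based semi-empirical solubility correlations.

Ten classic correlation forms relate the solubility of a solid in
supercritical CO2 to temperature T (K), pure-CO2 density rho (kg m^-3) and
pressure P (bar inside every model form; the storage unit MPa is converted
here).  Each form is linear in its adjustable parameters after a log-type
transform of the response, which this module exploits: an exact linear
least-squares solution in the transformed space seeds a multistart
Nelder-Mead minimisation of the AARD% objective in mole-fraction space,

    AARD% = (100 / N) * sum |y_exp - y_cal| / y_exp .

The Chrastil form predicts mass solubility S (kg m^-3); its predictions are
converted to mole fraction through the sampling-loop relation with each
record's density before residuals are formed, so that all ten models share
one objective.

Two thermodynamic by-products are provided: dissolution enthalpies from the
Chrastil and Bartle temperature coefficients, and the linear-collapse
self-consistency test of the data under the Chrastil and MST transforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.interpolate import PchipInterpolator

from .constants import R_GAS
from .core_data import Dataset, SolubilityRecord

MPA_TO_BAR = 10.0


class FitError(RuntimeError):
    """Raised when no optimizer restart converged; carries the best-so-far fit."""

    def __init__(self, message: str, best_fit: "SemiEmpiricalFit | None" = None):
        super().__init__(message)
        self.best_fit = best_fit


@dataclass(frozen=True)
class SemiEmpiricalModelSpec:
    """One of the ten correlation forms."""

    model_id: str
    n_params: int
    response: str  # "mass_solubility_kg_m3" or "mole_fraction"
    reference_pressure: float = 1.0  # bar (Bartle only)
    reference_density: float = 700.0  # kg m^-3 (Bartle only)


@dataclass
class SemiEmpiricalFit:
    spec: SemiEmpiricalModelSpec
    parameters: np.ndarray
    aard_percent: float
    residuals: np.ndarray  # per-record relative deviations (y_exp - y_cal)/y_exp
    optimizer_report: dict = field(default_factory=dict)


@dataclass(frozen=True)
class EnthalpyEstimates:
    """Dissolution enthalpies in kJ/mol extracted from correlation fits."""

    total: float
    vaporization: float
    solvation: float
    gas_constant_used: float = R_GAS


@dataclass
class ConsistencyTestResult:
    model_id: str
    abscissa: np.ndarray
    ordinate: np.ndarray
    slope: float
    intercept: float
    r_squared: float


# --- model registry --------------------------------------------------------
# Each entry: (n_params, response kind, feature builder, observed transformed
# response, inverse transform to ln y).  Feature builders take (T, P_bar, rho)
# arrays and return the design matrix X such that the transformed response is
# X @ a.

def _ones(T):
    return np.ones_like(T)


_FEATURES: dict[str, Callable] = {
    "chrastil": lambda T, P, rho: np.column_stack([np.log(rho), 1 / T, _ones(T)]),
    "mst": lambda T, P, rho: np.column_stack([_ones(T), rho, T]),
    "kj": lambda T, P, rho: np.column_stack([_ones(T), rho, 1 / T]),
    "bartle": lambda T, P, rho: np.column_stack([_ones(T), rho - 700.0, 1 / T]),
    "bian": lambda T, P, rho: np.column_stack(
        [_ones(T), 1 / T, rho / T, np.log(rho), rho * np.log(rho)]
    ),
    "garlapati": lambda T, P, rho: np.column_stack(
        [_ones(T), np.log(rho), rho * np.log(rho), 1 / T, np.log(rho * T)]
    ),
    "keshmiri": lambda T, P, rho: np.column_stack(
        [_ones(T), 1 / T, P**2, np.log(rho), np.log(rho) / T]
    ),
    "khansary": lambda T, P, rho: np.column_stack(
        [1 / T, P, P**2 / T, np.log(rho), P * np.log(rho)]
    ),
    "sodeifian": lambda T, P, rho: np.column_stack(
        [
            _ones(T),
            P**2 / T,
            np.log(rho * T),
            rho * np.log(rho),
            P * np.log(T),
            np.log(rho) / T,
        ]
    ),
    "belghait": lambda T, P, rho: np.column_stack(
        [_ones(T), rho, rho**2, rho * T, T, T**2, np.log(rho), 1 / T]
    ),
}

_N_PARAMS = {
    "chrastil": 3, "mst": 3, "kj": 3, "bartle": 3,
    "bian": 5, "garlapati": 5, "keshmiri": 5, "khansary": 5,
    "sodeifian": 6, "belghait": 8,
}

MODEL_IDS = tuple(_N_PARAMS)


def model_spec(model_id: str) -> SemiEmpiricalModelSpec:
    if model_id not in _N_PARAMS:
        raise KeyError(f"unknown model {model_id!r}; choose from {MODEL_IDS}")
    response = "mass_solubility_kg_m3" if model_id == "chrastil" else "mole_fraction"
    return SemiEmpiricalModelSpec(model_id, _N_PARAMS[model_id], response)


def _arrays(dataset: Dataset) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    T = np.array([r.temperature for r in dataset])
    P = np.array([r.pressure for r in dataset]) * MPA_TO_BAR
    rho = np.array([r.co2_density for r in dataset])
    y = np.array([r.mole_fraction for r in dataset])
    return T, P, rho, y


def _observed_transform(model_id: str, T, P_bar, rho, y, S):
    """The transformed response g such that the model states g = X @ a."""
    if model_id == "chrastil":
        return np.log(S)
    if model_id == "mst":
        return T * np.log(y * P_bar)
    if model_id == "bartle":
        return np.log(y * P_bar / 1.0)
    return np.log(y)


def _ln_y_from_linear(model_id: str, g: np.ndarray, T, P_bar, rho, solute=None, solvent=None):
    """Invert the transformed model value g = X @ a to ln y."""
    if model_id == "chrastil":
        S = np.exp(g)  # kg m^-3 == g L^-1
        m_ratio = (S / solute.molar_mass) / (
            rho / solvent.molar_mass + S / solute.molar_mass
        )
        return np.log(m_ratio)
    if model_id == "mst":
        return g / T - np.log(P_bar)
    if model_id == "bartle":
        return g - np.log(P_bar)
    return g


def evaluate_model(
    spec: SemiEmpiricalModelSpec,
    parameters: Sequence[float],
    record: SolubilityRecord,
) -> float:
    """Predicted response of one record: S in kg m^-3 for Chrastil, else y."""
    parameters = np.asarray(parameters, dtype=float)
    if parameters.shape != (spec.n_params,):
        raise ValueError(
            f"{spec.model_id} expects {spec.n_params} parameters, got {parameters.shape}"
        )
    T = np.array([record.temperature])
    P = np.array([record.pressure * MPA_TO_BAR])
    rho = np.array([record.co2_density])
    if not record.co2_density > 0:
        raise ValueError("non-positive density")
    g = (_FEATURES[spec.model_id](T, P, rho) @ parameters).item()
    if spec.model_id == "chrastil":
        out = math.exp(g)
    elif spec.model_id == "mst":
        out = math.exp(g / record.temperature) / (record.pressure * MPA_TO_BAR)
    elif spec.model_id == "bartle":
        out = math.exp(g) * spec.reference_pressure / (record.pressure * MPA_TO_BAR)
    else:
        out = math.exp(g)
    if not math.isfinite(out):
        raise ValueError(f"{spec.model_id} evaluation produced a non-finite value")
    return out


def predict_mole_fractions(
    spec: SemiEmpiricalModelSpec, parameters: Sequence[float], dataset: Dataset
) -> np.ndarray:
    """Model-predicted mole fraction at every record of the dataset."""
    T, P, rho, _ = _arrays(dataset)
    g = _FEATURES[spec.model_id](T, P, rho) @ np.asarray(parameters, dtype=float)
    return np.exp(
        _ln_y_from_linear(spec.model_id, g, T, P, rho, dataset.solute, dataset.solvent)
    )


def aard(y_exp: Sequence[float], y_cal: Sequence[float]) -> float:
    """Average absolute relative deviation, in percent."""
    y_exp = np.asarray(y_exp, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    if y_exp.shape != y_cal.shape:
        raise ValueError("y_exp and y_cal must have equal length")
    if np.any(y_exp <= 0):
        raise ValueError("y_exp must be strictly positive")
    return float(np.mean(np.abs(y_exp - y_cal) / y_exp) * 100.0)


@dataclass
class OptimizerConfig:
    """Multistart Nelder-Mead settings for the AARD% objective."""

    restarts: int = 64
    seed: int = 20230207
    spread: float = 0.4  # relative scatter of the perturbed starts
    maxiter: int = 4000
    xatol: float = 1e-10
    fatol: float = 1e-12
    extra_starts: tuple = ()  # user-supplied starting vectors (unscaled)


def fit_model(
    spec: SemiEmpiricalModelSpec | str,
    dataset: Dataset,
    config: OptimizerConfig | None = None,
) -> SemiEmpiricalFit:
    """AARD%-minimizing fit of one correlation to a dataset.

    The transformed-space least-squares solution is always one start; the
    remaining restarts perturb it multiplicatively with a seeded generator,
    so results are reproducible for a given (dataset, config).
    """
    if isinstance(spec, str):
        spec = model_spec(spec)
    config = config or OptimizerConfig()
    if len(dataset) < spec.n_params + 1:
        raise ValueError(
            f"need at least {spec.n_params + 1} records to fit {spec.model_id}"
        )
    T, P, rho, y = _arrays(dataset)
    S = np.array(
        [
            r.mass_solubility
            if r.mass_solubility is not None
            else dataset.solute.molar_mass
            * (r.mole_fraction / (1 - r.mole_fraction))
            * r.co2_density
            / dataset.solvent.molar_mass
            for r in dataset
        ]
    )
    X = _FEATURES[spec.model_id](T, P, rho)
    scale = np.abs(X).max(axis=0)
    Xs = X / scale
    g_obs = _observed_transform(spec.model_id, T, P, rho, y, S)
    b_lsq, *_ = np.linalg.lstsq(Xs, g_obs, rcond=None)

    solute, solvent = dataset.solute, dataset.solvent

    def objective(b: np.ndarray) -> float:
        g = Xs @ b
        lny = _ln_y_from_linear(spec.model_id, g, T, P, rho, solute, solvent)
        with np.errstate(over="ignore", invalid="ignore"):
            y_cal = np.exp(lny)
            if not np.all(np.isfinite(y_cal)):
                return 1e9
            out = float(np.mean(np.abs(y - y_cal) / y) * 100.0)
        return out if math.isfinite(out) else 1e9

    rng = np.random.default_rng(config.seed)
    starts = [b_lsq]
    for _ in range(max(config.restarts - 1, 0)):
        starts.append(b_lsq * (1.0 + config.spread * rng.standard_normal(b_lsq.size)))
    for extra in config.extra_starts:
        starts.append(np.asarray(extra, dtype=float) * scale)

    best_x, best_f, n_conv = None, np.inf, 0
    for s in starts:
        res = optimize.minimize(
            objective,
            s,
            method="Nelder-Mead",
            options=dict(maxiter=config.maxiter, xatol=config.xatol, fatol=config.fatol),
        )
        # a numerically perfect fit counts as converged even when the simplex
        # cannot meet the tolerances at the objective's noise floor
        if res.success or res.fun < 1e-6:
            n_conv += 1
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
    # gradient-based polish (numerical gradient); keep only if it improves
    polish = optimize.minimize(objective, best_x, method="L-BFGS-B")
    if polish.fun < best_f:
        best_f, best_x = polish.fun, polish.x
    # second Nelder-Mead pass from the winner with tight tolerances
    res = optimize.minimize(
        objective,
        best_x,
        method="Nelder-Mead",
        options=dict(maxiter=config.maxiter, xatol=1e-14, fatol=1e-15),
    )
    if res.fun < best_f:
        best_f, best_x = res.fun, res.x

    params = best_x / scale
    y_cal = predict_mole_fractions(spec, params, dataset)
    fit = SemiEmpiricalFit(
        spec=spec,
        parameters=params,
        aard_percent=float(best_f),
        residuals=(y - y_cal) / y,
        optimizer_report=dict(
            restarts=len(starts), converged=n_conv, seed=config.seed,
            lsq_start_aard=objective(b_lsq),
        ),
    )
    if n_conv == 0:
        raise FitError(f"no restart converged for {spec.model_id}", best_fit=fit)
    return fit


def fit_all(
    dataset: Dataset,
    model_ids: Sequence[str] = MODEL_IDS,
    config: OptimizerConfig | None = None,
) -> dict[str, SemiEmpiricalFit]:
    return {m: fit_model(m, dataset, config) for m in model_ids}


def enthalpies(
    chrastil_fit: SemiEmpiricalFit, bartle_fit: SemiEmpiricalFit
) -> EnthalpyEstimates:
    """Dissolution enthalpies (kJ/mol) from the fitted temperature coefficients.

    Total dissolution enthalpy is -a1(Chrastil) * R; vaporization enthalpy is
    -a2(Bartle) * R; solvation enthalpy is their difference.
    """
    if chrastil_fit.spec.model_id != "chrastil":
        raise ValueError("first argument must be a Chrastil fit")
    if bartle_fit.spec.model_id != "bartle":
        raise ValueError("second argument must be a Bartle fit")
    total = -chrastil_fit.parameters[1] * R_GAS / 1000.0
    vap = -bartle_fit.parameters[2] * R_GAS / 1000.0
    return EnthalpyEstimates(
        total=float(total), vaporization=float(vap), solvation=float(total - vap)
    )


def consistency_test(
    model_id: str, fit: SemiEmpiricalFit, dataset: Dataset
) -> ConsistencyTestResult:
    """Linear-collapse self-consistency test of the data under a fitted model.

    Chrastil collapse: ln S - a1/T against ln rho (slope ~ a0, intercept ~ a2).
    MST collapse: T ln(y P_bar) - a2 T against rho (slope ~ a1, intercept ~ a0).
    Data from all isotherms should fall on a single straight line if they are
    mutually consistent with the model's density scaling.
    """
    if model_id not in ("chrastil", "mst"):
        raise ValueError("consistency test is defined for 'chrastil' and 'mst'")
    if fit.spec.model_id != model_id:
        raise ValueError(f"fit is for {fit.spec.model_id!r}, expected {model_id!r}")
    T, P, rho, y = _arrays(dataset)
    if model_id == "chrastil":
        S = np.array(
            [
                r.mass_solubility
                if r.mass_solubility is not None
                else dataset.solute.molar_mass
                * (r.mole_fraction / (1 - r.mole_fraction))
                * r.co2_density
                / dataset.solvent.molar_mass
                for r in dataset
            ]
        )
        x = np.log(rho)
        z = np.log(S) - fit.parameters[1] / T
    else:
        x = rho
        z = T * np.log(y * P) - fit.parameters[2] * T
    reg = stats.linregress(x, z)
    return ConsistencyTestResult(
        model_id=model_id,
        abscissa=x,
        ordinate=z,
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        r_squared=float(reg.rvalue**2),
    )


def isotherm_crossovers(
    fit: SemiEmpiricalFit,
    dataset: Dataset,
    pressure_range: tuple[float, float] | None = None,
) -> list[dict]:
    """Locate pressures where model isotherms intersect, per temperature pair.

    Densities off the measured pressure grid are interpolated per isotherm
    with a monotone cubic (PCHIP), so the search is confined to the measured
    pressure span.  Returns one entry per adjacent temperature pair with a
    bracketed sign change of ln y(T1, P) - ln y(T2, P).
    """
    temps = dataset.temperatures
    pressures = sorted({r.pressure for r in dataset.records})
    lo = pressure_range[0] if pressure_range else pressures[0]
    hi = pressure_range[1] if pressure_range else pressures[-1]
    interp = {}
    for t in temps:
        iso = dataset.isotherm(t)
        interp[t] = PchipInterpolator(
            [r.pressure for r in iso], [r.co2_density for r in iso]
        )

    def ln_y(t: float, p: float) -> float:
        rho = float(interp[t](p))
        rec = SolubilityRecord(
            temperature=t, pressure=p, co2_density=rho, mole_fraction=0.5
        )
        resp = evaluate_model(fit.spec, fit.parameters, rec)
        if fit.spec.model_id == "chrastil":
            m2, m1 = dataset.solute.molar_mass, dataset.solvent.molar_mass
            return math.log((resp / m2) / (rho / m1 + resp / m2))
        return math.log(resp)

    out = []
    grid = np.linspace(lo, hi, 241)
    for t1, t2 in zip(temps[:-1], temps[1:]):
        diff = np.array([ln_y(t1, p) - ln_y(t2, p) for p in grid])
        crossing = None
        for p_a, p_b, d_a, d_b in zip(grid[:-1], grid[1:], diff[:-1], diff[1:]):
            if d_a == 0.0:
                crossing = float(p_a)
                break
            if d_a * d_b < 0:
                crossing = float(
                    optimize.brentq(lambda p: ln_y(t1, p) - ln_y(t2, p), p_a, p_b)
                )
                break
        out.append(
            dict(temperature_low=t1, temperature_high=t2, crossover_pressure=crossing)
        )
    return out
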