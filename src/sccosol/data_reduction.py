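"""Reduce trapped-solvent samples to equilibrium solubility and mole fraction.

A saturated ScCO2 sample of loop volume ``V_l`` is discharged into a known
volume ``V_s`` of trapping solvent; spectrophotometry gives the solute
concentration ``C_2`` of that solution.  The equilibrium mass solubility and
mole fraction follow from the moles of solute and of CO2 that were in the
loop:

    S2 = C2 * V_s / V_l
    n1 = rho1 * V_l / M1        (CO2 in the loop)
    n2 = C2 * V_s / M2          (solute trapped)
    y2 = n2 / (n1 + n2)

Replicate statistics follow the usual convention: sample standard deviation
over replicate runs, and an expanded uncertainty U = k * u_comb with
coverage factor k = 2 (~95% confidence), where the relative combined
standard uncertainty aggregates user-supplied relative contributions in
quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import SchemaError, ValidationError

RAW_CSV_COLUMNS = ("C2_g_L", "loop_volume_L", "solution_volume_L", "co2_density_kg_m3")


@dataclass(frozen=True)
class RawSample:
    """One trapped-solvent measurement."""

    solute_concentration: float  # C2, g/L of trapping solution
    loop_volume: float  # V_l, L
    solution_volume: float  # V_s, L
    co2_density: float  # rho1 in the loop, kg m^-3

    def __post_init__(self) -> None:
        if self.solute_concentration < 0:
            raise ValidationError("solute_concentration must be >= 0")
        for name in ("loop_volume", "solution_volume", "co2_density"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate mole fractions plus the relative uncertainty budget."""

    mole_fractions: Sequence[float]
    relative_component_uncertainties: Sequence[float] = field(default_factory=tuple)
    coverage_factor: float = 2.0

    def __post_init__(self) -> None:
        if len(self.mole_fractions) < 2:
            raise ValidationError("need at least 2 replicates for a standard deviation")
        if not self.coverage_factor > 0:
            raise ValidationError("coverage_factor must be > 0")


def reduce_sample(
    sample: RawSample, solvent_molar_mass: float, solute_molar_mass: float
) -> tuple[float, float]:
    """(mass solubility g/L, mole fraction) of one sample.

    Note: kg m^-3 equals g L^-1, so ``rho1 * V_l`` (density in kg/m3, volume
    in L) is grams of CO2, matching ``C2 * V_s`` in grams of solute.
    """
    mass_solubility = sample.solute_concentration * sample.solution_volume / sample.loop_volume
    n1 = sample.co2_density * sample.loop_volume / solvent_molar_mass
    n2 = sample.solute_concentration * sample.solution_volume / solute_molar_mass
    return mass_solubility, n2 / (n1 + n2)


def solute_concentration_from_mole_fraction(
    mole_fraction: float,
    loop_volume: float,
    solution_volume: float,
    co2_density: float,
    solvent_molar_mass: float,
    solute_molar_mass: float,
) -> float:
    """Invert :func:`reduce_sample`: the C2 that yields a given mole fraction."""
    n1 = co2_density * loop_volume / solvent_molar_mass
    n2 = n1 * mole_fraction / (1.0 - mole_fraction)
    return n2 * solute_molar_mass / solution_volume


def replicate_statistics(reps: ReplicateSet) -> tuple[float, float, float]:
    """(mean y, sample std of y, expanded uncertainty U(y-bar))."""
    y = np.asarray(reps.mole_fractions, dtype=float)
    mean = float(y.mean())
    std = float(y.std(ddof=1))
    rel = np.asarray(reps.relative_component_uncertainties, dtype=float)
    u_comb = mean * float(np.sqrt(np.sum(rel**2)))
    return mean, std, reps.coverage_factor * u_comb


def read_raw_samples(path: str | Path) -> list[RawSample]:
    """Read raw samples from the canonical CSV layout."""
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    missing = [c for c in RAW_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return [
        RawSample(
            solute_concentration=float(r.C2_g_L),
            loop_volume=float(r.loop_volume_L),
            solution_volume=float(r.solution_volume_L),
            co2_density=float(r.co2_density_kg_m3),
        )
        for r in frame.itertuples()
    ]
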