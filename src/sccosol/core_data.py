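"""Domain types and validated I/O for isothermal solid-in-ScCO2 solubility data.

Units are fixed at the type boundary: temperature in K, pressure in MPa,
CO2 density in kg m^-3, solubility as mole fraction (dimensionless) and as
mass solubility in g L^-1.  Model-specific unit conversions (e.g. pressure
in bar inside correlation forms) happen inside model evaluation, never in
storage.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .constants import (
    ATOMIC_WEIGHTS,
    CO2_ACENTRIC_FACTOR,
    CO2_CRITICAL_PRESSURE,
    CO2_CRITICAL_TEMPERATURE,
    CO2_MOLAR_MASS,
)


class SchemaError(ValueError):
    """A file does not declare the canonical columns/fields."""


class ValidationError(ValueError):
    """A value violates a domain-type invariant."""


#: Canonical CSV column order.  The last three columns are optional.
CSV_COLUMNS = (
    "temperature_K",
    "pressure_MPa",
    "co2_density_kg_m3",
    "mole_fraction",
    "mass_solubility_g_L",
    "std_y",
    "expanded_uncertainty_y",
)
REQUIRED_COLUMNS = CSV_COLUMNS[:4]

#: Relative tolerance for the sampling-loop S <-> y consistency check.
#: Absorbs rounding of values carried at printed precision.
LOOP_CONSISTENCY_RTOL = 0.02

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def molar_mass_from_formula(formula: str) -> float:
    """Molar mass in g/mol of a Hill-notation molecular formula.

    >>> round(molar_mass_from_formula("C24H29N7O2"), 2)
    447.54
    """
    mass = 0.0
    consumed = 0
    for symbol, count in _FORMULA_TOKEN.findall(formula):
        if not symbol:
            continue
        if symbol not in ATOMIC_WEIGHTS:
            raise ValueError(f"unknown element {symbol!r} in formula {formula!r}")
        mass += ATOMIC_WEIGHTS[symbol] * (int(count) if count else 1)
        consumed += len(symbol) + len(count)
    if consumed != len(formula):
        raise ValueError(f"could not parse formula {formula!r}")
    return mass


@dataclass(frozen=True)
class SolubilityRecord:
    """One equilibrium solubility measurement in supercritical CO2."""

    temperature: float  # K
    pressure: float  # MPa
    co2_density: float  # kg m^-3
    mole_fraction: float  # y2, dimensionless
    mass_solubility: float | None = None  # S2, g L^-1
    std_y: float | None = None  # replicate sample standard deviation of y
    expanded_uncertainty_y: float | None = None  # U(y-bar), k = 2

    def __post_init__(self) -> None:
        for name in ("temperature", "pressure", "co2_density"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0 < self.mole_fraction < 1:
            raise ValidationError(
                f"mole_fraction must lie in (0, 1), got {self.mole_fraction}"
            )
        if self.mass_solubility is not None and self.mass_solubility <= 0:
            raise ValidationError("mass_solubility must be > 0 when given")


@dataclass(frozen=True)
class SolutePropertyCard:
    """Pure-component constants of the solid solute."""

    name: str
    formula: str
    molar_mass: float  # g mol^-1
    melt_temperature: float  # K
    fusion_enthalpy: float  # kJ mol^-1
    critical_temperature: float  # K
    critical_pressure: float  # MPa
    acentric_factor: float  # dimensionless
    solid_molar_volume: float  # cm^3 mol^-1
    lambda_max: float | None = None  # nm, UV detection wavelength (metadata)

    def __post_init__(self) -> None:
        positive = (
            "molar_mass",
            "melt_temperature",
            "fusion_enthalpy",
            "critical_temperature",
            "critical_pressure",
            "solid_molar_volume",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.melt_temperature < self.critical_temperature:
            raise ValidationError("melt_temperature must be below critical_temperature")


@dataclass(frozen=True)
class SolventPropertyCard:
    """Pure-component constants of the supercritical solvent."""

    molar_mass: float  # g mol^-1
    critical_temperature: float  # K
    critical_pressure: float  # MPa
    acentric_factor: float  # dimensionless

    def __post_init__(self) -> None:
        for name in ("molar_mass", "critical_temperature", "critical_pressure"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")


def co2_card() -> SolventPropertyCard:
    """Standard CO2 property card."""
    return SolventPropertyCard(
        molar_mass=CO2_MOLAR_MASS,
        critical_temperature=CO2_CRITICAL_TEMPERATURE,
        critical_pressure=CO2_CRITICAL_PRESSURE,
        acentric_factor=CO2_ACENTRIC_FACTOR,
    )


def mass_solubility_from_mole_fraction(
    y: float, co2_density: float, solvent_molar_mass: float, solute_molar_mass: float
) -> float:
    """Invert the sampling-loop relation: S (g/L) from y at the given density."""
    return solute_molar_mass * (y / (1.0 - y)) * co2_density / solvent_molar_mass


@dataclass
class Dataset:
    """An ordered, validated collection of solubility records plus the cards."""

    records: list[SolubilityRecord]
    solute: SolutePropertyCard
    solvent: SolventPropertyCard
    provenance: str = ""

    def __post_init__(self) -> None:
        self.records = sorted(
            self.records, key=lambda r: (r.temperature, r.pressure)
        )
        seen: set[tuple[float, float]] = set()
        for i, rec in enumerate(self.records):
            key = (rec.temperature, rec.pressure)
            if key in seen:
                raise ValidationError(f"duplicate (T, P) pair {key} at record {i}")
            seen.add(key)
        self._check_loop_consistency()

    def _check_loop_consistency(self) -> None:
        for i, rec in enumerate(self.records):
            if rec.mass_solubility is None:
                continue
            s_from_y = mass_solubility_from_mole_fraction(
                rec.mole_fraction,
                rec.co2_density,
                self.solvent.molar_mass,
                self.solute.molar_mass,
            )
            rel = abs(rec.mass_solubility - s_from_y) / s_from_y
            if rel > LOOP_CONSISTENCY_RTOL:
                raise ValidationError(
                    f"record {i} (T={rec.temperature} K, P={rec.pressure} MPa): "
                    f"mass_solubility {rec.mass_solubility} disagrees with the "
                    f"sampling-loop relation ({s_from_y:.4g}) by {rel:.1%} "
                    f"(> {LOOP_CONSISTENCY_RTOL:.0%})"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def temperatures(self) -> list[float]:
        """Distinct temperatures, ascending."""
        return sorted({r.temperature for r in self.records})

    def isotherm(self, temperature: float) -> list[SolubilityRecord]:
        return [r for r in self.records if r.temperature == temperature]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records]).rename(
            columns={
                "temperature": "temperature_K",
                "pressure": "pressure_MPa",
                "co2_density": "co2_density_kg_m3",
                "mass_solubility": "mass_solubility_g_L",
            }
        )[list(CSV_COLUMNS)]

    def save(self, path: str | Path, format: str = "csv") -> None:
        path = Path(path)
        if format == "csv":
            self.to_frame().to_csv(path, index=False)
        elif format == "json":
            payload = {
                "provenance": self.provenance,
                "solute": asdict(self.solute),
                "solvent": asdict(self.solvent),
                "records": self.to_frame().to_dict(orient="records"),
            }
            path.write_text(json.dumps(payload, indent=1))
        else:
            raise ValueError(f"unknown format {format!r}")


def _records_from_frame(frame: pd.DataFrame, origin: str) -> list[SolubilityRecord]:
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{origin}: missing column(s) {', '.join(missing)}")
    records = []
    for i, row in frame.iterrows():
        def _opt(col: str) -> float | None:
            if col not in frame.columns:
                return None
            v = row[col]
            return None if pd.isna(v) else float(v)

        try:
            records.append(
                SolubilityRecord(
                    temperature=float(row["temperature_K"]),
                    pressure=float(row["pressure_MPa"]),
                    co2_density=float(row["co2_density_kg_m3"]),
                    mole_fraction=float(row["mole_fraction"]),
                    mass_solubility=_opt("mass_solubility_g_L"),
                    std_y=_opt("std_y"),
                    expanded_uncertainty_y=_opt("expanded_uncertainty_y"),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{origin}, row {i}: {exc}") from exc
    return records


def _card_from_mapping(mapping: dict, cls):
    fields = {f for f in cls.__dataclass_fields__}
    unknown = set(mapping) - fields
    if unknown:
        raise SchemaError(f"unknown field(s) {sorted(unknown)} for {cls.__name__}")
    try:
        return cls(**mapping)
    except TypeError as exc:
        raise SchemaError(str(exc)) from exc


def load_solute_card(path: str | Path) -> SolutePropertyCard:
    return _card_from_mapping(json.loads(Path(path).read_text()), SolutePropertyCard)


def load_solvent_card(path: str | Path) -> SolventPropertyCard:
    return _card_from_mapping(json.loads(Path(path).read_text()), SolventPropertyCard)


def load_dataset(
    path: str | Path,
    format: str = "csv",
    solute: SolutePropertyCard | None = None,
    solvent: SolventPropertyCard | None = None,
    provenance: str | None = None,
) -> Dataset:
    """Load a validated dataset from the canonical CSV or JSON layout.

    CSV files carry only records; the property cards must be supplied (the
    solvent card defaults to CO2).  JSON files embed the cards.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        try:
            frame = pd.read_csv(path)
        except pd.errors.EmptyDataError as exc:
            raise SchemaError(f"{path}: empty file") from exc
        if solute is None:
            raise ValueError("CSV datasets need an explicit solute card")
        return Dataset(
            records=_records_from_frame(frame, str(path)),
            solute=solute,
            solvent=solvent or co2_card(),
            provenance=provenance or str(path),
        )
    if format == "json":
        payload = json.loads(path.read_text())
        for key in ("records", "solute", "solvent"):
            if key not in payload:
                raise SchemaError(f"{path}: missing top-level key {key!r}")
        frame = pd.DataFrame(payload["records"]).rename(
            columns={  # accept internal field names too
                "temperature": "temperature_K",
                "pressure": "pressure_MPa",
                "co2_density": "co2_density_kg_m3",
                "mass_solubility": "mass_solubility_g_L",
            }
        )
        return Dataset(
            records=_records_from_frame(frame, str(path)),
            solute=_card_from_mapping(payload["solute"], SolutePropertyCard),
            solvent=_card_from_mapping(payload["solvent"], SolventPropertyCard),
            provenance=provenance or payload.get("provenance", str(path)),
        )
    raise ValueError(f"unknown format {format!r}")


def builtin_palbociclib_study() -> Dataset:
    """The packaged palbociclib/ScCO2 study: 24 records on a 4 x 6 (T, P) grid.

    Mole fractions and CO2 densities are authoritative; mass solubilities are
    recomputed from the sampling-loop relation at full precision.
    """
    data = resources.files("sccosol.data")
    with resources.as_file(data / "palbociclib_scco2.csv") as csv_path:
        frame = pd.read_csv(csv_path)
    solute = _card_from_mapping(
        json.loads((data / "palbociclib.json").read_text()), SolutePropertyCard
    )
    solvent = _card_from_mapping(
        json.loads((data / "co2.json").read_text()), SolventPropertyCard
    )
    return Dataset(
        records=_records_from_frame(frame, "palbociclib_scco2.csv"),
        solute=solute,
        solvent=solvent,
        provenance="packaged palbociclib/ScCO2 study (builtin)",
    )
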