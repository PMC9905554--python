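"""End-to-end study orchestration and report rendering."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import cubic_eos, semiempirical
from .core_data import Dataset, builtin_palbociclib_study, load_dataset, load_solute_card

logger = logging.getLogger("sccosol")

EOS_RULES = ("vdw", "wong_sandler", "huron_vidal")


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    dataset: str = "builtin"  # "builtin" or a CSV/JSON path
    dataset_format: str = "csv"
    solute_card: str | None = None  # required for CSV dataset paths
    semiempirical_models: Sequence[str] = semiempirical.MODEL_IDS
    eos_models: Sequence[str] = ("vdw",)
    restarts: int = 64
    eos_restarts: int = 8
    seed: int = 20230207
    output_dir: str = "sccosol-report"
    formats: Sequence[str] = ("csv", "json")
    plots: bool = False

    def validate(self) -> None:
        if not self.semiempirical_models and not self.eos_models:
            raise ConfigError("select at least one model to fit")
        bad = set(self.semiempirical_models) - set(semiempirical.MODEL_IDS)
        if bad:
            raise ConfigError(f"unknown semi-empirical model(s): {sorted(bad)}")
        bad = set(self.eos_models) - set(EOS_RULES)
        if bad:
            raise ConfigError(f"unknown EoS mixing rule(s): {sorted(bad)}")
        bad = set(self.formats) - {"csv", "txt", "json"}
        if bad:
            raise ConfigError(f"unknown report format(s): {sorted(bad)}")


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    payload = (
        yaml.safe_load(path.read_text())
        if path.suffix in (".yml", ".yaml")
        else json.loads(path.read_text())
    )
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(payload) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**payload)


def resolve_dataset(config: RunConfig) -> Dataset:
    if config.dataset == "builtin":
        return builtin_palbociclib_study()
    solute = load_solute_card(config.solute_card) if config.solute_card else None
    return load_dataset(config.dataset, format=config.dataset_format, solute=solute)


def semiempirical_table(fits: dict[str, semiempirical.SemiEmpiricalFit]) -> pd.DataFrame:
    """Fitted parameters and AARD% for the selected correlations, one row each."""
    rows = []
    for model_id, fit in fits.items():
        row = {"model": model_id}
        for i in range(8):
            row[f"a{i}"] = fit.parameters[i] if i < len(fit.parameters) else np.nan
        row["AARD_percent"] = fit.aard_percent
        rows.append(row)
    return pd.DataFrame(rows)


def eos_table(fits: dict[str, cubic_eos.EoSFit]) -> pd.DataFrame:
    """Fitted binary parameters, AARD% and ALD-y for the EoS models."""
    rows = []
    for rule_id, fit in fits.items():
        rule = fit.mixing_rule
        rows.append(
            {
                "model": rule_id,
                "k12": rule.k12 if rule.kind == "vdw" else np.nan,
                "u12_J_mol": rule.ge_model.u12 if rule.ge_model else np.nan,
                "u21_J_mol": rule.ge_model.u21 if rule.ge_model else np.nan,
                "AARD_percent": fit.aard_percent,
                "ALD_y": fit.ald_y,
                "failed_points": fit.n_failed,
            }
        )
    return pd.DataFrame(rows)


def _write_table(frame: pd.DataFrame, stem: Path, formats: Sequence[str]) -> None:
    if "csv" in formats:
        frame.to_csv(stem.with_suffix(".csv"), index=False)
    if "txt" in formats:
        stem.with_suffix(".txt").write_text(frame.to_string(index=False) + "\n")
    if "json" in formats:
        frame.to_json(stem.with_suffix(".json"), orient="records", indent=1)


def _plot_isotherms(dataset: Dataset, fits, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for t in dataset.temperatures:
        iso = dataset.isotherm(t)
        p = [r.pressure for r in iso]
        rho = [r.co2_density for r in iso]
        y = [r.mole_fraction for r in iso]
        axes[0].plot(p, y, "o-", label=f"{t:.0f} K")
        axes[1].plot(rho, y, "s-", label=f"{t:.0f} K")
    axes[0].set_xlabel("P / MPa")
    axes[1].set_xlabel(r"$\rho_{CO_2}$ / kg m$^{-3}$")
    for ax in axes:
        ax.set_ylabel("y")
        ax.set_yscale("log")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_dir / "isotherms.png", dpi=150)
    plt.close(fig)


def run_study(config: RunConfig) -> dict:
    """Run the configured pipeline and write the report bundle.

    Returns the machine-readable summary that is also written to
    ``summary.json``.
    """
    config.validate()
    dataset = resolve_dataset(config)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "dataset": dataset.provenance,
        "n_records": len(dataset),
        "seed": config.seed,
    }

    se_fits: dict[str, semiempirical.SemiEmpiricalFit] = {}
    if config.semiempirical_models:
        logger.info("fitting %d semi-empirical models", len(config.semiempirical_models))
        opt = semiempirical.OptimizerConfig(restarts=config.restarts, seed=config.seed)
        se_fits = semiempirical.fit_all(dataset, config.semiempirical_models, opt)
        table = semiempirical_table(se_fits)
        _write_table(table, out_dir / "semiempirical_fits", config.formats)
        summary["semiempirical"] = {
            m: {"parameters": list(map(float, f.parameters)), "aard_percent": f.aard_percent}
            for m, f in se_fits.items()
        }
        if "chrastil" in se_fits and "bartle" in se_fits:
            enth = semiempirical.enthalpies(se_fits["chrastil"], se_fits["bartle"])
            summary["enthalpies_kJ_mol"] = asdict(enth)
            (out_dir / "enthalpies.json").write_text(json.dumps(asdict(enth), indent=1))
        consistency = {}
        for m in ("chrastil", "mst"):
            if m in se_fits:
                res = semiempirical.consistency_test(m, se_fits[m], dataset)
                consistency[m] = {
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "r_squared": res.r_squared,
                }
                pd.DataFrame(
                    {"abscissa": res.abscissa, "ordinate": res.ordinate}
                ).to_csv(out_dir / f"consistency_{m}.csv", index=False)
        if consistency:
            summary["consistency"] = consistency
            (out_dir / "consistency.json").write_text(json.dumps(consistency, indent=1))

    eos_fits: dict[str, cubic_eos.EoSFit] = {}
    for rule_id in config.eos_models:
        logger.info("regressing PR EoS with %s mixing rule", rule_id)
        template = (
            cubic_eos.MixingRuleSpec(kind="vdw")
            if rule_id == "vdw"
            else cubic_eos.MixingRuleSpec(
                kind=rule_id, ge_model=cubic_eos.GEModelSpec(kind="wilson")
            )
        )
        eos_cfg = cubic_eos.EoSOptimizerConfig(
            restarts=config.eos_restarts, seed=config.seed
        )
        eos_fits[rule_id] = cubic_eos.fit_eos(dataset, template, eos_cfg)
    if eos_fits:
        _write_table(eos_table(eos_fits), out_dir / "eos_fits", config.formats)
        summary["eos"] = {
            rule_id: {
                "k12": fit.mixing_rule.k12 if fit.mixing_rule.kind == "vdw" else None,
                "u12_J_mol": fit.mixing_rule.ge_model.u12 if fit.mixing_rule.ge_model else None,
                "u21_J_mol": fit.mixing_rule.ge_model.u21 if fit.mixing_rule.ge_model else None,
                "aard_percent": fit.aard_percent,
                "ald_y": fit.ald_y,
                "failed_points": fit.n_failed,
            }
            for rule_id, fit in eos_fits.items()
        }

    if se_fits:
        best = min(se_fits.items(), key=lambda kv: kv[1].aard_percent)
        summary["best_semiempirical_model"] = best[0]

    if config.plots:
        _plot_isotherms(dataset, se_fits, out_dir)

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
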