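"""Profile/config I/O and the end-to-end pipeline.

Dissolution profiles travel as CSV with header
``time_min,percent_released[,pH]`` (decimal points, no locale commas).
Run configurations are YAML/JSON mappings with the blocks ``drug``,
``disposition``, ``physiology``, ``formulation``, ``dose`` and ``solver``;
unknown keys are rejected before any computation.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, datasets
from .dissolution_sources import ReleaseSource
from .pbbm import (
    DoseEvent,
    Route,
    SolverSettings,
    simulate_oral,
    terminal_half_life,
)
from .physiology import default_fasted_physiology, with_overrides
from .release_kinetics import DissolutionProfile, fit_all_models
from .metrics import two_fold_validation
from .synthetic import formulation_presets, generate_profile

__all__ = [
    "read_profile_csv",
    "write_profile_csv",
    "load_config",
    "run_pipeline",
    "ConfigError",
]

PROFILE_COLUMNS = ("time_min", "percent_released")


class ConfigError(ValueError):
    pass


def read_profile_csv(path) -> DissolutionProfile:
    """Read a dissolution profile CSV, validating header and monotone times."""
    path = Path(path)
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols[:2] != list(PROFILE_COLUMNS):
        raise ConfigError(
            f"{path}: expected header {','.join(PROFILE_COLUMNS)}[,pH], got {cols}"
        )
    for col in cols:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[~df[col].apply(lambda v: isinstance(v, (int, float)))].index
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise ConfigError(f"{path}: non-numeric value in column {col!r} near line {line}")
    t = df["time_min"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        line = int(np.nonzero(np.diff(t) <= 0)[0][0]) + 3
        raise ConfigError(f"{path}: times not strictly increasing at line {line}")
    ph = df["pH"].to_numpy(dtype=float) if "pH" in cols else None
    return DissolutionProfile.from_arrays(
        t, df["percent_released"].to_numpy(dtype=float), stage_pH=ph,
        formulation_id=path.stem,
    )


def write_profile_csv(profile: DissolutionProfile, path) -> None:
    data = {"time_min": profile.times, "percent_released": profile.released}
    if profile.stage_pH is not None:
        data["pH"] = profile.stage_pH
    pd.DataFrame(data).to_csv(path, index=False)


_TOP_KEYS = {"drug", "disposition", "physiology", "formulation", "dose",
             "solver", "output", "schema_version"}


def load_config(path) -> dict:
    """Load and schema-check a YAML/JSON run configuration."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, Mapping):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown top-level keys {sorted(unknown)}")
    return dict(cfg)


def _build_source(formulation: Mapping, base_dir: Path, seed: int) -> ReleaseSource:
    kind = formulation.get("type")
    if kind == "solid":
        return ReleaseSource.from_psd(
            d50_um=float(formulation.get("d50_um", 150.0)),
            d90_um=float(formulation.get("d90_um", 250.0)),
            n_bins=int(formulation.get("n_bins", 10)),
        )
    if kind == "dispersed":
        if "preset" in formulation:
            spec = formulation_presets()[formulation["preset"]]
            if formulation.get("noise_sd"):
                spec = type(spec)(**{**spec.__dict__,
                                     "noise_sd": float(formulation["noise_sd"]),
                                     "seed": seed})
            profile = generate_profile(spec)
        elif "profile_csv" in formulation:
            profile = read_profile_csv(base_dir / formulation["profile_csv"])
        else:
            raise ConfigError("dispersed formulation needs 'preset' or 'profile_csv'")
        return ReleaseSource.from_profile(
            profile,
            extension=formulation.get("extension", "hold_rate"),
            release_site=formulation.get("release_site", "all"),
            lag_min=float(formulation.get("lag_min", 0.0)),
        )
    raise ConfigError(f"formulation.type must be 'solid' or 'dispersed', got {kind!r}")


def run_pipeline(config: Mapping | str | Path, out_dir, seed: int = 0) -> dict:
    """Execute profile fitting -> oral simulation -> metrics -> validation.

    Writes a time-series CSV, a regional-absorption CSV, a metrics JSON and
    a provenance record into ``out_dir``; returns the artifact paths.
    Deterministic for a fixed config and seed.
    """
    if not isinstance(config, Mapping):
        base_dir = Path(config).parent
        config = load_config(config)
    else:
        base_dir = Path(".")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    drug = datasets.clopidogrel_drug_parameters()
    disp = datasets.clopidogrel_disposition_parameters()
    physiology = default_fasted_physiology()
    if config.get("physiology", {}).get("overrides"):
        physiology = with_overrides(physiology, config["physiology"]["overrides"])

    formulation = config.get("formulation")
    if formulation is None:
        raise ConfigError("p.o. run requires a formulation block")
    source = _build_source(formulation, base_dir, seed)

    dose_cfg = config.get("dose", {})
    dose_event = DoseEvent(
        route=Route.po, dose=float(dose_cfg.get("dose_mg", 75.0)),
        coadministered_water_mL=float(dose_cfg.get("water_mL", 200.0)),
    )
    solver_cfg = config.get("solver", {})
    solver = SolverSettings(
        rtol=float(solver_cfg.get("rtol", 1e-9)),
        dt_out=float(solver_cfg.get("dt_out", 0.01)),
        n_bins=int(solver_cfg.get("n_bins", 10)),
    )
    t_end = float(solver_cfg.get("t_end_h", 24.0))
    precipitation = bool(formulation.get("precipitation",
                                         formulation.get("type") == "solid"))

    artifacts = {}
    if source.profile is not None:
        fits = fit_all_models(source.profile)
        fit_rows = [
            {"model": f.model.value, "r_squared": f.r_squared, **f.params}
            for f in fits if f.converged
        ]
        fit_path = out / "release_fits.csv"
        pd.DataFrame(fit_rows).to_csv(fit_path, index=False)
        artifacts["release_fits"] = str(fit_path)

    result = simulate_oral(drug, disp, physiology, source, dose_event,
                           t_end=t_end, solver=solver,
                           precipitation=precipitation)

    ts_path = out / "timeseries.csv"
    pd.DataFrame({
        "time_h": result.times,
        "plasma_ng_per_mL": result.plasma_conc,
        "liver_ng_per_mL": result.liver_conc,
        "dissolved_total_mg": result.lumen_dissolved.sum(axis=0),
        "undissolved_total_mg": result.lumen_undissolved.sum(axis=0),
        "absorbed_total_mg": result.absorbed_cumulative.sum(axis=0),
    }).to_csv(ts_path, index=False)
    artifacts["timeseries"] = str(ts_path)

    regional_path = out / "regional_absorption.csv"
    pd.Series(result.regional_absorbed, name="percent_of_absorbed").rename_axis(
        "compartment").to_csv(regional_path)
    artifacts["regional"] = str(regional_path)

    metrics_path = out / "metrics.json"
    metrics = {
        "Fa_pct": result.Fa, "Fb_pct": result.Fb,
        "t_half_h": terminal_half_life(disp),
        "mass_balance_max_rel_error": result.mass_balance_max_error,
        **(result.metrics.to_dict() if result.metrics else {}),
    }
    metrics_path.write_text(json.dumps(metrics, indent=2))
    artifacts["metrics"] = str(metrics_path)

    # observed-vs-predicted two-fold validation of the reported PK metrics
    if result.metrics is not None:
        obs = datasets.observed_po_pk()
        obs = obs[obs.dose_mg == dose_event.dose]
        if len(obs):
            records = [
                (row.parameter, getattr(result.metrics,
                                        {"Cmax": "Cmax", "tmax": "tmax",
                                         "AUC_0_inf": "AUC_0_inf",
                                         "AUC_0_t": "AUC_0_t"}[row.parameter]),
                 row.observed)
                for row in obs.itertuples()
            ]
            val = two_fold_validation(records)
            val_path = out / "validation.csv"
            pd.DataFrame([v.__dict__ for v in val]).to_csv(val_path, index=False)
            artifacts["validation"] = str(val_path)

    cfg_text = json.dumps(config, sort_keys=True, default=str)
    provenance = {
        "package_version": __version__,
        "config": config,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": seed,
    }
    prov_path = out / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2, default=str))
    artifacts["provenance"] = str(prov_path)
    return artifacts
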