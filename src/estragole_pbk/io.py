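"""Readers and writers for rate tables, parameter files and results.

CSV dialect: comma-separated, UTF-8, ``.`` decimal separator, mandatory
header row, ``#`` comment lines.  Column names carry units (``_uM``,
``_mg_per_kg``, ``_h``) to prevent silent unit errors.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .invitro_kinetics import (
    InVitroRateDataset,
    MMKinetics,
    catalytic_efficiency_invitro,
)
from .ivive_scaling import ScaledPathway
from .pbk_core import PopulationConfig, SimulationResult
from .reference import POPULATIONS, load_population, population_from_dict

__all__ = [
    "MalformedInputError",
    "round_sig",
    "read_rate_table",
    "write_rate_table",
    "write_kinetics_csv",
    "write_scaled_csv",
    "write_simulation_csv",
    "simulation_summary",
    "write_summary_json",
    "load_population_file",
]

RATE_TABLE_COLUMNS = ["concentration_uM", "rate_mean", "rate_sem", "pathway", "protein_source"]


class MalformedInputError(ValueError):
    """An input file does not match the documented schema."""


def round_sig(x: float, digits: int = 2) -> float:
    """Round to ``digits`` significant figures (report-table convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        return pd.read_csv(path, sep=sep, comment="#")
    except Exception as exc:
        raise MalformedInputError(f"{path}: cannot parse as delimited text ({exc})") from exc


def read_rate_table(path: str | Path) -> list[InVitroRateDataset]:
    """Read incubation rate data, one dataset per (pathway, protein_source).

    Required columns: ``concentration_uM, rate_mean, pathway, protein_source``
    (``rate_sem`` optional).
    """
    df = _read_table(path)
    required = {"concentration_uM", "rate_mean", "pathway", "protein_source"}
    missing = required - set(df.columns)
    if missing:
        raise MalformedInputError(
            f"{path}: missing required column(s) {sorted(missing)}; "
            f"expected header {RATE_TABLE_COLUMNS}"
        )
    datasets = []
    for (pathway, source), grp in df.groupby(["pathway", "protein_source"], sort=False):
        try:
            datasets.append(
                InVitroRateDataset(
                    pathway_id=str(pathway),
                    protein_source=str(source),
                    concentrations=grp["concentration_uM"].to_numpy(float),
                    rates=grp["rate_mean"].to_numpy(float),
                    rate_sems=grp["rate_sem"].to_numpy(float) if "rate_sem" in grp else None,
                    n_replicates=int(grp["n_replicates"].iloc[0]) if "n_replicates" in grp else 1,
                )
            )
        except ValueError as exc:
            first_line = int(grp.index[0]) + 2  # +1 header, +1 one-based
            raise MalformedInputError(
                f"{path}, rows starting at line {first_line} "
                f"(pathway {pathway}): {exc}"
            ) from exc
    return datasets


def write_rate_table(datasets: Iterable[InVitroRateDataset], path: str | Path) -> None:
    rows = []
    for ds in datasets:
        for i, conc in enumerate(ds.concentrations):
            rows.append(
                {
                    "concentration_uM": conc,
                    "rate_mean": ds.rates[i],
                    "rate_sem": ds.rate_sems[i] if ds.rate_sems is not None else "",
                    "pathway": ds.pathway_id,
                    "protein_source": ds.protein_source,
                    "n_replicates": ds.n_replicates,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_kinetics_csv(fits: Iterable[MMKinetics], path: str | Path) -> None:
    """Fitted constants, mirroring the in vitro kinetics report table."""
    rows = [
        {
            "pathway": k.pathway_id,
            "protein_source": k.protein_source,
            "km_uM": k.km_uM,
            "km_sem_uM": k.km_sem,
            "vmax_nmol_min_mg": k.vmax_invitro,
            "vmax_sem_nmol_min_mg": k.vmax_sem,
            "efficiency_uL_min_mg": round_sig(catalytic_efficiency_invitro(k), 2),
        }
        for k in fits
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_scaled_csv(scaled: Iterable[ScaledPathway], path: str | Path) -> None:
    rows = [
        {
            "pathway": s.pathway_id,
            "parent": s.parent,
            "km_uM": s.km_uM,
            "vmax_scaled_umol_h_g": s.vmax_scaled,
            "efficiency_uL_h_g": s.efficiency_scaled,
        }
        for s in scaled
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_simulation_csv(result: SimulationResult, path: str | Path) -> None:
    out = result.states.copy()
    out.insert(0, "time_h", result.time_h)
    out.to_csv(path, index=False)


def simulation_summary(result: SimulationResult) -> dict:
    return {
        "dose_mg_per_kg": result.dose_mg_per_kg,
        "dose_umol": result.dose_umol,
        "percent_of_dose": result.percent_of_dose,
        "nmol_per_g_liver": result.nmol_per_g_liver,
        "cumulative_umol": result.cumulative_umol,
        "liver_HE_cmax_uM": result.liver_he_cmax_uM,
        "liver_HE_auc_uM_h": result.liver_he_auc_uM_h,
    }


def write_summary_json(result: SimulationResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(simulation_summary(result), indent=2) + "\n")


def load_population_file(source: str | Path) -> PopulationConfig:
    """Load a population: a bundled name (``chinese``/``caucasian``) or a
    YAML/JSON parameter file path."""
    if str(source) in POPULATIONS:
        return load_population(str(source))
    path = Path(source)
    if not path.exists():
        raise MalformedInputError(
            f"{source!r} is neither a bundled population {POPULATIONS} nor an existing file"
        )
    try:
        raw = (
            json.loads(path.read_text())
            if path.suffix.lower() == ".json"
            else yaml.safe_load(path.read_text())
        )
        return population_from_dict(raw)
    except (ValueError, yaml.YAMLError) as exc:
        raise MalformedInputError(f"{path}: {exc}") from exc
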