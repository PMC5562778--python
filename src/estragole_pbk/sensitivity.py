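"""Normalized local sensitivity analysis of the PBK model.

For a model output C and a parameter P, the normalized sensitivity
coefficient is

    SC = (C' - C) / (P' - P) * (P / C)

with C' the output after a one-sided forward perturbation P' = (1 + delta) P
(default delta = 0.05, i.e. +5%).  SC is dimensionless and invariant to the
units of P.  A central-difference variant is available behind a flag.

Parameters are addressed by dotted paths in the population parameter file
schema, e.g. ``physiology.body_weight_kg``, ``partition_coefficients.estragole.fat``,
``pathways.HE.vmax_invitro`` or ``protein_yields_mg_per_g_liver.microsomes``.
Derived quantities (compartment volumes, blood flows, scaled Vmax values)
are re-derived from the perturbed primitives, so perturbing e.g. the
microsomal protein yield moves every microsomal pathway's whole-liver Vmax.

Outputs are 24-h cumulative amounts formed (µmol) of a tracked metabolite;
the headline outputs are ``HE`` (proximate carcinogen) and ``HES``
(ultimate carcinogen).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd

from .pbk_core import (
    FLOW_TISSUES,
    METABOLITES,
    PATHWAYS,
    TISSUES,
    PopulationConfig,
    build_model_spec,
    simulate,
)

__all__ = [
    "SensitivityReport",
    "parameter_paths",
    "get_parameter",
    "with_parameter",
    "finite_difference_sc",
    "sensitivity_coefficient",
    "full_sweep",
]

DEFAULT_DOSES = (0.01, 5.0, 150.0)
DEFAULT_OUTPUTS = ("HE", "HES")
REPORT_THRESHOLD = 0.1


def parameter_paths(config: PopulationConfig) -> list[str]:
    """Every scalar parameter of the model, as a dotted path."""
    paths = ["physiology.body_weight_kg", "physiology.cardiac_output_constant"]
    paths += [f"physiology.tissue_fraction_pct.{t}" for t in TISSUES]
    paths += [f"physiology.flow_fraction_pct.{t}" for t in FLOW_TISSUES]
    paths += [f"partition_coefficients.estragole.{t}" for t in FLOW_TISSUES]
    paths += ["partition_coefficients.hydroxyestragole.liver"]
    paths += ["absorption.ka_per_h"]
    paths += [f"protein_yields_mg_per_g_liver.{k}" for k in sorted(config.protein_yields)]
    for p in PATHWAYS:
        paths += [f"pathways.{p}.km_uM", f"pathways.{p}.vmax_invitro"]
    return paths


def _resolve(config: PopulationConfig, path: str):
    """Return (owner-object-or-dict, final key) for a dotted parameter path."""
    parts = path.split(".")
    try:
        head = parts[0]
        if head == "physiology":
            if len(parts) == 2:
                return config.physiology, parts[1]
            return getattr(config.physiology, parts[1]), parts[2]
        if head == "partition_coefficients":
            return getattr(config.partitions, parts[1]), parts[2]
        if head == "absorption" and parts[1] == "ka_per_h":
            return config, "ka_per_h"
        if head == "protein_yields_mg_per_g_liver":
            return config.protein_yields, parts[1]
        if head == "pathways":
            return config.kinetics[parts[1]], parts[2]
    except (AttributeError, KeyError, IndexError):
        pass
    raise KeyError(f"unknown parameter path {path!r}")


def get_parameter(config: PopulationConfig, path: str) -> float:
    owner, key = _resolve(config, path)
    value = owner[key] if isinstance(owner, dict) else getattr(owner, key)
    if value is None:
        raise KeyError(f"parameter {path!r} has no value")
    return float(value)


def with_parameter(config: PopulationConfig, path: str, value: float) -> PopulationConfig:
    """A deep copy of ``config`` with one scalar parameter replaced."""
    new = copy.deepcopy(config)
    owner, key = _resolve(new, path)
    if isinstance(owner, dict):
        if key not in owner:
            raise KeyError(f"unknown parameter path {path!r}")
        owner[key] = float(value)
    else:
        if not hasattr(owner, key):
            raise KeyError(f"unknown parameter path {path!r}")
        # Physiology/PartitionSet are frozen; bypass for controlled perturbation.
        object.__setattr__(owner, key, float(value))
    return new


def finite_difference_sc(
    output_fn: Callable[[float], float],
    parameter_value: float,
    delta: float = 0.05,
    central: bool = False,
) -> float:
    """Normalized SC of ``output_fn`` at ``parameter_value`` by finite difference."""
    if parameter_value == 0:
        raise ValueError("cannot perturb a zero-valued parameter multiplicatively")
    c = output_fn(parameter_value)
    if c == 0:
        raise ZeroDivisionError("baseline output is zero; SC undefined")
    p = parameter_value
    if central:
        c_hi = output_fn(p * (1 + delta))
        c_lo = output_fn(p * (1 - delta))
        return (c_hi - c_lo) / (2 * delta * p) * (p / c)
    c_hi = output_fn(p * (1 + delta))
    return (c_hi - c) / (delta * p) * (p / c)


def _cumulative(config: PopulationConfig, dose: float, sim_kwargs: dict) -> dict[str, float]:
    return simulate(build_model_spec(config), dose, **sim_kwargs).cumulative_umol


def sensitivity_coefficient(
    config: PopulationConfig,
    parameter_path: str,
    output: str,
    dose_mg_per_kg: float,
    delta: float = 0.05,
    central: bool = False,
    **sim_kwargs,
) -> float:
    """SC of one 24-h cumulative output with respect to one parameter."""
    if output not in METABOLITES:
        raise KeyError(f"unknown output {output!r}; tracked: {METABOLITES}")
    p = get_parameter(config, parameter_path)

    def f(value: float) -> float:
        cfg = config if value == p else with_parameter(config, parameter_path, value)
        return _cumulative(cfg, dose_mg_per_kg, sim_kwargs)[output]

    return finite_difference_sc(f, p, delta=delta, central=central)


@dataclass
class SensitivityReport:
    """Full SC table plus the reporting threshold for the filtered view."""

    table: pd.DataFrame  # columns: parameter, output, dose_mg_per_kg, sc
    threshold: float = REPORT_THRESHOLD

    def __post_init__(self):
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")
        if not self.table["sc"].map(lambda v: v == v and abs(v) != float("inf")).all():
            raise ValueError("sensitivity coefficients must be finite")

    @property
    def filtered(self) -> pd.DataFrame:
        """Entries with |SC| at or above the reporting threshold."""
        return self.table[self.table["sc"].abs() >= self.threshold].reset_index(drop=True)


def full_sweep(
    config: PopulationConfig,
    doses: Sequence[float] = DEFAULT_DOSES,
    outputs: Sequence[str] = DEFAULT_OUTPUTS,
    parameters: Iterable[str] | None = None,
    delta: float = 0.05,
    threshold: float = REPORT_THRESHOLD,
    central: bool = False,
    **sim_kwargs,
) -> SensitivityReport:
    """Perturb every scalar parameter individually at every dose.

    One simulation per (parameter, dose) yields the SCs of all requested
    outputs at once.  The unfiltered table is retained in the report; use
    ``report.filtered`` for the |SC| >= threshold view.
    """
    parameters = list(parameters) if parameters is not None else parameter_paths(config)
    rows = []
    for dose in doses:
        base = _cumulative(config, dose, sim_kwargs)
        for path in parameters:
            p = get_parameter(config, path)
            hi = _cumulative(with_parameter(config, path, p * (1 + delta)), dose, sim_kwargs)
            if central:
                lo = _cumulative(with_parameter(config, path, p * (1 - delta)), dose, sim_kwargs)
            for out in outputs:
                c = base[out]
                if c == 0:
                    raise ZeroDivisionError(
                        f"baseline output {out} is zero at dose {dose}; SC undefined"
                    )
                if central:
                    sc = (hi[out] - lo[out]) / (2 * delta * c)
                else:
                    sc = (hi[out] - c) / (delta * c)
                rows.append(
                    {"parameter": path, "output": out, "dose_mg_per_kg": dose, "sc": sc}
                )
    return SensitivityReport(pd.DataFrame(rows), threshold=threshold)
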