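"""Six-compartment flow-limited PBK model for oral estragole.

Compartments: GI tract (first-order absorption depot, Ka = 1.0/h), liver,
fat, rapidly perfused tissue, slowly perfused tissue and blood.  All
estragole metabolism is hepatic and saturable; the substrate concentration
driving each Michaelis-Menten term is the venous-equilibrium concentration
CL/PL (flow-limited tissue assumption).  1'-Hydroxyestragole, the proximate
carcinogen, is tracked in a liver pool (partition coefficient 1.6)
exchanging with a blood pool at the liver blood flow, and is consumed in
liver by glucuronidation (HEG), oxidation (OE) and sulfation (HES).

Amounts are in µmol, volumes in L (tissue density 1 kg/L), flows in L/h,
time in h.  Cumulative metabolite formation is co-integrated so that mass
is exactly conserved:

    AGI + sum(tissue amounts) + AM_AP + AM_EE + AM_HA + AM_M5
        + (AL_HE + AB_HE + AM_HEG + AM_OE + AM_HES) = dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .invitro_kinetics import MMKinetics, PATHWAYS
from .ivive_scaling import (
    PROTEIN_YIELDS_MG_PER_G,
    ScaledPathway,
    build_scaled_table,
)

__all__ = [
    "TISSUES",
    "FLOW_TISSUES",
    "STATE_NAMES",
    "METABOLITES",
    "MW_ESTRAGOLE",
    "Physiology",
    "PartitionSet",
    "PBKModelSpec",
    "PopulationConfig",
    "SimulationResult",
    "SolverFailure",
    "build_model_spec",
    "derive_flows_volumes",
    "ode_rhs",
    "simulate",
    "percent_of_dose",
    "amount_per_g_liver",
]

TISSUES = ("liver", "fat", "rapidly_perfused", "slowly_perfused", "blood")
FLOW_TISSUES = ("liver", "fat", "rapidly_perfused", "slowly_perfused")

#: Molecular weight of estragole, g/mol (standard value; configurable).
MW_ESTRAGOLE = 148.20

#: ODE state ordering.  AM_* are cumulative amounts formed (µmol).
STATE_NAMES = (
    "AGI_E", "AL_E", "AF_E", "AR_E", "AS_E", "AB_E",
    "AL_HE", "AB_HE",
    "AM_AP", "AM_EE", "AM_HA", "AM_M5",
    "AM_HE", "AM_HEG", "AM_OE", "AM_HES",
)

#: Metabolites with a tracked cumulative formation amount.
METABOLITES = ("AP", "EE", "HA", "M5", "HE", "HEG", "OE", "HES")


class SolverFailure(RuntimeError):
    """ODE integration failed; carries the solver message."""


@dataclass(frozen=True)
class Physiology:
    """Body weight, tissue sizes and blood-flow distribution.

    Tissue fractions are % of body weight; flow fractions are % of cardiac
    output; the cardiac-output constant has units L/h/kg^0.74.
    """

    body_weight_kg: float
    tissue_fraction_pct: Mapping[str, float]
    cardiac_output_constant: float
    flow_fraction_pct: Mapping[str, float]

    def __post_init__(self):
        if self.body_weight_kg <= 0:
            raise ValueError("body_weight_kg must be positive")
        object.__setattr__(self, "tissue_fraction_pct", dict(self.tissue_fraction_pct))
        object.__setattr__(self, "flow_fraction_pct", dict(self.flow_fraction_pct))
        missing = set(TISSUES) - set(self.tissue_fraction_pct)
        if missing:
            raise ValueError(f"missing tissue fractions: {sorted(missing)}")
        missing = set(FLOW_TISSUES) - set(self.flow_fraction_pct)
        if missing:
            raise ValueError(f"missing flow fractions: {sorted(missing)}")
        if any(v < 0 for v in self.tissue_fraction_pct.values()):
            raise ValueError("tissue fractions must be non-negative")
        if sum(self.tissue_fraction_pct.values()) > 100.0 + 1e-9:
            raise ValueError("tissue fractions must sum to <= 100% of body weight")
        qsum = sum(self.flow_fraction_pct.values())
        # Printed flow fractions may carry rounding (e.g. a sum of 100.15%).
        if not 99.5 <= qsum <= 100.5:
            raise ValueError(f"flow fractions sum to {qsum}%, expected 100 +/- 0.5")


@dataclass(frozen=True)
class PartitionSet:
    """Tissue:blood partition coefficients for estragole and 1'-hydroxyestragole."""

    estragole: Mapping[str, float]
    hydroxyestragole: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "estragole", dict(self.estragole))
        object.__setattr__(self, "hydroxyestragole", dict(self.hydroxyestragole))
        for tissue in FLOW_TISSUES:
            if tissue not in self.estragole:
                raise ValueError(f"missing estragole partition coefficient for {tissue}")
        if "liver" not in self.hydroxyestragole:
            raise ValueError("missing hydroxyestragole liver partition coefficient")
        for chem in (self.estragole, self.hydroxyestragole):
            if any(v <= 0 for v in chem.values()):
                raise ValueError("partition coefficients must be positive")


@dataclass(frozen=True)
class PBKModelSpec:
    """Everything needed to integrate the model for one population."""

    physiology: Physiology
    partitions: PartitionSet
    pathways: Sequence[ScaledPathway]
    ka_per_h: float = 1.0
    mw_estragole: float = MW_ESTRAGOLE

    def __post_init__(self):
        object.__setattr__(self, "pathways", tuple(self.pathways))
        ids = [p.pathway_id for p in self.pathways]
        if sorted(ids) != sorted(PATHWAYS):
            raise ValueError(
                f"model needs exactly the eight pathways {PATHWAYS}, got {ids}"
            )
        if self.ka_per_h < 0:
            raise ValueError("ka_per_h must be non-negative")

    def pathway(self, pathway_id: str) -> ScaledPathway:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)


@dataclass
class PopulationConfig:
    """Raw population inputs: physiology, partitions, in vitro kinetics, yields.

    The PBK model spec is derived from this (``build_model_spec``); keeping
    the in vitro constants and protein yields separate lets the sensitivity
    analysis perturb them and re-derive the scaled kinetics.
    """

    name: str
    physiology: Physiology
    partitions: PartitionSet
    kinetics: dict[str, MMKinetics]
    ka_per_h: float = 1.0
    protein_yields: dict[str, float] = field(
        default_factory=lambda: dict(PROTEIN_YIELDS_MG_PER_G)
    )
    mw_estragole: float = MW_ESTRAGOLE


def build_model_spec(config: PopulationConfig) -> PBKModelSpec:
    """Scale the population's in vitro kinetics and assemble the model spec."""
    scaled = build_scaled_table(
        [config.kinetics[p] for p in PATHWAYS], yields=config.protein_yields
    )
    return PBKModelSpec(
        physiology=config.physiology,
        partitions=config.partitions,
        pathways=scaled,
        ka_per_h=config.ka_per_h,
        mw_estragole=config.mw_estragole,
    )


def derive_flows_volumes(physiology: Physiology):
    """Compartment volumes (L) and blood flows (L/h) from the physiology.

    Volume = fraction x body weight (density 1 kg/L).  Flow = fraction x
    cardiac output, with cardiac output = constant x BW^0.74.  The total
    blood-side flow is the sum of the tissue flows (so mass is conserved
    exactly even when the printed flow fractions do not sum to precisely
    100%).
    """
    bw = physiology.body_weight_kg
    volumes = {t: physiology.tissue_fraction_pct[t] / 100.0 * bw for t in TISSUES}
    cardiac_output = physiology.cardiac_output_constant * bw**0.74
    flows = {
        t: physiology.flow_fraction_pct[t] / 100.0 * cardiac_output
        for t in FLOW_TISSUES
    }
    return volumes, flows, sum(flows.values())


def _make_rhs(spec: PBKModelSpec):
    """Compile the ODE right-hand side as a closure over unpacked constants."""
    volumes, flows, q_total = derive_flows_volumes(spec.physiology)
    vl, vf, vr, vs, vb = (volumes[t] for t in TISSUES)
    ql, qf, qr, qs = (flows[t] for t in FLOW_TISSUES)
    pe = spec.partitions.estragole
    pl_e, pf_e, pr_e, ps_e = (pe[t] for t in FLOW_TISSUES)
    pl_he = spec.partitions.hydroxyestragole["liver"]
    ka = spec.ka_per_h
    liver_g = vl * 1000.0  # liver mass in g

    # whole-liver Vmax (µmol/h) and Km (µM) per pathway, in METABOLITE order
    km = {p.pathway_id: p.km_uM for p in spec.pathways}
    vmax = {p.pathway_id: p.vmax_scaled * liver_g for p in spec.pathways}

    def rhs(t, y):
        (agi, al, af, ar, as_, ab, al_he, ab_he) = y[:8]
        ca = ab / vb
        cvl = al / vl / pl_e
        cvf = af / vf / pf_e
        cvr = ar / vr / pr_e
        cvs = as_ / vs / ps_e

        r_ap = vmax["AP"] * cvl / (km["AP"] + cvl)
        r_ee = vmax["EE"] * cvl / (km["EE"] + cvl)
        r_he = vmax["HE"] * cvl / (km["HE"] + cvl)
        r_ha = vmax["HA"] * cvl / (km["HA"] + cvl)
        r_m5 = vmax["M5"] * cvl / (km["M5"] + cvl)

        cvl_he = al_he / vl / pl_he
        ca_he = ab_he / vb
        r_heg = vmax["HEG"] * cvl_he / (km["HEG"] + cvl_he)
        r_oe = vmax["OE"] * cvl_he / (km["OE"] + cvl_he)
        r_hes = vmax["HES"] * cvl_he / (km["HES"] + cvl_he)

        uptake = ka * agi
        he_exchange = ql * (ca_he - cvl_he)

        return (
            -uptake,
            uptake + ql * (ca - cvl) - (r_ap + r_ee + r_he + r_ha + r_m5),
            qf * (ca - cvf),
            qr * (ca - cvr),
            qs * (ca - cvs),
            ql * cvl + qf * cvf + qr * cvr + qs * cvs - q_total * ca,
            r_he - (r_heg + r_oe + r_hes) + he_exchange,
            -he_exchange,
            r_ap, r_ee, r_ha, r_m5,
            r_he, r_heg, r_oe, r_hes,
        )

    return rhs


def ode_rhs(state, spec: PBKModelSpec):
    """Time derivatives of the full state vector (see :data:`STATE_NAMES`)."""
    state = np.asarray(state, dtype=float)
    if state.shape != (len(STATE_NAMES),):
        raise ValueError(f"state must have length {len(STATE_NAMES)}")
    return np.asarray(_make_rhs(spec)(0.0, state))


@dataclass
class SimulationResult:
    """Time-resolved amounts plus 24-h summary metrics for one dose scenario."""

    spec: PBKModelSpec
    dose_mg_per_kg: float
    dose_umol: float
    time_h: np.ndarray
    states: pd.DataFrame  # columns = STATE_NAMES, µmol
    cumulative_umol: dict[str, float]
    liver_he_cmax_uM: float
    liver_he_auc_uM_h: float

    @property
    def percent_of_dose(self) -> dict[str, float]:
        if self.dose_umol == 0:
            return {m: 0.0 for m in METABOLITES}
        return {m: self.cumulative_umol[m] * 100.0 / self.dose_umol for m in METABOLITES}

    @property
    def nmol_per_g_liver(self) -> dict[str, float]:
        volumes, _, _ = derive_flows_volumes(self.spec.physiology)
        liver_g = volumes["liver"] * 1000.0
        return {m: self.cumulative_umol[m] * 1000.0 / liver_g for m in METABOLITES}


def simulate(
    spec: PBKModelSpec,
    dose_mg_per_kg: float,
    duration_h: float = 24.0,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    grid_step_h: float = 0.01,
) -> SimulationResult:
    """Integrate a single oral bolus for ``duration_h`` hours.

    The dose (mg/kg bw) is converted to µmol with the body weight and
    molecular weight and placed in the GI depot.  A stiff-capable solver
    (LSODA) integrates the system; Cmax and AUC of liver
    1'-hydroxyestragole are read off the dense output grid.
    """
    if dose_mg_per_kg < 0:
        raise ValueError("dose must be non-negative")
    bw = spec.physiology.body_weight_kg
    dose_umol = dose_mg_per_kg * bw / spec.mw_estragole * 1000.0

    t_eval = np.linspace(0.0, duration_h, int(round(duration_h / grid_step_h)) + 1)
    y0 = np.zeros(len(STATE_NAMES))
    y0[0] = dose_umol

    if dose_umol == 0.0:
        sol_y = np.zeros((len(STATE_NAMES), t_eval.size))
    else:
        sol = solve_ivp(
            _make_rhs(spec),
            (0.0, duration_h),
            y0,
            method="LSODA",
            rtol=rtol,
            atol=atol,
            t_eval=t_eval,
        )
        if not sol.success:
            raise SolverFailure(f"ODE integration failed: {sol.message}")
        sol_y = sol.y

    states = pd.DataFrame(sol_y.T, columns=list(STATE_NAMES))
    volumes, _, _ = derive_flows_volumes(spec.physiology)
    conc_he = sol_y[STATE_NAMES.index("AL_HE")] / volumes["liver"]  # µM

    cumulative = {m: float(states[f"AM_{m}"].iloc[-1]) for m in METABOLITES}
    return SimulationResult(
        spec=spec,
        dose_mg_per_kg=dose_mg_per_kg,
        dose_umol=dose_umol,
        time_h=t_eval,
        states=states,
        cumulative_umol=cumulative,
        liver_he_cmax_uM=float(conc_he.max()),
        liver_he_auc_uM_h=float(np.trapezoid(conc_he, t_eval)),
    )


def percent_of_dose(result: SimulationResult, metabolite: str) -> float:
    """24-h cumulative formation of ``metabolite`` as % of the oral dose."""
    if metabolite not in METABOLITES:
        raise KeyError(f"unknown metabolite {metabolite!r}")
    return result.percent_of_dose[metabolite]


def amount_per_g_liver(result: SimulationResult, metabolite: str) -> float:
    """24-h cumulative formation of ``metabolite`` in nmol/(g liver)."""
    if metabolite not in METABOLITES:
        raise KeyError(f"unknown metabolite {metabolite!r}")
    return result.nmol_per_g_liver[metabolite]
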