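"""Bundled reference parameter sets and published validation values.

Two population parameter files (``data/chinese.yaml``, ``data/caucasian.yaml``)
carry the physiology, partition coefficients and in vitro kinetic constants
for pooled Chinese and Caucasian liver fractions.  :func:`load_population`
turns one into a :class:`~estragole_pbk.pbk_core.PopulationConfig`.

``PUBLISHED_EFFICIENCY`` and ``PUBLISHED_SCALED`` hold the catalytic
efficiencies and whole-liver scaled constants as originally published in the reference
tables (to their printed precision).  They are validation oracles only —
the package always recomputes these quantities from the in vitro constants.
Note: the printed Chinese 1'-hydroxyestragole efficiency (7.9) is not
reproducible from the printed Km and Vmax (0.35/49 x 1000 = 7.1, presumably
a pre-rounding artifact); the recomputed value is the one this package
reports.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .invitro_kinetics import MMKinetics
from .pbk_core import PartitionSet, Physiology, PopulationConfig

__all__ = [
    "POPULATIONS",
    "PUBLISHED_EFFICIENCY",
    "PUBLISHED_SCALED",
    "load_population",
    "population_from_dict",
    "published_kinetics",
]

POPULATIONS = ("chinese", "caucasian")

#: Printed catalytic efficiencies, µL/min/(mg protein), per population/pathway.
PUBLISHED_EFFICIENCY = {
    "chinese": {
        "AP": 1.3, "EE": 2.6, "HE": 7.9, "HA": 0.71, "M5": 0.29,
        "HEG": 0.35, "OE": 4.5, "HES": 0.002,
    },
    "caucasian": {
        "AP": 2.4, "EE": 12.7, "HE": 19.3, "HA": 2.3, "M5": 0.82,
        "HEG": 0.93, "OE": 5.4, "HES": 0.01,
    },
}

#: Printed scaled constants: (Vmax µmol/h/(g liver), efficiency µL/h/(g liver)).
PUBLISHED_SCALED = {
    "chinese": {
        "AP": (0.3, 2.7), "EE": (0.9, 5.5), "HE": (0.7, 15.0),
        "HA": (0.7, 1.5), "M5": (0.4, 0.6),
        "HEG": (3.4, 0.7), "OE": (15.6, 38.7), "HES": (0.01, 0.02),
    },
    "caucasian": {
        "AP": (1.6, 5.0), "EE": (3.9, 26.6), "HE": (2.5, 40.3),
        "HA": (2.1, 4.8), "M5": (2.5, 1.7),
        "HEG": (9.0, 2.0), "OE": (24.0, 46.1), "HES": (0.03, 0.08),
    },
}


def population_from_dict(raw: dict) -> PopulationConfig:
    """Build a :class:`PopulationConfig` from a parsed parameter file."""
    try:
        phys = raw["physiology"]
        physiology = Physiology(
            body_weight_kg=float(phys["body_weight_kg"]),
            tissue_fraction_pct=phys["tissue_fraction_pct"],
            cardiac_output_constant=float(phys["cardiac_output_constant"]),
            flow_fraction_pct=phys["flow_fraction_pct"],
        )
        partitions = PartitionSet(
            estragole=raw["partition_coefficients"]["estragole"],
            hydroxyestragole=raw["partition_coefficients"]["hydroxyestragole"],
        )
        kinetics = {
            pid: MMKinetics(
                pathway_id=pid,
                protein_source=entry["protein_source"],
                km_uM=float(entry["km_uM"]),
                vmax_invitro=float(entry["vmax_invitro"]),
                km_sem=entry.get("km_sem"),
                vmax_sem=entry.get("vmax_sem"),
            )
            for pid, entry in raw["pathways"].items()
        }
        return PopulationConfig(
            name=raw.get("population", "unnamed"),
            physiology=physiology,
            partitions=partitions,
            kinetics=kinetics,
            ka_per_h=float(raw["absorption"]["ka_per_h"]),
            protein_yields={
                k: float(v)
                for k, v in raw["protein_yields_mg_per_g_liver"].items()
            },
        )
    except KeyError as exc:
        raise ValueError(f"population file is missing section/field {exc}") from exc


def load_population(name: str) -> PopulationConfig:
    """Load a bundled population parameter set (``chinese`` or ``caucasian``)."""
    if name not in POPULATIONS:
        raise KeyError(f"unknown population {name!r}; bundled: {POPULATIONS}")
    text = resources.files("estragole_pbk.data").joinpath(f"{name}.yaml").read_text()
    return population_from_dict(yaml.safe_load(text))


def published_kinetics(population: str, pathway: str) -> MMKinetics:
    """Published in vitro Michaelis-Menten constants for one pathway."""
    return load_population(population).kinetics[pathway]
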