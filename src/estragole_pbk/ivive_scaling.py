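"""In vitro to in vivo extrapolation of hepatic kinetic constants.

In vitro Vmax values, measured per mg of microsomal or S9 protein, are
scaled to the whole liver with protein-yield constants of 35 mg microsomal
protein and 143 mg S9 protein per gram of liver:

    Vmax_scaled [µmol/h/(g liver)] = Vmax_invitro [nmol/min/mg] * yield [mg/g] * 60 / 1000

Km is a concentration and is unchanged by scaling.  The scaled catalytic
efficiency Vmax_scaled/Km x 1000 has units µL/h/(g liver).

The glucuronidation pathway (HEG) was assayed in microsomes (with UDPGA)
and therefore uses the microsomal yield; oxidation (OE) and sulfation
(HES) were assayed in S9 and use the S9 yield.  The same (Caucasian-derived)
yields are applied to both populations, no Chinese-specific liver protein
yields being available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .invitro_kinetics import (
    ESTRAGOLE_PATHWAYS,
    HYDROXYESTRAGOLE_PATHWAYS,
    PATHWAYS,
    MMKinetics,
)

__all__ = [
    "PROTEIN_YIELDS_MG_PER_G",
    "PATHWAY_PARENT",
    "PATHWAY_SOURCE",
    "ScaledPathway",
    "scale_vmax",
    "unscale_vmax",
    "build_scaled_table",
]

#: Liver protein yields, mg protein per g liver.
PROTEIN_YIELDS_MG_PER_G: Mapping[str, float] = {"microsomes": 35.0, "s9": 143.0}

#: Parent chemical of each pathway.
PATHWAY_PARENT: Mapping[str, str] = {
    **{p: "estragole" for p in ESTRAGOLE_PATHWAYS},
    **{p: "hydroxyestragole" for p in HYDROXYESTRAGOLE_PATHWAYS},
}

#: Tissue fraction each pathway was assayed in (fixes the scaling yield).
PATHWAY_SOURCE: Mapping[str, str] = {
    "AP": "microsomes",
    "EE": "microsomes",
    "HE": "microsomes",
    "HA": "microsomes",
    "M5": "microsomes",
    "HEG": "microsomes",
    "OE": "s9",
    "HES": "s9",
}


@dataclass(frozen=True)
class ScaledPathway:
    """Whole-liver kinetics for one metabolic pathway."""

    pathway_id: str
    parent: str
    km_uM: float
    vmax_scaled: float  # µmol/h/(g liver)

    def __post_init__(self):
        if self.pathway_id not in PATHWAYS:
            raise ValueError(f"unknown pathway {self.pathway_id!r}")
        if self.parent != PATHWAY_PARENT[self.pathway_id]:
            raise ValueError(
                f"pathway {self.pathway_id} has parent {PATHWAY_PARENT[self.pathway_id]!r}, "
                f"not {self.parent!r}"
            )
        if not self.km_uM > 0:
            raise ValueError("km_uM must be positive")
        if self.vmax_scaled < 0:
            raise ValueError("vmax_scaled must be non-negative")

    @property
    def efficiency_scaled(self) -> float:
        """Vmax_scaled/Km x 1000, µL/h/(g liver)."""
        return self.vmax_scaled / self.km_uM * 1000.0


def _yield_for(protein_source: str, yields: Mapping[str, float]) -> float:
    try:
        return yields[protein_source]
    except KeyError:
        raise ValueError(
            f"unknown protein source {protein_source!r}; expected one of {sorted(yields)}"
        ) from None


def scale_vmax(
    vmax_invitro: float,
    protein_source: str,
    yields: Mapping[str, float] = PROTEIN_YIELDS_MG_PER_G,
) -> float:
    """nmol/min/(mg protein) -> µmol/h/(g liver)."""
    if vmax_invitro < 0:
        raise ValueError("vmax_invitro must be non-negative")
    return vmax_invitro * _yield_for(protein_source, yields) * 60.0 / 1000.0


def unscale_vmax(
    vmax_scaled: float,
    protein_source: str,
    yields: Mapping[str, float] = PROTEIN_YIELDS_MG_PER_G,
) -> float:
    """Inverse of :func:`scale_vmax` (µmol/h/(g liver) -> nmol/min/mg)."""
    return vmax_scaled / (_yield_for(protein_source, yields) * 60.0 / 1000.0)


def build_scaled_table(
    fits: Iterable[MMKinetics],
    yields: Mapping[str, float] = PROTEIN_YIELDS_MG_PER_G,
) -> list[ScaledPathway]:
    """Scale a collection of in vitro fits to whole-liver pathway kinetics.

    Requires at most one fit per pathway; the scaling yield is fixed by the
    pathway's assay fraction (:data:`PATHWAY_SOURCE`), not by the fit's
    ``protein_source`` tag, which must agree.
    """
    seen: dict[str, ScaledPathway] = {}
    for kin in fits:
        if kin.pathway_id in seen:
            raise ValueError(f"duplicate pathway {kin.pathway_id}")
        expected = PATHWAY_SOURCE[kin.pathway_id]
        if kin.protein_source != expected:
            raise ValueError(
                f"pathway {kin.pathway_id} is assayed in {expected}, "
                f"got protein_source={kin.protein_source!r}"
            )
        seen[kin.pathway_id] = ScaledPathway(
            pathway_id=kin.pathway_id,
            parent=PATHWAY_PARENT[kin.pathway_id],
            km_uM=kin.km_uM,
            vmax_scaled=scale_vmax(kin.vmax_invitro, expected, yields),
        )
    # preserve canonical pathway order
    return [seen[p] for p in PATHWAYS if p in seen]
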