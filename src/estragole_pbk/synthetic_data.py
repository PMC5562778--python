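"""Synthetic in vitro incubation data with realistic noise structure.

Real incubation series (triplicate, substrate grids of 25-1000 µM for the
estragole pathways, extended into the mM range for the high-Km
glucuronidation pathway) are emulated by evaluating the Michaelis-Menten
curve at a concentration grid and applying multiplicative Gaussian noise:

    rate_ij = v(S_i; Km, Vmax) * (1 + eps_ij),   eps ~ N(0, cv),

truncated at -0.99 so rates stay positive.  Multiplicative noise is used
because assay coefficients of variation scale with signal.  Replicate
means and SEMs are computed exactly as they would be for bench data, and a
fixed seed reproduces a dataset bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .invitro_kinetics import InVitroRateDataset, mm_rate
from .ivive_scaling import PATHWAY_SOURCE

__all__ = [
    "ESTRAGOLE_GRID_UM",
    "GLUCURONIDATION_GRID_UM",
    "default_grid",
    "SyntheticSpec",
    "generate_invitro_dataset",
]

#: Default substrate grids, µM.
ESTRAGOLE_GRID_UM = (25.0, 50.0, 100.0, 250.0, 500.0, 1000.0)
#: Extended grid for glucuronidation, whose Km (~4.7 mM) must be spanned.
GLUCURONIDATION_GRID_UM = (100.0, 250.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0)


def default_grid(pathway_id: str) -> tuple[float, ...]:
    return GLUCURONIDATION_GRID_UM if pathway_id == "HEG" else ESTRAGOLE_GRID_UM


@dataclass
class SyntheticSpec:
    """Ground truth and noise model for one synthetic incubation series."""

    pathway_id: str
    true_km_uM: float
    true_vmax: float
    concentrations: Sequence[float] | None = None
    noise_cv: float = 0.10
    n_replicates: int = 3
    seed: int = 0
    protein_source: str | None = None  # defaults to the pathway's assay fraction

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.true_km_uM <= 0:
            raise ValueError("true_km_uM must be positive")
        if self.true_vmax < 0:
            raise ValueError("true_vmax must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.concentrations is None:
            self.concentrations = default_grid(self.pathway_id)
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive")
        if self.protein_source is None:
            self.protein_source = PATHWAY_SOURCE[self.pathway_id]


def generate_invitro_dataset(spec: SyntheticSpec) -> InVitroRateDataset:
    """Draw one noisy triplicate incubation dataset (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    conc = np.asarray(spec.concentrations, dtype=float)
    truth = mm_rate(spec.true_km_uM, spec.true_vmax, conc)
    eps = rng.normal(0.0, spec.noise_cv, size=(spec.n_replicates, conc.size))
    eps = np.maximum(eps, -0.99)
    replicates = truth[None, :] * (1.0 + eps)
    means = replicates.mean(axis=0)
    if spec.n_replicates > 1:
        sems = replicates.std(axis=0, ddof=1) / np.sqrt(spec.n_replicates)
    else:
        sems = None
    return InVitroRateDataset(
        pathway_id=spec.pathway_id,
        protein_source=spec.protein_source,
        concentrations=conc,
        rates=means,
        rate_sems=sems,
        n_replicates=spec.n_replicates,
    )
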