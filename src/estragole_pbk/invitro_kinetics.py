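"""Michaelis-Menten analysis of in vitro incubation data.

Eight hepatic pathways are tracked.  Five consume estragole (microsomal
incubations): 4-allylphenol (``AP``), estragole-2',3'-oxide (``EE``),
1'-hydroxyestragole (``HE``), 3'-hydroxyanethole (``HA``) and an
unidentified minor metabolite (``M5``).  Three consume 1'-hydroxyestragole:
glucuronidation (``HEG``, microsomes + UDPGA), oxidation to 1'-oxoestragole
(``OE``, S9 + NAD+) and sulfation to the ultimate carcinogen
1'-sulfooxyestragole (``HES``, S9 + PAPS).

Rates are in nmol/min/(mg microsomal or S9 protein), substrate
concentrations in µM.  Catalytic efficiency is Vmax/Km x 1000, in
µL/min/(mg protein) — the first-order rate constant of the pathway in the
low-substrate limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "PATHWAYS",
    "PROTEIN_SOURCES",
    "InVitroRateDataset",
    "MMKinetics",
    "FitError",
    "FoldDifference",
    "mm_rate",
    "fit_michaelis_menten",
    "catalytic_efficiency_invitro",
    "fold_difference",
]

#: Pathway identifiers, grouped by parent chemical.
ESTRAGOLE_PATHWAYS = ("AP", "EE", "HE", "HA", "M5")
HYDROXYESTRAGOLE_PATHWAYS = ("HEG", "OE", "HES")
PATHWAYS = ESTRAGOLE_PATHWAYS + HYDROXYESTRAGOLE_PATHWAYS

PROTEIN_SOURCES = ("microsomes", "s9")

# Fit bounds and convergence tolerance.
KM_BOUNDS_UM = (1e-12, 1e7)
VMAX_BOUNDS = (0.0, 1e3)
SSE_RTOL = 1e-10


class FitError(RuntimeError):
    """Michaelis-Menten fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def _validate_pathway(pathway_id: str) -> str:
    if pathway_id not in PATHWAYS:
        raise ValueError(f"unknown pathway {pathway_id!r}; expected one of {PATHWAYS}")
    return pathway_id


def _validate_source(protein_source: str) -> str:
    src = protein_source.lower()
    if src not in PROTEIN_SOURCES:
        raise ValueError(
            f"unknown protein source {protein_source!r}; expected one of {PROTEIN_SOURCES}"
        )
    return src


@dataclass
class InVitroRateDataset:
    """One incubation series: mean formation rate vs substrate concentration.

    ``concentrations`` (µM) must be positive; the series is sorted by
    concentration on construction.  ``rates`` are replicate means in
    nmol/min/(mg protein); ``rate_sems`` optional standard errors.
    """

    pathway_id: str
    protein_source: str
    concentrations: np.ndarray
    rates: np.ndarray
    rate_sems: np.ndarray | None = None
    n_replicates: int = 1

    def __post_init__(self):
        self.pathway_id = _validate_pathway(self.pathway_id)
        self.protein_source = _validate_source(self.protein_source)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.concentrations.ndim != 1:
            raise ValueError("concentrations must be one-dimensional")
        if self.concentrations.shape != self.rates.shape:
            raise ValueError("concentrations and rates must have equal length")
        if np.any(self.concentrations <= 0):
            raise ValueError("substrate concentrations must be strictly positive")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")
        order = np.argsort(self.concentrations)
        self.concentrations = self.concentrations[order]
        self.rates = self.rates[order]
        if self.rate_sems is not None:
            self.rate_sems = np.asarray(self.rate_sems, dtype=float)[order]
        if np.any(np.diff(self.concentrations) == 0):
            raise ValueError("concentrations must be distinct")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class MMKinetics:
    """Fitted (or published) Michaelis-Menten constants for one pathway."""

    pathway_id: str
    protein_source: str
    km_uM: float
    vmax_invitro: float  # nmol/min/(mg protein)
    km_sem: float | None = None
    vmax_sem: float | None = None
    diagnostics: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        self.pathway_id = _validate_pathway(self.pathway_id)
        self.protein_source = _validate_source(self.protein_source)
        if not self.km_uM > 0:
            raise ValueError("km_uM must be positive")
        if self.vmax_invitro < 0:
            raise ValueError("vmax_invitro must be non-negative")


def mm_rate(km_uM, vmax, substrate_uM):
    """Michaelis-Menten rate v = Vmax * S / (Km + S).

    Accepts scalars or arrays for ``substrate_uM``.  Zero at S = 0,
    approaches Vmax as S grows.
    """
    km_uM = float(km_uM)
    if not km_uM > 0:
        raise ValueError("km_uM must be positive")
    s = np.asarray(substrate_uM, dtype=float)
    if np.any(s < 0):
        raise ValueError("substrate_uM must be non-negative")
    v = vmax * s / (km_uM + s)
    return v if v.ndim else float(v)


def _sse(conc, rates, km, vmax):
    return float(np.sum((rates - vmax * conc / (km + conc)) ** 2))


def fit_michaelis_menten(dataset: InVitroRateDataset) -> MMKinetics:
    """Unweighted least-squares fit of (Km, Vmax) to a rate dataset.

    Fits on replicate means with non-negative bounds and a small multistart
    over the initial Km guess (0.1x, 1x, 10x the interpolated half-maximum
    concentration) to avoid local minima.  Reported uncertainties are
    asymptotic standard errors from the Jacobian.

    An all-zero dataset is degenerate: Vmax = 0 and Km is unidentifiable;
    the returned kinetics carry a ``km_unidentifiable`` diagnostic flag.
    """
    conc, rates = dataset.concentrations, dataset.rates
    if conc.size < 2:
        raise ValueError("need at least as many points as parameters (2)")

    diagnostics: dict = {"n_points": int(conc.size)}
    span = conc.max() / conc.min()
    if conc.size < 4 or span < 10:
        diagnostics["design_warning"] = (
            f"{conc.size} concentrations spanning {span:.1f}-fold; "
            "4 points over a 10-fold range are recommended"
        )

    if np.all(rates == 0):
        diagnostics["km_unidentifiable"] = True
        return MMKinetics(
            dataset.pathway_id,
            dataset.protein_source,
            km_uM=float(np.median(conc)),
            vmax_invitro=0.0,
            diagnostics=diagnostics,
        )

    vmax0 = float(rates.max())
    half = vmax0 / 2.0
    # interpolated concentration at half-maximal rate (rates already sorted by S)
    km0 = float(np.interp(half, rates, conc)) if rates[0] < half else float(conc[0])
    km0 = min(max(km0, KM_BOUNDS_UM[0]), KM_BOUNDS_UM[1])

    best = None
    failures = []
    for mult in (0.1, 1.0, 10.0):
        p0 = (km0 * mult, vmax0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    lambda s, km, vm: vm * s / (km + s),
                    conc,
                    rates,
                    p0=p0,
                    bounds=(
                        [KM_BOUNDS_UM[0], VMAX_BOUNDS[0]],
                        [KM_BOUNDS_UM[1], VMAX_BOUNDS[1]],
                    ),
                    ftol=SSE_RTOL,
                    xtol=1e-12,
                    maxfev=20000,
                )
        except (RuntimeError, ValueError) as exc:
            failures.append(f"start {p0}: {exc}")
            continue
        sse = _sse(conc, rates, *popt)
        if best is None or sse < best[2]:
            best = (popt, pcov, sse)

    if best is None:
        raise FitError(
            "Michaelis-Menten fit did not converge from any start",
            {"starts": failures, **diagnostics},
        )

    (km, vmax), pcov, sse = best
    perr = np.sqrt(np.diag(pcov))
    diagnostics["sse"] = sse
    return MMKinetics(
        dataset.pathway_id,
        dataset.protein_source,
        km_uM=float(km),
        vmax_invitro=float(vmax),
        km_sem=float(perr[0]) if np.isfinite(perr[0]) else None,
        vmax_sem=float(perr[1]) if np.isfinite(perr[1]) else None,
        diagnostics=diagnostics,
    )


def catalytic_efficiency_invitro(kin: MMKinetics) -> float:
    """Vmax/Km x 1000, in µL/min/(mg protein)."""
    return kin.vmax_invitro / kin.km_uM * 1000.0


class FoldDifference(NamedTuple):
    """Ratio of two positive quantities, always >= 1, with direction."""

    ratio: float
    lower: str  # label of the smaller value

    def __float__(self):
        return self.ratio


def fold_difference(
    reference: float | MMKinetics,
    other: float | MMKinetics,
    labels: Sequence[str] = ("reference", "other"),
) -> FoldDifference:
    """larger/smaller ratio of two efficiencies (or any positive scalars).

    ``MMKinetics`` arguments are converted to catalytic efficiencies.
    """
    a = catalytic_efficiency_invitro(reference) if isinstance(reference, MMKinetics) else float(reference)
    b = catalytic_efficiency_invitro(other) if isinstance(other, MMKinetics) else float(other)
    if a <= 0 or b <= 0:
        raise ValueError("fold difference requires two positive values")
    if a >= b:
        return FoldDifference(a / b, labels[1])
    return FoldDifference(b / a, labels[0])
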