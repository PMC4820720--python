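"""Stable Sr and Ca determination from ICP-AES intensities.

The incinerated tooth ash is dissolved (1 g in 10 mL of acid) and an
aliquot diluted 10,000-fold before nebulization.  Stable Sr is quantified
by standard addition (robust to the heavy Ca matrix); Ca by an external
calibration curve.  Both reduce to straight-line fits of intensity against
concentration; all measurements are run in triplicate and summarized as
mean ± sample SD.  The resulting composition normalizes decay-corrected
⁹⁰Sr activities two ways: activity concentration in mBq per g Ca (the
contamination metric) and specific activity in Bq per g stable Sr (the
isotopic-enrichment metric).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from statistics import mean as _mean

import numpy as np

__all__ = [
    "ElementAssay",
    "ToothComposition",
    "NormalizedActivity",
    "standard_addition_concentration",
    "calibration_curve_concentration",
    "triplicate_summary",
    "normalize_activity",
]

#: statuses a tooth record can carry; only "ok" enters statistics
STATUSES = ("ok", "fallen_out", "separation_failed")


@dataclass(frozen=True)
class ElementAssay:
    """One element's ICP measurement for one sample.

    ``points`` pairs the added (standard-addition) or standard
    (calibration-curve) concentration in µg L⁻¹ with the measured intensity.
    ``dilution_factor`` and the dissolution geometry convert a solution
    concentration back to µg per g of ash.
    """

    sample_id: str
    element: str  # "Sr" or "Ca"
    method: str  # "standard_addition" or "calibration_curve"
    points: tuple[tuple[float, float], ...]
    dilution_factor: float = 10_000.0
    dissolution_volume_L: float = 0.010
    ash_mass_g: float = 1.0

    def __post_init__(self) -> None:
        if self.method not in ("standard_addition", "calibration_curve"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.element not in ("Sr", "Ca"):
            raise ValueError(f"unknown element {self.element!r}")
        if any(i < 0 for _, i in self.points):
            raise ValueError("intensities must be nonnegative")

    @property
    def solution_to_ash_factor(self) -> float:
        """µg per g ash per (µg L⁻¹ in the diluted solution)."""
        return self.dilution_factor * self.dissolution_volume_L / self.ash_mass_g


@dataclass(frozen=True)
class ToothComposition:
    """Elemental composition of one incinerated tooth sample."""

    sample_id: str
    sr_ug_g_mean: float
    sr_ug_g_sd: float
    ca_frac_mean: float
    ca_frac_sd: float
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "ok":
            if self.sr_ug_g_mean <= 0:
                raise ValueError("Sr concentration must be positive")
            if not 0.0 < self.ca_frac_mean < 1.0:
                raise ValueError("Ca fraction must lie in (0, 1)")


@dataclass(frozen=True)
class NormalizedActivity:
    activity_conc: float  # mBq per g Ca
    specific_activity: float  # Bq per g stable Sr


class AssayFitError(ValueError):
    """Raised when an intensity–concentration line cannot be fitted."""


def _fit_line(conc: np.ndarray, intensity: np.ndarray) -> tuple[float, float]:
    """OLS intensity = a + b·conc; returns (a, b)."""
    if np.unique(conc).size < 2:
        raise AssayFitError("need >=2 distinct concentration points")
    b, a = np.polyfit(conc, intensity, 1)
    return float(a), float(b)


def standard_addition_concentration(assay: ElementAssay) -> float:
    """Native concentration by standard addition, in µg per g of ash.

    Fits intensity = a + b·added; the solution concentration is the
    x-axis intercept magnitude a/b, scaled by the dilution and dissolution
    geometry.  A nonpositive slope means the spikes did not raise the
    signal — a failed calibration, not a concentration.
    """
    if assay.method != "standard_addition":
        raise ValueError("assay method is not standard_addition")
    conc = np.array([c for c, _ in assay.points], dtype=float)
    inten = np.array([i for _, i in assay.points], dtype=float)
    a, b = _fit_line(conc, inten)
    if b <= 0:
        raise AssayFitError(
            f"sample {assay.sample_id!r}: nonpositive standard-addition slope"
        )
    solution_ug_L = a / b
    return solution_ug_L * assay.solution_to_ash_factor


def calibration_curve_concentration(
    assay: ElementAssay, sample_intensity: float
) -> float:
    """Concentration by inverse prediction from an external standard line,
    in µg per g of ash.  Sample intensities outside the standard range
    trigger an extrapolation warning."""
    if assay.method != "calibration_curve":
        raise ValueError("assay method is not calibration_curve")
    conc = np.array([c for c, _ in assay.points], dtype=float)
    inten = np.array([i for _, i in assay.points], dtype=float)
    a, b = _fit_line(conc, inten)
    scale = float(np.max(np.abs(inten))) + 1.0
    span = float(np.ptp(conc)) or 1.0
    if abs(b) <= 1e-9 * scale / span:
        raise AssayFitError(f"sample {assay.sample_id!r}: zero calibration slope")
    lo, hi = inten.min(), inten.max()
    if not lo <= sample_intensity <= hi:
        warnings.warn(
            f"sample {assay.sample_id!r}: intensity {sample_intensity:g} outside "
            f"standard range [{lo:g}, {hi:g}]; extrapolating",
            stacklevel=2,
        )
    solution_ug_L = (sample_intensity - a) / b
    return solution_ug_L * assay.solution_to_ash_factor


def triplicate_summary(values) -> tuple[float, float]:
    """Mean and sample SD (n−1) of replicate measurements.

    The lab protocol runs triplicates; fewer replicates are summarized
    anyway but flagged with a warning.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size != 3:
        warnings.warn(
            f"expected triplicate, got {vals.size} replicates", stacklevel=2
        )
    if vals.size < 2:
        return float(vals[0]), 0.0
    return float(vals.mean()), float(vals.std(ddof=1))


def normalize_activity(
    activity_ref_mBq: float,
    ash_mass_g: float,
    comp: ToothComposition,
) -> NormalizedActivity:
    """Normalize a decay-corrected activity (mBq) to the sample's Ca and Sr.

    activity_conc = A / (m_ash · f_Ca)          [mBq (g Ca)⁻¹]
    specific      = (A/1000) / (m_ash · c_Sr)   [Bq (g Sr)⁻¹], c_Sr in g/g
    """
    if ash_mass_g <= 0:
        raise ValueError("ash mass must be positive")
    if comp.status != "ok":
        raise ValueError(f"cannot normalize sample with status {comp.status!r}")
    if comp.ca_frac_mean <= 0 or comp.sr_ug_g_mean <= 0:
        raise ValueError("Ca and Sr contents must be positive")
    activity_conc = activity_ref_mBq / (ash_mass_g * comp.ca_frac_mean)
    specific = (activity_ref_mBq / 1000.0) / (ash_mass_g * comp.sr_ug_g_mean * 1e-6)
    return NormalizedActivity(activity_conc=activity_conc, specific_activity=specific)
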