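"""Susceptibility extraction calculus.

The slice-selection measurement reads the solvent frequency in a thin
layer at the flat interface with a solid and far above it. Flux
conservation across the interface makes the interface reading the mean
of the two susceptibilities, so

    χ_solid = χ_solvent + 2·(δ_interface − δ_bulk)            (ppm)

with the solvent reference corrected for isotope composition. The same
linear calculus covers the NaCl dependence of aqueous χ and the
paramagnetic-doping calibration of printer resin.

Sign convention: δ = interface peak minus bulk peak; an upfield
(negative) shift means the solid is more diamagnetic than the solvent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    CHI_D2O_PPM,
    CHI_H2O_PPM,
    DEFAULT_SPECTROMETER_MHZ,
    NACL_RANGE_M,
    NACL_SLOPE_PPM_PER_M,
)

__all__ = [
    "InterfaceMeasurement",
    "LinearCalibration",
    "mixture_chi",
    "chi_from_interface_shift",
    "isotope_chi_difference",
    "salt_chi",
    "fit_linear",
    "doping_zero_crossing",
    "hz_to_ppm",
    "extract_chi",
]


def hz_to_ppm(shift_hz: float, spectrometer_mhz: float = DEFAULT_SPECTROMETER_MHZ) -> float:
    """Convert a frequency difference in Hz to ppm."""
    if spectrometer_mhz <= 0:
        raise ValueError("spectrometer frequency must be > 0")
    return shift_hz / spectrometer_mhz


def mixture_chi(components) -> float:
    """Fraction-weighted susceptibility of a solvent mixture.

    ``components`` is an iterable of (fraction, χ/ppm); fractions must be
    non-negative and sum to 1.
    """
    comps = [(float(f), float(chi)) for f, chi in components]
    fracs = np.array([f for f, _ in comps])
    if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must be >= 0 and sum to 1, got {fracs}")
    return float(sum(f * chi for f, chi in comps))


def chi_from_interface_shift(delta_ppm: float, chi_solvent: float) -> float:
    """Solid susceptibility from the interface-minus-bulk shift (ppm):
    the interface reads (χ_solid + χ_solvent)/2, so
    χ_solid = χ_solvent + 2·δ."""
    return chi_solvent + 2.0 * delta_ppm


def isotope_chi_difference(shift_diff_ppm: float, fraction_span: float) -> float:
    """χ difference of two isotopologues from paired interface
    measurements against the same solid.

    ``shift_diff_ppm`` is the difference between the two samples'
    interface shifts and ``fraction_span`` the difference in protonation
    fraction between them (0.94 for a 97%/3% pair measured both ways).
    Δχ = 2·Δδ / span.
    """
    if not 0 < fraction_span <= 1:
        raise ValueError("fraction_span must lie in (0, 1]")
    return 2.0 * shift_diff_ppm / fraction_span


def salt_chi(concentration_m: float, solvent: str = "D2O") -> float:
    """Aqueous susceptibility (ppm) at a NaCl molarity.

    Linear model χ = 0.2·[NaCl] + χ0 with χ0 = −9.01 (D2O) or −9.05
    (H2O), validated over 0–2 M; extrapolation warns.
    """
    if concentration_m < 0:
        raise ValueError("concentration must be >= 0")
    try:
        intercept = {"D2O": CHI_D2O_PPM, "H2O": CHI_H2O_PPM}[solvent]
    except KeyError:
        raise ValueError("solvent must be 'H2O' or 'D2O'") from None
    lo, hi = NACL_RANGE_M
    if not lo <= concentration_m <= hi:
        warnings.warn(f"NaCl model validated for {lo}-{hi} M; "
                      f"extrapolating to {concentration_m} M", UserWarning,
                      stacklevel=2)
    return NACL_SLOPE_PPM_PER_M * concentration_m + intercept


@dataclass
class LinearCalibration:
    """Ordinary-least-squares line y = slope·x + intercept."""

    slope: float
    intercept: float
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_points: int = 0

    def __post_init__(self):
        self.residuals = np.asarray(self.residuals, dtype=np.float64)
        if self.n_points and self.residuals.size not in (0, self.n_points):
            raise ValueError("residuals length must equal the number of points")

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=np.float64) + self.intercept

    @property
    def x_intercept(self) -> float:
        if self.slope == 0:
            raise ZeroDivisionError("horizontal line has no x intercept")
        return -self.intercept / self.slope


def fit_linear(points) -> LinearCalibration:
    """OLS fit of (x, y) pairs; requires >= 2 distinct x values."""
    pts = np.asarray(list(points), dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all x values identical")
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return LinearCalibration(slope=float(coef[0]), intercept=float(coef[1]),
                             residuals=resid, n_points=pts.shape[0])


def doping_zero_crossing(points) -> float:
    """Dopant concentration at which the interface shift crosses zero,
    i.e. the solid is susceptibility-matched to the solvent.

    Fits all supplied (concentration, shift) points by OLS and returns
    the root of the line. Points must bracket a sign change; otherwise
    the value is an extrapolation and a warning is issued.
    """
    pts = np.asarray(list(points), dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 (concentration, shift) points")
    cal = fit_linear(pts)
    x0 = cal.x_intercept
    shifts = pts[:, 1]
    if shifts.min() > 0 or shifts.max() < 0:
        warnings.warn("shifts do not change sign within the point range; "
                      "zero crossing is an extrapolation", UserWarning,
                      stacklevel=2)
    return float(x0)


@dataclass
class InterfaceMeasurement:
    """One slice-selected interface measurement.

    Offsets may be given in ppm or Hz (set ``units='hz'``); the solvent
    reference is a list of (fraction, χ/ppm) components.
    """

    interface_peak: float
    bulk_peak: float
    solvent_components: list[tuple[float, float]]
    units: str = "ppm"
    spectrometer_mhz: float = DEFAULT_SPECTROMETER_MHZ

    def __post_init__(self):
        if self.units not in ("ppm", "hz"):
            raise ValueError("units must be 'ppm' or 'hz'")
        if not (np.isfinite(self.interface_peak) and np.isfinite(self.bulk_peak)):
            raise ValueError("peak offsets must be finite")
        mixture_chi(self.solvent_components)  # validates fractions

    @property
    def delta_ppm(self) -> float:
        d = self.interface_peak - self.bulk_peak
        if self.units == "hz":
            d = hz_to_ppm(d, self.spectrometer_mhz)
        return d

    @property
    def chi_solvent(self) -> float:
        return mixture_chi(self.solvent_components)


def extract_chi(measurement: InterfaceMeasurement, *, decimals: int = 2) -> dict:
    """Run the extraction chain and return a report dict.

    Reported χ is rounded to ``decimals`` (the measurement's meaningful
    precision); the unrounded value is included as ``chi_solid_raw``.
    """
    delta = measurement.delta_ppm
    chi_solvent = measurement.chi_solvent
    chi_solid = chi_from_interface_shift(delta, chi_solvent)
    return {
        "delta_ppm": delta,
        "chi_solvent_ppm": chi_solvent,
        "chi_solid_raw": chi_solid,
        "chi_solid_ppm": round(chi_solid, decimals),
        "solvent_components": list(measurement.solvent_components),
        "spectrometer_mhz": measurement.spectrometer_mhz,
    }
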