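"""Spectral pretreatments: full MSC and Savitzky-Golay second derivative.

Multiplicative scatter correction (MSC) regresses each spectrum on a
reference spectrum (here the calibration-set mean) over the whole retained
window and removes the fitted additive offset and multiplicative slope.
"Full" distinguishes it from segment-wise variants. The Savitzky-Golay
second derivative fits an order-2 polynomial over a moving window of 11 or
21 points and differentiates it analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .spectra_io import GridMismatchError, SpectraSet, Spectrum, WavelengthGrid

__all__ = [
    "PretreatmentSpec",
    "MSCModel",
    "fit_msc",
    "apply_msc",
    "msc_coefficients",
    "sg_second_derivative",
    "apply_pretreatment",
]

METHODS = ("raw", "msc_full", "sg_second_derivative")


@dataclass(frozen=True)
class PretreatmentSpec:
    """Which pretreatment to apply and its parameters.

    ``window`` (odd; 11 or 21 in routine use) and ``polyorder`` concern only
    the derivative method. ``derivative_units`` selects d2A/dindex2 (step-free)
    or d2A/dnm2; the choice rescales the matrix uniformly and cannot alter
    PLS predictions.
    """

    method: str = "raw"
    window: int = 11
    polyorder: int = 2
    derivative_order: int = 2
    derivative_units: str = "per_index"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown pretreatment method {self.method!r}")
        if self.method == "sg_second_derivative":
            if self.window % 2 == 0 or self.window <= 2:
                raise ValueError(f"SG window must be odd and > 2, got {self.window}")
            if self.window <= self.polyorder:
                raise ValueError("SG window must exceed the polynomial order")
            if self.derivative_order != 2 or self.polyorder != 2:
                raise ValueError("only the order-2 polynomial second derivative is supported")
        if self.derivative_units not in ("per_index", "per_nm"):
            raise ValueError(f"unknown derivative units {self.derivative_units!r}")


@dataclass(frozen=True)
class MSCModel:
    """The MSC reference spectrum (calibration-set mean) and its grid."""

    grid: WavelengthGrid
    reference: np.ndarray

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float)
        if ref.size != len(self.grid):
            raise GridMismatchError("reference length does not match grid")
        object.__setattr__(self, "reference", ref)


def fit_msc(cal: SpectraSet) -> MSCModel:
    """Fit the MSC reference as the arithmetic mean of the calibration set."""
    if len(cal) < 2:
        raise ValueError(f"MSC needs at least 2 calibration spectra, got {len(cal)}")
    return MSCModel(cal.grid, cal.to_matrix().mean(axis=0))


def msc_coefficients(model: MSCModel, s: Spectrum) -> tuple[float, float]:
    """OLS intercept a and slope b of s = a + b * reference."""
    if s.absorbance.size != len(model.grid):
        raise GridMismatchError("spectrum grid does not match MSC reference")
    m = model.reference
    mc = m - m.mean()
    denom = float(mc @ mc)
    if denom < 1e-24:
        raise ValueError("MSC reference has zero variance")
    b = float(mc @ (s.absorbance - s.absorbance.mean())) / denom
    a = float(s.absorbance.mean() - b * m.mean())
    return a, b


def apply_msc(model: MSCModel, s: Spectrum) -> Spectrum:
    """Scatter-correct one spectrum: (s - a) / b with a, b fitted by OLS."""
    a, b = msc_coefficients(model, s)
    if abs(b) < 1e-12:
        raise ValueError(
            f"degenerate spectrum {s.sample_id!r}: fitted MSC slope {b:g} is ~0"
        )
    return replace(s, absorbance=(s.absorbance - a) / b)


def sg_second_derivative(s: Spectrum, spec: PretreatmentSpec, grid: WavelengthGrid) -> Spectrum:
    """Savitzky-Golay second derivative of one spectrum.

    Edge points are evaluated from the polynomial fitted to the nearest full
    window, keeping the output length equal to the input length.
    """
    if spec.method != "sg_second_derivative":
        raise ValueError("spec.method must be sg_second_derivative")
    if spec.window > s.absorbance.size:
        raise ValueError(
            f"SG window {spec.window} exceeds spectrum length {s.absorbance.size}"
        )
    delta = grid.step if spec.derivative_units == "per_nm" else 1.0
    deriv = savgol_filter(
        s.absorbance, window_length=spec.window, polyorder=spec.polyorder,
        deriv=2, delta=delta, mode="interp",
    )
    return replace(s, absorbance=deriv)


def apply_pretreatment(
    spectra_set: SpectraSet,
    spec: PretreatmentSpec,
    msc: MSCModel | None = None,
) -> SpectraSet:
    """Apply one pretreatment to every spectrum of a set.

    For ``msc_full`` the MSC model must have been fitted on the calibration
    set; prediction spectra are corrected against that same reference (never
    refit on prediction data).
    """
    if spec.method == "msc_full" and msc is None:
        raise ValueError("msc_full requires a fitted MSCModel")
    if spec.method != "msc_full" and msc is not None:
        raise ValueError(f"MSCModel given but method is {spec.method!r}")
    if spec.method == "raw":
        return spectra_set
    if spec.method == "msc_full":
        assert msc is not None
        return SpectraSet(spectra_set.grid, tuple(apply_msc(msc, s) for s in spectra_set.spectra))
    return SpectraSet(
        spectra_set.grid,
        tuple(sg_second_derivative(s, spec, spectra_set.grid) for s in spectra_set.spectra),
    )
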