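"""Calibration/prediction statistics and spectral band interpretation.

With d = X - Y (measured minus predicted, both in % w/w):

    r     Pearson correlation between X and Y
    bias  mean(d)
    SEP   sqrt[(sum d^2 - (sum d)^2 / N) / (N - 1)]   (bias-corrected)
    RMSEP sqrt(sum d^2 / N)
    RPD   SD(reference values of the evaluated set) / SEP

The same dispersion statistic computed on calibration residuals is reported
as SEC. These satisfy RMSEP^2 = SEP^2 (N-1)/N + bias^2 exactly. Model
applicability is graded from r using Williams' correlation bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "PredictionMetrics",
    "BandTable",
    "DEFAULT_BAND_TABLE",
    "evaluate_predictions",
    "classify_williams",
    "find_coefficient_peaks",
    "assign_bands",
    "rpd",
]


@dataclass(frozen=True)
class PredictionMetrics:
    """Performance statistics of one model on one sample set."""

    n: int
    r: float
    stderr: float          # SEC for the calibration role, SEP for prediction
    bias: float
    rmsep: float
    rpd: float
    role: str = "prediction"
    model_h: int | None = None
    williams_class: str = ""

    @property
    def sep(self) -> float:
        return self.stderr

    @property
    def sec(self) -> float:
        return self.stderr


@dataclass(frozen=True)
class BandTable:
    """Literature band assignments: (center nm, tolerance nm, assignment)."""

    rows: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        centers = [r[0] for r in self.rows]
        if len(set(centers)) != len(centers):
            raise ValueError("band centers must be unique")
        if any(r[1] <= 0 for r in self.rows):
            raise ValueError("band tolerances must be positive")


#: Bands relevant to pigments, water, protein and oil in intact citrus peel.
DEFAULT_BAND_TABLE = BandTable(
    rows=(
        (662.0, 6.0, "chlorophyll-a"),
        (680.0, 6.0, "chlorophyll"),
        (708.0, 6.0, "protein"),
        (740.0, 4.0, "C-H fourth overtone (CH3)"),
        (746.0, 4.0, "C-H fourth overtone (CH2)"),
        (808.0, 6.0, "protein"),
        (827.0, 6.0, "aliphatic hydrocarbon C-H"),
        (908.0, 6.0, "protein"),
        (928.0, 6.0, "oil"),
        (961.0, 14.0, "water"),
    )
)


def rpd(set_sd: float, sep: float) -> float:
    """Ratio of reference-value SD to SEP for the evaluated set."""
    if sep <= 0:
        raise ValueError("SEP must be positive to form an RPD")
    return set_sd / sep


def evaluate_predictions(
    measured: np.ndarray,
    predicted: np.ndarray,
    role: str = "prediction",
    model_h: int | None = None,
    set_sd: float | None = None,
) -> PredictionMetrics:
    """Compute r, SEC/SEP, bias, RMSEP, RPD and the Williams grade.

    ``set_sd`` is the reference-value SD of the evaluated set; it defaults
    to the sample SD of ``measured``.
    """
    X = np.asarray(measured, dtype=float).ravel()
    Y = np.asarray(predicted, dtype=float).ravel()
    if X.size != Y.size:
        raise ValueError("measured and predicted must have the same length")
    n = X.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    if role not in ("calibration", "prediction"):
        raise ValueError(f"unknown role {role!r}")
    if np.ptp(X) == 0 or np.ptp(Y) == 0:
        raise ValueError("zero variance in measured or predicted values: r undefined")

    r = float(np.corrcoef(X, Y)[0, 1])
    d = X - Y
    bias = float(d.sum() / n)
    stderr = float(np.sqrt((np.sum(d * d) - d.sum() ** 2 / n) / (n - 1)))
    rmsep = float(np.sqrt(np.sum(d * d) / n))
    sd = float(np.std(X, ddof=1)) if set_sd is None else float(set_sd)
    return PredictionMetrics(
        n=n, r=r, stderr=stderr, bias=bias, rmsep=rmsep,
        rpd=(sd / stderr if stderr > 0 else float("inf")),
        role=role, model_h=model_h, williams_class=classify_williams(r),
    )


def classify_williams(r: float) -> str:
    """Grade NIR model applicability from the prediction correlation.

    Bands (upper edges inclusive): below 0.51 not applicable; up to 0.70
    poor; up to 0.80 very rough to rough screening; up to 0.90 screening /
    approximate calibration; above 0.90 quantitative.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    if r < 0.51:
        return "not applicable"
    if r < 0.71:
        return "poor"
    if r < 0.81:
        return "very rough to rough screening"
    if r <= 0.90:
        return "screening / approximate calibration"
    return "quantitative"


def find_coefficient_peaks(
    wavelengths: np.ndarray,
    values: np.ndarray,
    min_prominence: float = 0.1,
) -> list[tuple[float, float]]:
    """Local extrema of |values| with prominence >= min_prominence * max|values|.

    Returns (wavelength, signed value) pairs sorted by |value| descending,
    ties broken by wavelength.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty coefficient vector")
    mag = np.abs(values)
    scale = mag.max()
    if scale == 0:
        return []
    idx, _ = find_peaks(mag, prominence=min_prominence * scale)
    peaks = [(float(wavelengths[i]), float(values[i])) for i in idx]
    peaks.sort(key=lambda p: (-abs(p[1]), p[0]))
    return peaks


def assign_bands(
    peaks: list[float],
    table: BandTable = DEFAULT_BAND_TABLE,
) -> list[tuple[float, str]]:
    """Attach the nearest in-tolerance literature assignment to each peak."""
    out = []
    for wl in peaks:
        best, best_dist = "unassigned", np.inf
        for center, tol, name in table.rows:
            dist = abs(wl - center)
            if dist <= tol and dist < best_dist:
                best, best_dist = name, dist
        out.append((float(wl), best))
    return out
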