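"""Published summary statistics of the pomelo peel essential-oil study.

The original fruit spectra are not publicly deposited; what the study
reports are per-set reference statistics (sample counts, ranges, means,
SDs) and the performance of the best PLS model per constituent
(pretreatment, latent variables, r, SEC, SEP, bias). These printed numbers
are inputs from which the derived ratios — RPD = prediction-set SD / SEP
and SEP:SEC — can be recomputed and checked against the printed values.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SetStats", "ModelStats", "SET_STATS", "MODEL_STATS"]


@dataclass(frozen=True)
class SetStats:
    """Reference-value statistics of one calibration or prediction set."""

    n: int
    low: float
    high: float
    mean: float
    sd: float


@dataclass(frozen=True)
class ModelStats:
    """Reported performance of the best PLS model for one constituent."""

    pretreatment: str
    n_components: int
    r_cal: float
    sec: float
    r_pred: float
    sep: float
    bias_pred: float
    rpd_printed: float


#: (calibration, prediction) reference statistics per constituent, % w/w.
SET_STATS: dict[str, tuple[SetStats, SetStats]] = {
    "nootkatone": (
        SetStats(71, 0.02, 0.98, 0.26, 0.22),
        SetStats(24, 0.04, 0.68, 0.26, 0.19),
    ),
    "beta_phellandrene": (
        SetStats(87, 3.67, 7.54, 5.57, 0.92),
        SetStats(32, 3.99, 7.36, 5.54, 0.90),
    ),
    "geranial": (
        SetStats(90, 0.16, 0.51, 0.33, 0.06),
        SetStats(34, 0.23, 0.42, 0.32, 0.05),
    ),
    "limonene": (
        SetStats(93, 76.02, 87.82, 81.79, 2.72),
        SetStats(33, 78.17, 85.94, 81.71, 2.39),
    ),
}

#: Best-model performance per constituent as published.
MODEL_STATS: dict[str, ModelStats] = {
    "nootkatone": ModelStats("msc_full", 4, 0.85, 0.11, 0.82, 0.11, 0.01, 1.7),
    "beta_phellandrene": ModelStats("sg_second_derivative", 5, 0.73, 0.63, 0.75, 0.59, -0.01, 1.5),
    "geranial": ModelStats("msc_full", 12, 0.84, 0.03, 0.76, 0.03, 0.02, 1.5),
    "limonene": ModelStats("raw", 10, 0.76, 1.76, 0.67, 1.82, 0.35, 1.3),
}
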