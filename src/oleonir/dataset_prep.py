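"""Outlier screening, distribution trimming and the rank-ordered 5:2 split.

Outliers are screened by PCA with Hotelling T2 (score space) and Q residual
(model residual space) limits; flagged spectra are reported, never removed
automatically. Trimming flattens a peaked reference-value distribution
toward a rectangle by capping the number of samples per equal-width bin.
The calibration/prediction split sorts samples by reference value and deals
them out in a repeating 5-calibration / 2-prediction pattern, then moves
any prediction sample holding the global minimum or maximum into the
calibration set so the prediction range is contained in the calibration
range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spectra_io import ReferenceTable, SpectraSet

__all__ = [
    "OutlierReport",
    "SplitAssignment",
    "pca_outlier_screen",
    "rectangle_trim",
    "rank_ordered_split",
]


@dataclass(frozen=True)
class OutlierReport:
    """Per-sample T2/Q statistics, their limits and outlier flags."""

    sample_ids: tuple[str, ...]
    t2: np.ndarray
    q: np.ndarray
    t2_limit: float
    q_limit: float
    flags: np.ndarray
    k: int
    confidence: float

    @property
    def flagged_ids(self) -> list[str]:
        return [sid for sid, f in zip(self.sample_ids, self.flags) if f]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "t2": self.t2,
                "q": self.q,
                "t2_limit": self.t2_limit,
                "q_limit": self.q_limit,
                "flagged": self.flags,
            }
        )


@dataclass(frozen=True)
class SplitAssignment:
    """Disjoint calibration/prediction sample ids for one constituent."""

    constituent: str
    calibration_ids: tuple[str, ...]
    prediction_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.calibration_ids) & set(self.prediction_ids)
        if overlap:
            raise ValueError(f"samples in both sets: {sorted(overlap)[:5]}")


def _jackson_mudholkar_q_limit(residual_eigs: np.ndarray, confidence: float) -> float:
    theta1 = float(residual_eigs.sum())
    if theta1 <= 1e-30:
        return np.inf  # model explains everything; no residual space
    theta2 = float((residual_eigs**2).sum())
    theta3 = float((residual_eigs**3).sum())
    h0 = 1.0 - 2.0 * theta1 * theta3 / (3.0 * theta2**2)
    if h0 <= 0:
        h0 = 1e-4
    c = stats.norm.ppf(confidence)
    term = (
        c * np.sqrt(2.0 * theta2 * h0**2) / theta1
        + 1.0
        + theta2 * h0 * (h0 - 1.0) / theta1**2
    )
    if term <= 0:
        return np.inf
    return float(theta1 * term ** (1.0 / h0))


def pca_outlier_screen(
    spectra_set: SpectraSet, k: int = 4, confidence: float = 0.95
) -> OutlierReport:
    """Flag spectra whose Hotelling T2 or Q residual exceeds its limit.

    PCA is computed on the mean-centered matrix by SVD. The T2 limit is the
    F-based k(n-1)/(n-k) * F_conf(k, n-k); the Q limit uses the
    Jackson-Mudholkar approximation from the residual eigenvalues.
    """
    X = spectra_set.to_matrix()
    n = X.shape[0]
    if k < 1 or k >= n:
        raise ValueError(f"need 1 <= k < n, got k={k}, n={n}")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigs = S**2 / (n - 1)  # score variances
    scores = U * S
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = np.sum(
            np.where(eigs[:k] > 1e-30, scores[:, :k] ** 2 / eigs[:k], 0.0), axis=1
        )
    recon = scores[:, :k] @ Vt[:k]
    q = np.sum((Xc - recon) ** 2, axis=1)

    t2_limit = k * (n - 1) / (n - k) * stats.f.ppf(confidence, k, n - k)
    q_limit = _jackson_mudholkar_q_limit(eigs[k:], confidence)
    flags = (t2 > t2_limit) | (q > q_limit)
    return OutlierReport(
        sample_ids=tuple(spectra_set.sample_ids),
        t2=t2, q=q, t2_limit=float(t2_limit), q_limit=float(q_limit),
        flags=flags, k=k, confidence=confidence,
    )


def rectangle_trim(
    refs: ReferenceTable, constituent: str, bins: int = 8, cap: int = 10
) -> list[str]:
    """Ids retained after capping each equal-width reference-value bin.

    Within an over-full bin the ``cap`` samples closest to the bin center
    are kept (ties by sample_id order). Samples carrying the global minimum
    or maximum value are always represented.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    values = refs.values_for(constituent)
    ids = list(values.index)
    v = values.to_numpy(dtype=float)
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        return ids  # degenerate distribution: nothing to trim
    edges = np.linspace(lo, hi, bins + 1)
    which = np.clip(np.digitize(v, edges[1:-1], right=False), 0, bins - 1)
    retained: list[str] = []
    for b in range(bins):
        members = [i for i in range(len(ids)) if which[i] == b]
        if len(members) <= cap:
            retained.extend(ids[i] for i in members)
            continue
        center = 0.5 * (edges[b] + edges[b + 1])
        members.sort(key=lambda i: (abs(v[i] - center), i))
        retained.extend(ids[i] for i in members[:cap])
    kept = set(retained)
    for extreme in (lo, hi):
        holders = [ids[i] for i in range(len(ids)) if v[i] == extreme]
        if not kept & set(holders):
            retained.append(holders[0])
            kept.add(holders[0])
    return [i for i in ids if i in kept]


def rank_ordered_split(
    refs: ReferenceTable, constituent: str, block: tuple[int, int] = (5, 2)
) -> SplitAssignment:
    """Deterministic rank-ordered calibration/prediction split.

    Samples are sorted ascending by reference value (ties by sample_id);
    each consecutive block of ``block[0] + block[1]`` ranks contributes its
    first ``block[0]`` to calibration and the rest to prediction. Prediction
    samples holding the global extreme values are then moved to calibration.
    """
    n_cal, n_pred = block
    if n_cal < 1 or n_pred < 1:
        raise ValueError("block counts must be positive")
    values = refs.values_for(constituent)
    if len(values) < n_cal + n_pred:
        raise ValueError(
            f"need at least {n_cal + n_pred} samples to split, got {len(values)}"
        )
    order = sorted(range(len(values)), key=lambda i: (values.iloc[i], values.index[i]))
    ids = [values.index[i] for i in order]
    vals = [values.iloc[i] for i in order]
    period = n_cal + n_pred
    cal, pred = [], []
    for rank, sid in enumerate(ids):
        (cal if rank % period < n_cal else pred).append(sid)
    lo, hi = vals[0], vals[-1]
    still_pred = []
    for sid in pred:
        v = values[sid]
        if v == lo or v == hi:
            cal.append(sid)
        else:
            still_pred.append(sid)
    return SplitAssignment(
        constituent=constituent,
        calibration_ids=tuple(cal),
        prediction_ids=tuple(still_pred),
    )
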