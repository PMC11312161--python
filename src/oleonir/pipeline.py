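"""End-to-end calibration pipeline and its configuration.

Stage order (leakage-safe): truncate the wavelength window -> average
repeated scans -> PCA outlier screen on raw spectra (report; removal only
for explicitly listed ids) -> per constituent: rectangle trim -> rank-
ordered 5:2 split -> fit the MSC reference on the calibration set only ->
pretreat both sets -> cross-validated PRESS with F-test factor selection ->
final fit -> evaluation statistics -> regression-coefficient peak
interpretation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dataset_prep, evaluation, pls, preprocessing, synthetic, trends
from .preprocessing import MSCModel, PretreatmentSpec
from .spectra_io import ReferenceTable, SpectraSet, average_scans, read_spectra, truncate_range

__all__ = [
    "PipelineConfig",
    "ConstituentResult",
    "default_pretreatments",
    "run_calibration",
    "run_trend",
    "load_config",
    "save_config",
    "config_hash",
]


def default_pretreatments() -> dict[str, PretreatmentSpec]:
    """Best pretreatment per constituent in routine use."""
    return {
        "nootkatone": PretreatmentSpec("msc_full"),
        "beta_phellandrene": PretreatmentSpec("sg_second_derivative", window=11),
        "geranial": PretreatmentSpec("msc_full"),
        "limonene": PretreatmentSpec("raw"),
    }


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to rerun a calibration bit-identically."""

    spectra_path: str | None = None
    reference_path: str | None = None
    synthetic: synthetic.SyntheticConfig | None = None
    window: tuple[float, float] = (663.0, 961.0)
    pretreatments: dict[str, PretreatmentSpec] = field(default_factory=default_pretreatments)
    cv_scheme: str = "leave-one-out"
    cv_folds: int | None = None
    alpha: float = 0.25
    split_block: tuple[int, int] = (5, 2)
    trim_bins: int | None = None
    trim_cap: int | None = None
    outlier_k: int = 4
    outlier_confidence: float = 0.95
    remove_ids: tuple[str, ...] = ()
    h_max: int | None = None
    fixed_h: int | None = None   # skip CV selection and fit exactly this many factors
    strict_cv_msc: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.synthetic is None and (self.spectra_path is None or self.reference_path is None):
            object.__setattr__(
                self, "synthetic", synthetic.SyntheticConfig(seed=self.seed)
            )


@dataclass(frozen=True)
class ConstituentResult:
    """All artifacts of one constituent's calibration."""

    constituent: str
    pretreatment: PretreatmentSpec
    split: dataset_prep.SplitAssignment
    msc: MSCModel | None
    cv: pls.CVResult
    model: pls.PLSModel
    metrics_cal: evaluation.PredictionMetrics
    metrics_pred: evaluation.PredictionMetrics
    peaks: list[tuple[float, float]]
    assignments: list[tuple[float, str]]


def _load_inputs(config: PipelineConfig) -> tuple[SpectraSet, ReferenceTable]:
    if config.synthetic is not None:
        return synthetic.generate_dataset(config.synthetic)
    spectra = read_spectra(config.spectra_path)
    refs = ReferenceTable.read_csv(config.reference_path)
    return spectra, refs


def _pretreat_split(
    cal: SpectraSet, pred: SpectraSet, spec: PretreatmentSpec
) -> tuple[np.ndarray, np.ndarray, MSCModel | None]:
    msc = None
    if spec.method == "msc_full":
        msc = preprocessing.fit_msc(cal)
    cal_p = preprocessing.apply_pretreatment(cal, spec, msc)
    pred_p = preprocessing.apply_pretreatment(pred, spec, msc)
    return cal_p.to_matrix(), pred_p.to_matrix(), msc


def _calibrate_one(
    constituent: str,
    spectra: SpectraSet,
    refs: ReferenceTable,
    config: PipelineConfig,
) -> ConstituentResult:
    spec = config.pretreatments[constituent]
    values = refs.values_for(constituent)
    available = [sid for sid in spectra.sample_ids if sid in values.index]
    refs_c = refs.subset(available)

    if config.trim_bins is not None and config.trim_cap is not None:
        keep = dataset_prep.rectangle_trim(
            refs_c, constituent, bins=config.trim_bins, cap=config.trim_cap
        )
        refs_c = refs_c.subset(keep)

    split = dataset_prep.rank_ordered_split(refs_c, constituent, block=config.split_block)
    cal_set = spectra.subset(list(split.calibration_ids))
    pred_set = spectra.subset(list(split.prediction_ids))
    vals = refs_c.values_for(constituent)
    y_cal = vals[list(cal_set.sample_ids)].to_numpy(dtype=float)
    y_pred = vals[list(pred_set.sample_ids)].to_numpy(dtype=float)

    X_cal, X_pred, msc = _pretreat_split(cal_set, pred_set, spec)

    n = X_cal.shape[0]
    h_max = config.h_max if config.h_max is not None else max(1, min(15, n // 3))

    pretreat_cb = None
    if config.strict_cv_msc and spec.method == "msc_full":
        grid = cal_set.grid

        def pretreat_cb(X_tr, X_te, _grid=grid):
            ref = X_tr.mean(axis=0)
            refc = ref - ref.mean()
            denom = float(refc @ refc)

            def correct(M):
                b = (M - M.mean(axis=1, keepdims=True)) @ refc / denom
                a = M.mean(axis=1) - b * ref.mean()
                return (M - a[:, None]) / b[:, None]

            return correct(X_tr), correct(X_te)

        # strict mode re-derives MSC from raw calibration spectra per fold
        X_cv = cal_set.to_matrix()
    else:
        X_cv = X_cal

    if config.fixed_h is not None:
        cv = pls.CVResult(
            press=np.array([]), h_star=config.fixed_h, selected_h=config.fixed_h,
            alpha=config.alpha, scheme="fixed", n=n,
        )
    else:
        cv = pls.cross_validate_press(
            X_cv, y_cal, h_max=h_max, scheme=config.cv_scheme,
            n_folds=config.cv_folds, alpha=config.alpha, pretreat=pretreat_cb,
        )
    model = pls.nipals_pls1_fit(X_cal, y_cal, cv.selected_h)

    yhat_cal = pls.pls_predict(model, X_cal)
    yhat_pred = pls.pls_predict(model, X_pred)
    metrics_cal = evaluation.evaluate_predictions(
        y_cal, yhat_cal, role="calibration", model_h=model.h
    )
    metrics_pred = evaluation.evaluate_predictions(
        y_pred, yhat_pred, role="prediction", model_h=model.h
    )

    wavelengths = cal_set.grid.values
    peaks = evaluation.find_coefficient_peaks(wavelengths, model.coef)
    assignments = evaluation.assign_bands([wl for wl, _ in peaks])
    return ConstituentResult(
        constituent=constituent, pretreatment=spec, split=split, msc=msc,
        cv=cv, model=model, metrics_cal=metrics_cal, metrics_pred=metrics_pred,
        peaks=peaks, assignments=assignments,
    )


def run_calibration(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    constituents: list[str] | None = None,
) -> dict[str, ConstituentResult]:
    """Run the full calibration for every configured constituent."""
    spectra, refs = _load_inputs(config)
    targets = constituents if constituents is not None else refs.constituents
    for constituent in targets:
        if constituent not in config.pretreatments:
            raise ValueError(f"no pretreatment configured for {constituent!r}")

    spectra = truncate_range(spectra, *config.window)
    spectra = average_scans(spectra)
    outliers = dataset_prep.pca_outlier_screen(
        spectra, k=config.outlier_k, confidence=config.outlier_confidence
    )
    if config.remove_ids:
        keep = [sid for sid in spectra.sample_ids if sid not in set(config.remove_ids)]
        spectra = spectra.subset(keep)
        refs = refs.subset(keep)

    results = {
        constituent: _calibrate_one(constituent, spectra, refs, config)
        for constituent in targets
    }
    if out_dir is not None:
        _write_artifacts(config, results, outliers, Path(out_dir))
    return results


def run_trend(config: PipelineConfig, out_dir: str | Path | None = None):
    """Per-constituent storage-trend table with Duncan letters."""
    _, refs = _load_inputs(config)
    if refs.df.empty:
        raise ValueError("reference table is empty")
    report = trends.trend_report(refs)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        digest = config_hash(config)
        for constituent, payload in report.items():
            table = payload["table"].copy()
            table["config_hash"] = digest
            table.to_csv(out / f"trend_{constituent}.csv", index=False)
    return report


def summary_frame(results: dict[str, ConstituentResult]) -> pd.DataFrame:
    """Model-performance summary, one row per constituent."""
    rows = []
    for name, res in results.items():
        rows.append(
            {
                "constituent": name,
                "pretreatment": res.pretreatment.method,
                "n_components": res.model.h,
                "n_cal": res.metrics_cal.n,
                "r_cal": res.metrics_cal.r,
                "sec": res.metrics_cal.stderr,
                "bias_cal": res.metrics_cal.bias,
                "n_pred": res.metrics_pred.n,
                "r_pred": res.metrics_pred.r,
                "sep": res.metrics_pred.stderr,
                "bias_pred": res.metrics_pred.bias,
                "rpd": res.metrics_pred.rpd,
                "williams_class": res.metrics_pred.williams_class,
            }
        )
    return pd.DataFrame(rows)


def _write_artifacts(config, results, outliers, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    digest = config_hash(config)
    summary = summary_frame(results)
    summary["config_hash"] = digest
    summary.to_csv(out / "summary.csv", index=False)
    outlier_frame = outliers.to_frame()
    outlier_frame["config_hash"] = digest
    outlier_frame.to_csv(out / "outliers.csv", index=False)
    for name, res in results.items():
        pls.save_model(res.model, out / f"model_{name}.json")
        split_frame = pd.DataFrame(
            {
                "sample_id": list(res.split.calibration_ids) + list(res.split.prediction_ids),
                "set": ["calibration"] * len(res.split.calibration_ids)
                + ["prediction"] * len(res.split.prediction_ids),
            }
        )
        split_frame["config_hash"] = digest
        split_frame.to_csv(out / f"split_{name}.csv", index=False)
        interp = {
            "press": res.cv.press.tolist(),
            "h_star": res.cv.h_star,
            "selected_h": res.cv.selected_h,
            "explained_x_variance": res.model.explained_x_variance.tolist(),
            "peaks": res.peaks,
            "assignments": res.assignments,
            "config_hash": digest,
        }
        with open(out / f"interpretation_{name}.json", "w") as fh:
            json.dump(interp, fh, indent=1)
    log = {
        "config_hash": digest,
        "config": _config_to_dict(config),
        "n_flagged_outliers": int(outliers.flags.sum()),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1)


# -- configuration (de)serialisation -------------------------------------


def _config_to_dict(config: PipelineConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, frozenset):
            return sorted(obj)
        return obj

    return convert(config)


def config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(_config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=True)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return _config_from_dict(raw)


def _config_from_dict(raw: dict) -> PipelineConfig:
    kwargs = dict(raw)
    if kwargs.get("synthetic"):
        s = dict(kwargs["synthetic"])
        s["days"] = tuple(s.get("days", ()))
        s["trends"] = tuple(
            synthetic.TrendSpec(
                constituent=t["constituent"],
                means={int(k): float(v) for k, v in t["means"].items()},
                sds={int(k): float(v) for k, v in t["sds"].items()},
                not_detectable=frozenset(t.get("not_detectable", ())),
            )
            for t in s.get("trends", ())
        ) or synthetic.default_trends()
        s["bands"] = {
            name: tuple(synthetic.BandSpec(**b) for b in bands)
            for name, bands in s.get("bands", {}).items()
        } or synthetic.default_bands()
        grid = s.get("grid")
        if isinstance(grid, dict):
            s["grid"] = synthetic.WavelengthGrid(np.asarray(grid["values"], dtype=float))
        else:
            s.pop("grid", None)
        kwargs["synthetic"] = synthetic.SyntheticConfig(**s)
    else:
        kwargs.pop("synthetic", None)
    if "pretreatments" in kwargs and kwargs["pretreatments"]:
        kwargs["pretreatments"] = {
            name: PretreatmentSpec(**spec) if isinstance(spec, dict) else spec
            for name, spec in kwargs["pretreatments"].items()
        }
    for key in ("window", "split_block", "remove_ids"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return PipelineConfig(**kwargs)
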