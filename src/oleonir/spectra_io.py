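"""Containers and wide-CSV I/O for VIS/NIR diffuse-reflectance spectra.

The canonical on-disk dialect is a wide CSV: one row per spectrum with
``sample_id``, ``storage_day``, an optional ``scan_index`` column, and then
one column per wavelength (the column header is the wavelength in nm).
Reference concentrations travel in a long CSV with columns
``sample_id, storage_day, constituent, concentration_pct``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "SpectraSet",
    "ReferenceTable",
    "SpectraFormatError",
    "GridMismatchError",
    "read_spectra",
    "write_spectra",
    "average_scans",
    "truncate_range",
]

_META_COLUMNS = ("sample_id", "storage_day", "scan_index")


class SpectraFormatError(ValueError):
    """Raised when a spectra file violates the wide-CSV dialect."""


class GridMismatchError(ValueError):
    """Raised when spectra on different wavelength grids are combined."""


@dataclass(frozen=True)
class WavelengthGrid:
    """A strictly increasing, uniformly spaced wavelength axis in nm.

    The instrument default is 600-1100 nm at 2 nm resolution (251 points).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise SpectraFormatError("wavelength grid needs at least two points")
        steps = np.diff(values)
        if np.any(steps <= 0):
            raise SpectraFormatError("wavelength grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise SpectraFormatError(
                f"non-uniform wavelength spacing: steps range "
                f"{steps.min():g}..{steps.max():g} nm"
            )
        object.__setattr__(self, "values", values)

    @classmethod
    def regular(cls, start: float = 600.0, stop: float = 1100.0, step: float = 2.0) -> "WavelengthGrid":
        n = int(round((stop - start) / step)) + 1
        return cls(start + step * np.arange(n))

    @property
    def start(self) -> float:
        return float(self.values[0])

    @property
    def stop(self) -> float:
        return float(self.values[-1])

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class Spectrum:
    """One absorbance vector aligned to a :class:`WavelengthGrid`."""

    sample_id: str
    storage_day: int
    absorbance: np.ndarray
    scan_index: int | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.absorbance, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite absorbance in sample {self.sample_id!r}")
        object.__setattr__(self, "absorbance", arr)


@dataclass(frozen=True)
class SpectraSet:
    """A collection of spectra sharing one wavelength grid."""

    grid: WavelengthGrid
    spectra: tuple[Spectrum, ...]

    def __post_init__(self) -> None:
        spectra = tuple(self.spectra)
        for s in spectra:
            if s.absorbance.size != len(self.grid):
                raise GridMismatchError(
                    f"sample {s.sample_id!r} has {s.absorbance.size} points, "
                    f"grid has {len(self.grid)}"
                )
        object.__setattr__(self, "spectra", spectra)

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.spectra]

    @property
    def storage_days(self) -> np.ndarray:
        return np.array([s.storage_day for s in self.spectra], dtype=int)

    def to_matrix(self) -> np.ndarray:
        """Stack absorbances as an (n_samples, n_wavelengths) matrix."""
        return np.vstack([s.absorbance for s in self.spectra])

    def with_matrix(self, X: np.ndarray, grid: WavelengthGrid | None = None) -> "SpectraSet":
        """Same metadata, new absorbance values (and optionally a new grid)."""
        grid = grid if grid is not None else self.grid
        X = np.asarray(X, dtype=float)
        if X.shape != (len(self), len(grid)):
            raise GridMismatchError(f"matrix shape {X.shape} does not match set")
        return SpectraSet(
            grid, tuple(replace(s, absorbance=X[i]) for i, s in enumerate(self.spectra))
        )

    def subset(self, sample_ids: list[str]) -> "SpectraSet":
        wanted = set(sample_ids)
        return SpectraSet(self.grid, tuple(s for s in self.spectra if s.sample_id in wanted))


@dataclass(frozen=True)
class ReferenceTable:
    """Long-format per-sample constituent concentrations in % w/w."""

    df: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["sample_id", "storage_day", "constituent", "concentration_pct"]
        )
    )

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        required = {"sample_id", "storage_day", "constituent", "concentration_pct"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"reference table missing columns: {sorted(missing)}")
        if len(df) and (df["concentration_pct"] < 0).any():
            raise ValueError("negative concentration in reference table")
        if len(df):
            totals = df.groupby("sample_id")["concentration_pct"].sum()
            if (totals > 100.0 + 1e-9).any():
                bad = totals[totals > 100.0 + 1e-9].index[0]
                raise ValueError(f"constituents of sample {bad!r} sum to > 100 %")
        object.__setattr__(self, "df", df)

    @property
    def constituents(self) -> list[str]:
        return sorted(self.df["constituent"].unique())

    def values_for(self, constituent: str) -> pd.Series:
        """Concentrations of one constituent indexed by sample_id."""
        sub = self.df[self.df["constituent"] == constituent]
        if sub.empty:
            raise KeyError(f"constituent {constituent!r} not in reference table")
        return sub.set_index("sample_id")["concentration_pct"]

    def subset(self, sample_ids: list[str]) -> "ReferenceTable":
        wanted = set(sample_ids)
        return ReferenceTable(self.df[self.df["sample_id"].isin(wanted)])

    def write_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ReferenceTable":
        return cls(pd.read_csv(path))


def _parse_wavelength_columns(columns: list[str]) -> tuple[list[str], np.ndarray]:
    meta, wavelengths = [], []
    for col in columns:
        if col in _META_COLUMNS:
            meta.append(col)
            continue
        try:
            wavelengths.append(float(col))
        except ValueError as exc:
            raise SpectraFormatError(f"column {col!r} is neither metadata nor a wavelength") from exc
    return meta, np.asarray(wavelengths, dtype=float)


def read_spectra(path, dialect: str = "wide_csv") -> SpectraSet:
    """Read a wide-CSV spectra file; the grid is rebuilt from the header."""
    if dialect != "wide_csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    # round_trip parsing: correctly-rounded floats so read(write(S)) == S exactly
    df = pd.read_csv(path, float_precision="round_trip")
    if "sample_id" not in df.columns or "storage_day" not in df.columns:
        raise SpectraFormatError("wide CSV requires sample_id and storage_day columns")
    meta, wavelengths = _parse_wavelength_columns(list(df.columns))
    grid = WavelengthGrid(wavelengths)  # raises on non-uniform spacing
    wl_cols = [c for c in df.columns if c not in _META_COLUMNS]
    values = df[wl_cols].to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"missing/NaN absorbance at row {i} (sample "
            f"{df['sample_id'].iloc[i]!r}), wavelength column {wl_cols[j]}"
        )
    has_scan = "scan_index" in df.columns
    spectra = tuple(
        Spectrum(
            sample_id=str(df["sample_id"].iloc[i]),
            storage_day=int(df["storage_day"].iloc[i]),
            scan_index=int(df["scan_index"].iloc[i]) if has_scan else None,
            absorbance=values[i],
        )
        for i in range(len(df))
    )
    return SpectraSet(grid, spectra)


def write_spectra(spectra_set: SpectraSet, path, dialect: str = "wide_csv") -> None:
    """Write a SpectraSet as wide CSV with full (round-tripping) precision."""
    if dialect != "wide_csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    has_scan = any(s.scan_index is not None for s in spectra_set.spectra)
    records: dict[str, list] = {
        "sample_id": spectra_set.sample_ids,
        "storage_day": [s.storage_day for s in spectra_set.spectra],
    }
    if has_scan:
        records["scan_index"] = [s.scan_index for s in spectra_set.spectra]
    X = spectra_set.to_matrix() if len(spectra_set) else np.empty((0, len(spectra_set.grid)))
    for j, wl in enumerate(spectra_set.grid.values):
        records[repr(float(wl))] = list(X[:, j])
    # str(float) is the shortest exact representation, so read(write(S)) == S
    pd.DataFrame(records).to_csv(path, index=False)


def average_scans(spectra_set: SpectraSet, group_by: str = "sample_id") -> SpectraSet:
    """Average repeated scans per fruit (arithmetic mean per wavelength)."""
    if group_by != "sample_id":
        raise ValueError(f"unsupported grouping key {group_by!r}")
    if not len(spectra_set):
        raise ValueError("cannot average an empty SpectraSet")
    order: list[str] = []
    groups: dict[str, list[Spectrum]] = {}
    for s in spectra_set.spectra:
        if s.sample_id not in groups:
            order.append(s.sample_id)
            groups[s.sample_id] = []
        groups[s.sample_id].append(s)
    averaged = []
    for sid in order:
        scans = groups[sid]
        days = {s.storage_day for s in scans}
        if len(days) != 1:
            raise ValueError(f"sample {sid!r} has scans from multiple storage days {sorted(days)}")
        mean = np.mean([s.absorbance for s in scans], axis=0)
        averaged.append(Spectrum(sid, scans[0].storage_day, mean, scan_index=None))
    return SpectraSet(spectra_set.grid, tuple(averaged))


def truncate_range(spectra_set: SpectraSet, low: float, high: float) -> SpectraSet:
    """Keep grid points p with low <= p <= high (inclusive bounds).

    The working window 663-961 nm intersected with the instrument's even-nm
    grid retains the 149 points 664-960 nm.
    """
    if low >= high:
        raise ValueError(f"invalid window [{low}, {high}]")
    mask = (spectra_set.grid.values >= low) & (spectra_set.grid.values <= high)
    if mask.sum() < 2:
        raise ValueError(f"window [{low}, {high}] does not overlap the grid")
    grid = WavelengthGrid(spectra_set.grid.values[mask])
    spectra = tuple(replace(s, absorbance=s.absorbance[mask]) for s in spectra_set.spectra)
    return SpectraSet(grid, spectra)
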