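"""Synthetic pomelo storage experiment: concentrations and forward-modelled spectra.

The generator emulates a cold-storage study design: 9 sampling dates at
15-day intervals (0..120 days), 15 fruits per date, with per-date
constituent means and SDs matching the reported storage trajectories —
nootkatone rising from below the detection limit to 0.63 % w/w,
beta-phellandrene and geranial U-shaped with a minimum near day 60, and
limonene mirroring them with a maximum near 84.6 % at day 60.

Spectra follow a Beer-Lambert mixture model on the 600-1100 nm grid:
Gaussian absorption bands per constituent, a chlorophyll background at
680 nm whose amplitude decays with storage day, a constant water band at
960 nm, multiplicative and additive scatter, and i.i.d. Gaussian noise per
wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra_io import ReferenceTable, SpectraSet, Spectrum, WavelengthGrid

__all__ = [
    "TrendSpec",
    "BandSpec",
    "SyntheticConfig",
    "DETECTION_LIMIT_PCT",
    "default_trends",
    "default_bands",
    "sample_concentrations",
    "generate_spectrum",
    "generate_dataset",
]

#: GC-MS detection limit used for "not detectable" cells, % w/w (the lower
#: edge of the nootkatone calibration range).
DETECTION_LIMIT_PCT = 0.02


@dataclass(frozen=True)
class TrendSpec:
    """Per-storage-day mean and SD (% w/w) of one constituent.

    Days listed in ``not_detectable`` are generated as uniform draws on
    (0, detection limit) instead of a truncated normal.
    """

    constituent: str
    means: dict[int, float]
    sds: dict[int, float]
    not_detectable: frozenset = frozenset()

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.sds.values()):
            raise ValueError(f"negative SD in trend for {self.constituent!r}")


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band: center (nm), sigma (nm), amplitude per % w/w."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if not 600.0 <= self.center <= 1100.0:
            raise ValueError(f"band center {self.center} nm outside 600-1100 nm")


def default_trends() -> tuple[TrendSpec, ...]:
    """Storage trajectories of the four major peel-oil constituents."""
    return (
        TrendSpec(
            "nootkatone",
            means={30: 0.06, 45: 0.08, 60: 0.13, 75: 0.22, 90: 0.33, 105: 0.47, 120: 0.63},
            sds={30: 0.02, 45: 0.05, 60: 0.07, 75: 0.12, 90: 0.16, 105: 0.30, 120: 0.22},
            not_detectable=frozenset({0, 15}),
        ),
        TrendSpec(
            "beta_phellandrene",
            means={0: 6.16, 15: 6.22, 30: 5.27, 45: 4.85, 60: 4.64, 75: 5.00, 90: 6.32, 105: 5.70, 120: 6.15},
            sds={0: 0.56, 15: 0.62, 30: 0.54, 45: 0.66, 60: 0.59, 75: 0.73, 90: 1.02, 105: 0.98, 120: 0.90},
        ),
        TrendSpec(
            "geranial",
            means={0: 0.39, 15: 0.40, 30: 0.33, 45: 0.31, 60: 0.27, 75: 0.31, 90: 0.33, 105: 0.31, 120: 0.37},
            sds={0: 0.06, 15: 0.05, 30: 0.04, 45: 0.04, 60: 0.03, 75: 0.04, 90: 0.05, 105: 0.07, 120: 0.07},
        ),
        TrendSpec(
            "limonene",
            means={0: 79.95, 15: 80.37, 30: 83.07, 45: 84.23, 60: 84.61, 75: 83.89, 90: 79.54, 105: 81.13, 120: 79.17},
            sds={0: 1.63, 15: 1.93, 30: 1.72, 45: 1.50, 60: 1.42, 75: 1.98, 90: 2.36, 105: 1.90, 120: 2.09},
        ),
    )


def default_bands() -> dict[str, tuple[BandSpec, ...]]:
    """Constituent band tables mirroring the usual VIS/NIR assignments.

    Nootkatone carries the distinctive 740/746 nm C-H fourth-overtone pair;
    the monoterpenes share heavily overlapping oil/aliphatic bands near
    827 and 908-950 nm. Amplitudes are scaled so each constituent's total
    contribution at its typical concentration is a plausible fraction of a
    fruit absorbance spectrum (order 0.05-0.3 AU).
    """
    return {
        "nootkatone": (
            BandSpec(740.0, 8.0, 0.10),
            BandSpec(746.0, 8.0, 0.10),
            BandSpec(827.0, 10.0, 0.05),
            BandSpec(930.0, 12.0, 0.05),
        ),
        "beta_phellandrene": (
            BandSpec(908.0, 12.0, 0.020),
            BandSpec(930.0, 12.0, 0.020),
        ),
        "geranial": (
            BandSpec(925.0, 12.0, 0.050),
            BandSpec(950.0, 12.0, 0.050),
        ),
        "limonene": (
            BandSpec(827.0, 10.0, 0.0020),
            BandSpec(930.0, 12.0, 0.0030),
        ),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic storage experiment."""

    days: tuple[int, ...] = (0, 15, 30, 45, 60, 75, 90, 105, 120)
    fruits_per_day: int = 15
    trends: tuple[TrendSpec, ...] = field(default_factory=default_trends)
    bands: dict[str, tuple[BandSpec, ...]] = field(default_factory=default_bands)
    grid: WavelengthGrid = field(default_factory=WavelengthGrid.regular)
    # chlorophyll background at 680 nm decays with storage day (degreening)
    chlorophyll_center: float = 680.0
    chlorophyll_width: float = 12.0
    chlorophyll_amp0: float = 0.5
    chlorophyll_amp_inf: float = 0.25
    chlorophyll_tau_days: float = 30.0
    water_center: float = 960.0
    water_width: float = 25.0
    water_amp: float = 0.5
    scatter_sd: float = 0.05     # multiplicative, dimensionless
    offset_sd: float = 0.01      # additive, AU
    noise_sd: float = 0.002      # per-wavelength, AU
    detection_limit: float = DETECTION_LIMIT_PCT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fruits_per_day < 1:
            raise ValueError("fruits_per_day must be >= 1")
        for sd in (self.scatter_sd, self.offset_sd, self.noise_sd):
            if sd < 0:
                raise ValueError("noise SDs must be >= 0")

    @property
    def constituents(self) -> list[str]:
        return [t.constituent for t in self.trends]


def _fruit_rng(cfg: SyntheticConfig, day: int, rep: int, stream: int) -> np.random.Generator:
    # per-fruit substreams keyed on (seed, day, replicate, purpose)
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, day, rep, stream]))


def _sample_id(day: int, rep: int) -> str:
    return f"d{day:03d}_r{rep:02d}"


def _draw_concentration(trend: TrendSpec, day: int, cfg: SyntheticConfig,
                        rng: np.random.Generator) -> float:
    if day in trend.not_detectable:
        return float(rng.uniform(0.0, cfg.detection_limit))
    if day not in trend.means:
        raise ValueError(f"day {day} missing from trend for {trend.constituent!r}")
    mean, sd = trend.means[day], trend.sds[day]
    if sd == 0:
        return mean
    # truncated-at-zero normal via resampling
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v >= 0:
            return float(v)
    raise RuntimeError("truncated-normal resampling failed (mean far below zero?)")


def sample_concentrations(cfg: SyntheticConfig) -> ReferenceTable:
    """Draw per-fruit constituent concentrations for every day x replicate."""
    for trend in cfg.trends:
        for day in cfg.days:
            if day not in trend.means and day not in trend.not_detectable:
                raise ValueError(
                    f"day {day} absent from trend for {trend.constituent!r}"
                )
    rows = []
    for day in cfg.days:
        for rep in range(cfg.fruits_per_day):
            rng = _fruit_rng(cfg, day, rep, stream=0)
            sid = _sample_id(day, rep)
            for trend in cfg.trends:
                rows.append(
                    {
                        "sample_id": sid,
                        "storage_day": day,
                        "constituent": trend.constituent,
                        "concentration_pct": _draw_concentration(trend, day, cfg, rng),
                    }
                )
    return ReferenceTable(pd.DataFrame(rows))


def _band_profile(grid: WavelengthGrid, center: float, width: float) -> np.ndarray:
    lam = grid.values
    return np.exp(-((lam - center) ** 2) / (2.0 * width**2))


def _background(cfg: SyntheticConfig, day: int) -> np.ndarray:
    chl_amp = cfg.chlorophyll_amp_inf + (
        cfg.chlorophyll_amp0 - cfg.chlorophyll_amp_inf
    ) * np.exp(-day / cfg.chlorophyll_tau_days)
    return chl_amp * _band_profile(
        cfg.grid, cfg.chlorophyll_center, cfg.chlorophyll_width
    ) + cfg.water_amp * _band_profile(cfg.grid, cfg.water_center, cfg.water_width)


def generate_spectrum(
    concentrations: dict[str, float],
    day: int,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    sample_id: str = "synthetic",
) -> Spectrum:
    """Forward-model one absorbance spectrum from concentrations.

    absorbance = (mixture + background) * (1 + m) + o + eps, with
    m ~ N(0, scatter_sd), o ~ N(0, offset_sd) and eps i.i.d. N(0, noise_sd).
    """
    clean = _background(cfg, day)
    for constituent, conc in concentrations.items():
        if constituent not in cfg.bands:
            raise ValueError(f"no band specification for constituent {constituent!r}")
        for band in cfg.bands[constituent]:
            clean = clean + conc * band.amplitude * _band_profile(
                cfg.grid, band.center, band.width
            )
    m = rng.normal(0.0, cfg.scatter_sd) if cfg.scatter_sd > 0 else 0.0
    o = rng.normal(0.0, cfg.offset_sd) if cfg.offset_sd > 0 else 0.0
    eps = (
        rng.normal(0.0, cfg.noise_sd, size=len(cfg.grid))
        if cfg.noise_sd > 0
        else 0.0
    )
    return Spectrum(sample_id, day, clean * (1.0 + m) + o + eps)


def generate_dataset(cfg: SyntheticConfig) -> tuple[SpectraSet, ReferenceTable]:
    """One averaged spectrum plus reference rows per fruit.

    Sample ids encode day and replicate (``d060_r04``); the dataset holds
    ``len(days) * fruits_per_day`` fruits and is reproducible from the seed.
    """
    refs = sample_concentrations(cfg)
    by_sample = refs.df.pivot_table(
        index="sample_id", columns="constituent", values="concentration_pct"
    )
    spectra = []
    for day in cfg.days:
        for rep in range(cfg.fruits_per_day):
            sid = _sample_id(day, rep)
            conc = by_sample.loc[sid].to_dict()
            rng = _fruit_rng(cfg, day, rep, stream=1)
            spectra.append(generate_spectrum(conc, day, cfg, rng, sample_id=sid))
    return SpectraSet(cfg.grid, tuple(spectra)), refs
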