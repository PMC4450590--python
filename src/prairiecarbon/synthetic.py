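"""Seed-reproducible synthetic inputs for the regional pipeline.

This module generates the forcing and observation surfaces the analysis
assumes — monthly climate with scenario-specific trends, annual categorical
land-use rasters with corn rotation, a spatially correlated initial SOC
field, annual CO₂ paths, and county-aggregated noisy yield/NPP observations
— standing in for the external climate, land-use, soils and yield products a
regional application would ingest. Randomness is split into independent
per-component streams so regenerating one surface never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .carbon import run_site
from .params import (
    CROP_CLASSES,
    DEFAULT_CROPS,
    ClimateSeries,
    CropParameters,
    DecompositionParams,
    Management,
)

__all__ = [
    "SyntheticConfig",
    "LandUseSequence",
    "LANDUSE_CODES",
    "make_climate",
    "make_landuse_sequence",
    "make_soil_map",
    "make_observations",
    "county_labels",
]

#: integer codes used in land-use rasters (and their TIFF exports)
LANDUSE_CODES: dict[str, int] = {
    "corn": 1,
    "soybean": 2,
    "wheat": 3,
    "grass_shrub": 4,
    "forest": 5,
    "wetland": 6,
    "other": 7,
}
_CODE_TO_CLASS = {v: k for k, v in LANDUSE_CODES.items()}

# total temperature change (°C) and precipitation factor change over an
# 80-year span, per climate track; B1 warming is the anchored value, the
# others are loosely anchored defaults
_TRACK_TEMP_DELTA_80YR = {"BASELINE": 0.0, "A1B": 2.0, "A2": 2.2, "B1": 2.4}
_TRACK_PRECIP_DELTA_80YR = {"BASELINE": 0.0, "A1B": 0.0, "A2": -0.05 * 80 / 40, "B1": 0.0}
# annual CO₂ growth, ppm/yr (linear paths from the reference 370 ppm)
_TRACK_CO2_RATE = {"BASELINE": 1.9, "A1B": 3.3, "A2": 3.2, "B1": 2.4}

# monthly climatology weights for precipitation (summer-peaked, sum 1) and
# the seasonal temperature half-amplitude of a continental interior
_PRECIP_WEIGHTS = np.array(
    [18, 20, 40, 65, 90, 105, 95, 85, 70, 55, 35, 22], dtype=float
)
_PRECIP_WEIGHTS /= _PRECIP_WEIGHTS.sum()
_TEMP_AMPLITUDE = 15.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic study region.

    Defaults describe the emulated region: a 250-m grid, ~780 mm annual
    precipitation, ~9 °C mean temperature, cropland rising from 58.6% toward
    59.8%, and a mean initial SOC density of 5.97 kg C/m².
    """

    grid_rows: int = 50
    grid_cols: int = 50
    cell_size_m: float = 250.0
    start_year: int = 2001
    end_year: int = 2050
    seed: int = 0
    climate_track: str = "BASELINE"
    cropland_fraction_start: float = 0.586
    cropland_fraction_end: float = 0.598
    corn_rotation_prob: float = 0.45
    yield_noise_cv: float = 0.05
    soc_mean: float = 5.97          # kg C/m²
    soc_cv: float = 0.3
    # climate knobs
    temp_mean_c: float = 9.0
    precip_annual_mm: float = 780.0
    temp_noise_sd: float = 1.5      # °C monthly AR(1) innovation scale
    temp_noise_ar1: float = 0.3
    precip_noise_cv: float = 0.3    # multiplicative lognormal CV
    trend_enabled: bool = True
    co2_start_ppm: float = 370.0
    soc_correlation_cells: float = 5.0
    county_blocks: tuple[int, int] = (10, 10)
    noncrop_weights: dict[str, float] = field(
        default_factory=lambda: {
            "grass_shrub": 0.55, "forest": 0.2, "wetland": 0.1, "other": 0.15
        }
    )

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.start_year >= self.end_year:
            raise ValueError("start_year must precede end_year")
        if self.climate_track not in _TRACK_TEMP_DELTA_80YR:
            raise ValueError(f"unknown climate_track {self.climate_track!r}")
        for name in (
            "cropland_fraction_start",
            "cropland_fraction_end",
            "corn_rotation_prob",
            "yield_noise_cv",
            "soc_cv",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0, 1]")
        if self.soc_mean <= 0:
            raise ValueError("soc_mean must be positive")

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def shape(self) -> tuple[int, int]:
        return (self.grid_rows, self.grid_cols)

    def rng(self, component: str) -> np.random.Generator:
        """Independent stream per component (climate/landuse/soil/obs)."""
        keys = {"climate": 1, "landuse": 2, "soil": 3, "obs": 4}
        ss = np.random.SeedSequence(self.seed, spawn_key=(keys[component],))
        return np.random.default_rng(ss)


@dataclass(frozen=True)
class LandUseSequence:
    """Per-year categorical land-use rasters (codes per LANDUSE_CODES)."""

    years: np.ndarray       # (n_years,)
    codes: np.ndarray       # (n_years, rows, cols) int8

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        valid = set(LANDUSE_CODES.values())
        if not set(np.unique(codes)).issubset(valid):
            raise ValueError("land-use raster contains unknown class codes")

    @property
    def n_years(self) -> int:
        return int(self.years.size)

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape[1:]

    def year_index(self, year: int) -> int:
        i = int(year - self.years[0])
        if i < 0 or i >= self.n_years:
            raise KeyError(f"year {year} outside land-use span")
        return i

    def class_name(self, code: int) -> str:
        return _CODE_TO_CLASS[int(code)]

    def class_fractions(self, year: int) -> dict[str, float]:
        """Per-class area fractions for one year; sums to 1 exactly."""
        arr = self.codes[self.year_index(year)]
        n = arr.size
        return {
            cls: float(np.count_nonzero(arr == code)) / n
            for cls, code in LANDUSE_CODES.items()
        }

    def cropland_fraction(self, year: int) -> float:
        arr = self.codes[self.year_index(year)]
        crop_codes = [LANDUSE_CODES[c] for c in CROP_CLASSES]
        return float(np.isin(arr, crop_codes).mean())


def make_climate(config: SyntheticConfig) -> ClimateSeries:
    """Monthly temperature/precipitation and annual CO₂ for the region.

    Temperature is a seasonal sinusoid around the annual mean plus a linear
    per-year warming ramp (track-specific total over an 80-year span) and
    AR(1) monthly noise. Precipitation is the summer-peaked monthly
    climatology scaled by a per-year trend factor and mean-one lognormal
    noise. The trend is constant within a calendar year, so with noise
    disabled the end-minus-start annual-mean difference equals
    delta × span/80 exactly.
    """
    rng = config.rng("climate")
    ny = config.n_years
    years = np.arange(config.start_year, config.end_year + 1)
    span = config.end_year - config.start_year

    t_delta = _TRACK_TEMP_DELTA_80YR[config.climate_track] if config.trend_enabled else 0.0
    p_delta = _TRACK_PRECIP_DELTA_80YR[config.climate_track] if config.trend_enabled else 0.0
    t_rate = t_delta / 80.0              # °C per year
    p_rate = p_delta / 80.0              # fractional change per year

    months = np.arange(1, 13)
    seasonal = config.temp_mean_c - _TEMP_AMPLITUDE * np.cos(
        2 * np.pi * (months - 0.5) / 12.0
    )
    tmean = np.tile(seasonal, (ny, 1))
    tmean += (t_rate * np.arange(ny))[:, None]

    if config.temp_noise_sd > 0:
        eps = rng.normal(0.0, config.temp_noise_sd, size=ny * 12)
        noise = np.empty(ny * 12)
        rho = config.temp_noise_ar1
        noise[0] = eps[0]
        for i in range(1, ny * 12):
            noise[i] = rho * noise[i - 1] + np.sqrt(1 - rho**2) * eps[i]
        tmean += noise.reshape(ny, 12)
    else:
        # keep stream alignment so toggling noise does not reshuffle precip
        rng.normal(size=ny * 12)

    base_precip = config.precip_annual_mm * _PRECIP_WEIGHTS
    precip = np.tile(base_precip, (ny, 1))
    precip *= (1.0 + p_rate * np.arange(ny))[:, None]
    if config.precip_noise_cv > 0:
        sigma = np.sqrt(np.log(1.0 + config.precip_noise_cv**2))
        z = rng.normal(size=(ny, 12))
        precip *= np.exp(sigma * z - 0.5 * sigma**2)
    else:
        rng.normal(size=(ny, 12))
    precip = np.maximum(precip, 0.0)

    co2 = config.co2_start_ppm + _TRACK_CO2_RATE[config.climate_track] * np.arange(ny)
    return ClimateSeries(years=years, precip_mm=precip, tmean_c=tmean, co2_ppm=co2)


def _initial_landuse(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.grid_rows * config.grid_cols
    n_crop = int(round(config.cropland_fraction_start * n))
    cells = rng.permutation(n)
    grid = np.empty(n, dtype=np.int8)

    crop_cells = cells[:n_crop]
    p = config.corn_rotation_prob
    crop_probs = np.array([p, (1 - p) * 0.6, (1 - p) * 0.4])
    crop_codes = np.array([LANDUSE_CODES[c] for c in CROP_CLASSES], dtype=np.int8)
    grid[crop_cells] = rng.choice(crop_codes, size=n_crop, p=crop_probs)

    noncrop_cells = cells[n_crop:]
    classes = list(config.noncrop_weights)
    w = np.array([config.noncrop_weights[c] for c in classes])
    w = w / w.sum()
    codes = np.array([LANDUSE_CODES[c] for c in classes], dtype=np.int8)
    grid[noncrop_cells] = rng.choice(codes, size=n - n_crop, p=w)
    return grid.reshape(config.shape)


def _rotate_crops(prev: np.ndarray, crop_mask: np.ndarray,
                  p_corn: float, rng: np.random.Generator) -> np.ndarray:
    """First-order rotation among corn/soybean/wheat on cropland cells.

    Each cropland cell plants corn with probability ``p_corn``; the
    remaining probability is split to favour switching away from the
    previous non-corn crop (soybean↔wheat alternation).
    """
    out = prev.copy()
    idx = np.flatnonzero(crop_mask.ravel())
    if idx.size == 0:
        return out
    flat_prev = prev.ravel()[idx]
    u = rng.random(idx.size)
    v = rng.random(idx.size)
    corn = u < p_corn
    prev_soy = flat_prev == LANDUSE_CODES["soybean"]
    # after corn or wheat: soybean 70% / wheat 30%; after soybean: wheat 70%
    soy_prob = np.where(prev_soy, 0.3, 0.7)
    soy = ~corn & (v < soy_prob)
    new = np.where(
        corn,
        LANDUSE_CODES["corn"],
        np.where(soy, LANDUSE_CODES["soybean"], LANDUSE_CODES["wheat"]),
    )
    flat = out.ravel()
    flat[idx] = new.astype(np.int8)
    return flat.reshape(prev.shape)


def make_landuse_sequence(config: SyntheticConfig) -> LandUseSequence:
    """Annual land-use rasters with cropland expansion and corn rotation.

    Cropland area tracks a linear interpolation between the configured start
    and end fractions (conversions drawn from/into grass_shrub and other);
    within cropland, species rotate by a first-order Markov rule with
    P(corn) = ``corn_rotation_prob``.
    """
    rng = config.rng("landuse")
    ny = config.n_years
    years = np.arange(config.start_year, config.end_year + 1)
    n = config.grid_rows * config.grid_cols
    crop_codes = np.array([LANDUSE_CODES[c] for c in CROP_CLASSES])

    grid = _initial_landuse(config, rng)
    rasters = np.empty((ny, *config.shape), dtype=np.int8)
    rasters[0] = grid

    targets = np.linspace(
        config.cropland_fraction_start, config.cropland_fraction_end, ny
    )
    for iy in range(1, ny):
        grid = rasters[iy - 1].copy()
        crop_mask = np.isin(grid, crop_codes)
        target_cells = int(round(targets[iy] * n))
        current = int(crop_mask.sum())
        if target_cells > current:
            convertible = np.flatnonzero(
                np.isin(grid.ravel(), [LANDUSE_CODES["grass_shrub"], LANDUSE_CODES["other"]])
            )
            k = min(target_cells - current, convertible.size)
            chosen = rng.choice(convertible, size=k, replace=False)
            grid.ravel()[chosen] = LANDUSE_CODES["soybean"]
        elif target_cells < current:
            croplist = np.flatnonzero(crop_mask.ravel())
            chosen = rng.choice(croplist, size=current - target_cells, replace=False)
            grid.ravel()[chosen] = LANDUSE_CODES["grass_shrub"]
        crop_mask = np.isin(grid, crop_codes)
        grid = _rotate_crops(grid, crop_mask, config.corn_rotation_prob, rng)
        rasters[iy] = grid

    return LandUseSequence(years=years, codes=rasters)


def make_soil_map(config: SyntheticConfig) -> np.ndarray:
    """Spatially correlated lognormal initial SOC field (kg C/m²).

    A Gaussian random field (white noise smoothed over
    ``soc_correlation_cells`` cells) is exponentiated and rescaled so the
    sample mean equals ``soc_mean`` exactly; ``soc_cv`` = 0 degenerates to a
    constant field.
    """
    if config.soc_mean <= 0:
        raise ValueError("soc_mean must be positive")
    if config.soc_cv == 0:
        return np.full(config.shape, config.soc_mean)
    rng = config.rng("soil")
    white = rng.normal(size=config.shape)
    z = ndimage.gaussian_filter(white, sigma=config.soc_correlation_cells, mode="wrap")
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    sigma = np.sqrt(np.log(1.0 + config.soc_cv**2))
    raw = np.exp(sigma * z)
    return config.soc_mean * raw / raw.mean()


def county_labels(shape: tuple[int, int], blocks: tuple[int, int]) -> np.ndarray:
    """Synthetic 'county' id per grid cell: contiguous rectangular blocks."""
    rows, cols = shape
    br = max(1, rows // blocks[0])
    bc = max(1, cols // blocks[1])
    r_id = np.minimum(np.arange(rows) // br, blocks[0] - 1)
    c_id = np.minimum(np.arange(cols) // bc, blocks[1] - 1)
    return (r_id[:, None] * blocks[1] + c_id[None, :]).astype(int)


def per_area_outputs(
    truth: dict[str, CropParameters],
    climate: ClimateSeries,
    classes: list[str],
    initial_soc: float,
    mgmt: Management | None = None,
    decomp: DecompositionParams | None = None,
) -> dict[str, "np.ndarray"]:
    """Annual per-area model output per land-cover class (kg C/m²/yr).

    Climate is spatially uniform, so one site run per class gives the
    per-area grain yield (crops) or NPP (other covers) everywhere.
    """
    if mgmt is None:
        mgmt = Management()
    out: dict[str, np.ndarray] = {}
    for cls in classes:
        crop = truth[cls]
        traj = run_site(
            initial_soc,
            climate,
            schedule=[cls] * climate.n_years,
            mgmt=mgmt,
            crops={cls: crop},
            decomp=decomp,
        )
        out[cls] = traj.grain if crop.harvested else traj.npp
    return out


def make_observations(
    truth: dict[str, CropParameters],
    climate: ClimateSeries,
    landuse: LandUseSequence,
    noise_cv: float,
    seed: int,
    cell_area_m2: float = 250.0**2,
    blocks: tuple[int, int] = (10, 10),
    mgmt: Management | None = None,
    decomp: DecompositionParams | None = None,
    initial_soc: float = 5.97,
) -> pd.DataFrame:
    """County-aggregated annual yield/NPP observations from a truth model.

    Runs the carbon model forward with the truth parameters, aggregates
    per-area annual grain yield (crop classes) and NPP (non-crop classes)
    to rectangular synthetic counties, and applies mean-one multiplicative
    lognormal noise with the configured CV. Columns: unit_id, year,
    variable, species, value_gC_m2, area_m2.
    """
    if landuse.n_years == 0:
        raise ValueError("empty land-use sequence")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(4,)))
    counties = county_labels(landuse.shape, blocks)
    present = [
        cls for cls, code in LANDUSE_CODES.items()
        if np.any(landuse.codes == code) and cls in truth
    ]
    per_area = per_area_outputs(
        truth, climate, present, initial_soc, mgmt=mgmt, decomp=decomp
    )
    sigma = np.sqrt(np.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0

    records = []
    county_ids = np.unique(counties)
    for cls in present:
        code = LANDUSE_CODES[cls]
        variable = "grain_yield" if truth[cls].harvested else "npp"
        values = per_area[cls]  # kg C/m²/yr per year
        for iy, year in enumerate(landuse.years):
            mask = landuse.codes[iy] == code
            counts = np.bincount(
                counties[mask].ravel(), minlength=county_ids.max() + 1
            )
            for uid in county_ids:
                if counts[uid] == 0:
                    continue
                value_g = values[iy] * 1000.0  # g C/m²/yr
                if sigma > 0:
                    value_g *= np.exp(sigma * rng.normal() - 0.5 * sigma**2)
                records.append(
                    (int(uid), int(year), variable, cls,
                     float(value_g), float(counts[uid] * cell_area_m2))
                )
    df = pd.DataFrame.from_records(
        records,
        columns=["unit_id", "year", "variable", "species", "value_gC_m2", "area_m2"],
    )
    if (df["value_gC_m2"] < 0).any():
        raise RuntimeError("negative observation generated")
    return df
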