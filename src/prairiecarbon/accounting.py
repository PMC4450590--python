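"""Carbon accounting: change maps, sink/source classification, summaries.

Converts scenario runs into the headline regional products: SOC change maps
between a start and end year, classification of each location as a carbon
sink, source or neutral (|ΔSOC| ≤ 0.5 kg C/m² over the projection window is
neutral, i.e. ±12.5 g C/m²/yr over 40 years), density↔storage conversions
(storage in TgC = 10¹² g C), sequestration rates, relative increases, and
a scenario summary table in the conventional layout (areas, stover biomass,
corn-field and regional SOC storage and density, sequestration rates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenarios import RegionalRun, corn_mask
from .synthetic import LANDUSE_CODES, LandUseSequence

__all__ = [
    "ChangeMap",
    "ClassificationSummary",
    "classify_change",
    "change_map",
    "area_fractions",
    "density_to_storage",
    "storage_to_density",
    "sequestration_rate",
    "total_from_rate",
    "relative_increase",
    "build_summary",
]

NEUTRAL_THRESHOLD_KG = 0.5      # |ΔSOC| at or below this is carbon-neutral
LABELS = ("sink", "neutral", "source")
LABEL_CODES = {"sink": 1, "neutral": 0, "source": -1}


@dataclass(frozen=True)
class ChangeMap:
    """Per-sample ΔSOC = SOC(end) − SOC(start), kg C/m²."""

    delta: np.ndarray
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.start_year >= self.end_year:
            raise ValueError("start_year must precede end_year")
        if not np.all(np.isfinite(self.delta)):
            raise ValueError("non-finite SOC change")


@dataclass(frozen=True)
class ClassificationSummary:
    """Area fractions of sink/neutral/source; fractions sum to 1."""

    fractions: dict[str, float]
    threshold_kg: float

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1")


def classify_change(
    delta: float | np.ndarray, threshold: float = NEUTRAL_THRESHOLD_KG
):
    """Label SOC change: sink if Δ > threshold, source if Δ < −threshold.

    Boundary values (|Δ| exactly equal to the threshold) are neutral.
    Accepts scalars (returns a string) or arrays (returns integer codes
    1 sink / 0 neutral / −1 source).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    arr = np.asarray(delta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite SOC change")
    codes = np.where(arr > threshold, 1, np.where(arr < -threshold, -1, 0))
    if np.isscalar(delta) or arr.ndim == 0:
        return {1: "sink", 0: "neutral", -1: "source"}[int(codes)]
    return codes


def change_map(run: RegionalRun, start_year: int, end_year: int) -> ChangeMap:
    """ΔSOC per sampled cell between two years of a scenario run."""
    i0 = int(np.flatnonzero(run.years == start_year)[0])
    i1 = int(np.flatnonzero(run.years == end_year)[0])
    return ChangeMap(
        delta=run.soc[:, i1] - run.soc[:, i0],
        start_year=start_year,
        end_year=end_year,
    )


def area_fractions(
    delta: np.ndarray,
    areas: np.ndarray | None = None,
    threshold: float = NEUTRAL_THRESHOLD_KG,
) -> ClassificationSummary:
    """Area-weighted sink/neutral/source fractions over a masked set."""
    delta = np.asarray(delta, dtype=float)
    if delta.size == 0:
        raise ValueError("empty mask: nothing to classify")
    if areas is None:
        areas = np.ones_like(delta)
    areas = np.asarray(areas, dtype=float)
    codes = classify_change(delta, threshold)
    total = areas.sum()
    fractions = {
        label: float(areas[codes == code].sum() / total)
        for label, code in LABEL_CODES.items()
    }
    # guard the sum-to-one invariant against rounding drift
    drift = 1.0 - sum(fractions.values())
    fractions["neutral"] += drift
    return ClassificationSummary(fractions=fractions, threshold_kg=threshold)


def density_to_storage(density_kg_m2: float, area_km2: float) -> float:
    """kg C/m² over km² → TgC (10¹² g C): density × area × 10⁶ / 10⁹."""
    if area_km2 < 0:
        raise ValueError("negative area")
    if np.any(np.asarray(density_kg_m2) < 0):
        raise ValueError("negative density")
    return float(density_kg_m2 * area_km2 * 1e6 / 1e9)


def storage_to_density(storage_tgc: float, area_km2: float) -> float:
    """Inverse of :func:`density_to_storage`."""
    if area_km2 <= 0:
        raise ValueError("area must be positive")
    return float(storage_tgc * 1e9 / (area_km2 * 1e6))


def sequestration_rate(d_start: float, d_end: float, years: float) -> float:
    """Mean annual SOC change, g C/m²/yr: (d_end − d_start)·1000/years."""
    if years <= 0:
        raise ValueError("years must be positive")
    return float((d_end - d_start) * 1000.0 / years)


def total_from_rate(rate_g_m2_yr: float, area_km2: float) -> float:
    """Regional sequestration total, TgC/yr: rate × area × 10⁶ / 10¹²."""
    if area_km2 < 0:
        raise ValueError("negative area")
    return float(rate_g_m2_yr * area_km2 * 1e6 / 1e12)


def relative_increase(v0: float, v1: float) -> float:
    """Percent change relative to the base value: 100·(v1−v0)/v0."""
    if v0 <= 0:
        raise ValueError("base value must be positive")
    return float(100.0 * (v1 - v0) / v0)


def _masked_mean_density(run: RegionalRun, year: int, mask: np.ndarray | None) -> float:
    iy = int(np.flatnonzero(run.years == year)[0])
    if mask is None:
        keep = np.ones(run.samples.n_samples, dtype=bool)
    else:
        keep = mask[run.samples.rows, run.samples.cols]
    w = run.samples.rep_area_m2[keep]
    return float(np.average(run.soc[keep, iy], weights=w))


def _mask_fraction(run: RegionalRun, mask: np.ndarray) -> float:
    keep = mask[run.samples.rows, run.samples.cols]
    return float(run.samples.rep_area_m2[keep].sum() / run.samples.rep_area_m2.sum())


def build_summary(
    runs: dict[str, RegionalRun],
    landuse_by_track: dict[str, LandUseSequence],
    region_area_km2: float = 521455.0,
    base_year: int = 2010,
    end_year: int = 2050,
) -> pd.DataFrame:
    """Scenario summary table: areas, stover, SOC storage/density, rates.

    The synthetic grid is treated as a statistical sample of the region:
    class fractions and area-weighted mean densities scale to
    ``region_area_km2``. Corn-field columns use the fixed corn-area mask
    (corn planted in any year of [base_year, end_year]); corn planting area
    is the per-year planted fraction. Full-precision values are emitted;
    round for display.
    """
    if not runs:
        raise ValueError("no runs supplied")
    years_ref = next(iter(runs.values())).years
    rows = []
    for name, run in runs.items():
        if not np.array_equal(run.years, years_ref):
            raise ValueError("inconsistent years across runs")
        track = run.spec.climate_landuse_track
        lu = landuse_by_track[track]
        mask = corn_mask(lu, base_year, end_year)
        corn_frac_end = lu.class_fractions(end_year)["corn"]
        corn_area_km2 = corn_frac_end * region_area_km2
        mask_area_km2 = _mask_fraction(run, mask) * region_area_km2

        # per-area corn stover in the end year (area-weighted over sampled
        # corn cells), scaled by the planted corn area to a regional total
        iy_end = int(np.flatnonzero(run.years == end_year)[0])
        corn_now = run.landuse_codes[:, iy_end] == LANDUSE_CODES["corn"]
        if corn_now.any():
            stover_density = float(np.average(
                run.stover[corn_now, iy_end],
                weights=run.samples.rep_area_m2[corn_now],
            ))
        else:
            stover_density = 0.0
        stover_capacity_tg = density_to_storage(stover_density, corn_area_km2)

        corn_density_start = _masked_mean_density(run, base_year, mask)
        corn_density_end = _masked_mean_density(run, end_year, mask)
        region_density_start = _masked_mean_density(run, base_year, None)
        region_density_end = _masked_mean_density(run, end_year, None)
        span = end_year - base_year

        rows.append(
            {
                "scenario": name,
                "track": track,
                "removal_rate": run.spec.stover_removal_rate,
                "corn_area_km2": corn_area_km2,
                "stover_capacity_TgC_yr": stover_capacity_tg,
                "stover_density_kgC_m2_yr": stover_density,
                "cornfield_soc_density_kgC_m2": corn_density_end,
                "cornfield_soc_storage_TgC": density_to_storage(
                    corn_density_end, mask_area_km2
                ),
                "regional_soc_density_kgC_m2": region_density_end,
                "regional_soc_storage_TgC": density_to_storage(
                    region_density_end, region_area_km2
                ),
                "cornfield_seq_rate_gC_m2_yr": sequestration_rate(
                    corn_density_start, corn_density_end, span
                ),
                "regional_seq_rate_gC_m2_yr": sequestration_rate(
                    region_density_start, region_density_end, span
                ),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["regional_storage_range_TgC"] = float(
        df["regional_soc_storage_TgC"].max() - df["regional_soc_storage_TgC"].min()
    )
    df.attrs["base_year"] = base_year
    df.attrs["end_year"] = end_year
    return df
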