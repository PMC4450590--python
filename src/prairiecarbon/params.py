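"""Domain parameter containers shared across the package.

Units follow the CENTURY-family convention used throughout: carbon pools in
kg C/m², monthly fluxes in g C/m²/month, precipitation in mm/month,
temperature in °C, CO₂ in ppm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ClimateSeries",
    "CropParameters",
    "Management",
    "DecompositionParams",
    "DEFAULT_CROPS",
    "CROP_CLASSES",
    "NONCROP_CLASSES",
]

#: land-cover classes that carry a crop harvest
CROP_CLASSES = ("corn", "soybean", "wheat")
#: unharvested classes (production senesces to litter every autumn)
NONCROP_CLASSES = ("grass_shrub", "forest", "wetland", "other")


@dataclass(frozen=True)
class ClimateSeries:
    """Monthly climate forcing plus the annual CO₂ path for one site or cell.

    Arrays are shaped ``(n_years, 12)`` for the monthly fields and
    ``(n_years,)`` for CO₂; ``years`` gives the calendar year of each row.
    """

    years: np.ndarray            # (n_years,) calendar years, contiguous
    precip_mm: np.ndarray        # (n_years, 12) monthly precipitation, mm
    tmean_c: np.ndarray          # (n_years, 12) monthly mean air temperature, °C
    co2_ppm: np.ndarray          # (n_years,) annual CO₂ concentration

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        precip = np.asarray(self.precip_mm, dtype=float)
        tmean = np.asarray(self.tmean_c, dtype=float)
        co2 = np.asarray(self.co2_ppm, dtype=float)
        if precip.shape != (years.size, 12) or tmean.shape != (years.size, 12):
            raise ValueError("monthly fields must be (n_years, 12)")
        if co2.shape != (years.size,):
            raise ValueError("co2_ppm must be (n_years,)")
        if np.any(precip < 0):
            raise ValueError("precipitation must be non-negative")
        if np.any(co2 <= 0):
            raise ValueError("CO2 must be positive")
        if years.size > 1 and not np.all(np.diff(years) == 1):
            raise ValueError("years must be contiguous")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "precip_mm", precip)
        object.__setattr__(self, "tmean_c", tmean)
        object.__setattr__(self, "co2_ppm", co2)

    @property
    def n_years(self) -> int:
        return int(self.years.size)

    def year_index(self, year: int) -> int:
        i = int(year - self.years[0])
        if i < 0 or i >= self.n_years:
            raise KeyError(f"year {year} outside climate span")
        return i

    def window(self, start_year: int, end_year: int) -> "ClimateSeries":
        """Sub-series covering [start_year, end_year] inclusive."""
        i0 = self.year_index(start_year)
        i1 = self.year_index(end_year) + 1
        return ClimateSeries(
            years=self.years[i0:i1],
            precip_mm=self.precip_mm[i0:i1],
            tmean_c=self.tmean_c[i0:i1],
            co2_ppm=self.co2_ppm[i0:i1],
        )


@dataclass(frozen=True)
class CropParameters:
    """Species parameters controlling monthly production and partitioning.

    ``prdx`` is the genetic maximum potential production (g C/m²/month); it is
    the single parameter targeted by regional calibration. ``harvest_index``
    is expressed as the stover:grain ratio (1.0 means stover biomass equals
    grain yield in carbon terms). ``harvested=False`` marks unmanaged covers
    whose seasonal biomass senesces to litter instead of being harvested.
    """

    species: str
    prdx: float                       # g C/m²/month potential production
    t_min: float = 8.0                # °C, production stops at/below
    t_opt: float = 25.0               # °C, production optimum
    t_max: float = 40.0               # °C, production stops at/above
    harvest_index: float = 1.0        # stover:grain ratio
    co2_beta: float = 0.2             # log CO₂ response coefficient
    co2_ref: float = 370.0            # ppm reference concentration
    enhancement_rate: float = 0.01    # fraction/yr yield-technology trend
    root_fraction: float = 0.2        # fraction of NPP allocated below ground
    lignin_fraction: float = 0.25     # structural fraction of surface residue
    harvested: bool = True

    def __post_init__(self) -> None:
        if self.prdx <= 0:
            raise ValueError("prdx must be positive")
        if not (self.t_min < self.t_opt < self.t_max):
            raise ValueError("require t_min < t_opt < t_max")
        if not (0.0 <= self.enhancement_rate <= 0.02):
            raise ValueError("enhancement_rate outside [0, 0.02]")
        for name in ("root_fraction", "lignin_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0, 1]")
        if self.harvest_index < 0:
            raise ValueError("harvest_index (stover:grain) must be >= 0")

    def with_prdx(self, prdx: float) -> "CropParameters":
        return replace(self, prdx=float(prdx))


#: default species library; PRDX values are package defaults sized so a
#: baseline Temperate-Prairies climate yields ~0.45 kg C/m² corn grain,
#: and are the quantities regional calibration re-estimates.
DEFAULT_CROPS: dict[str, CropParameters] = {
    "corn": CropParameters("corn", prdx=315.0, t_min=8, t_opt=25, t_max=40),
    "soybean": CropParameters("soybean", prdx=160.0, t_min=8, t_opt=24, t_max=38),
    "wheat": CropParameters("wheat", prdx=150.0, t_min=4, t_opt=20, t_max=34),
    "grass_shrub": CropParameters(
        "grass_shrub", prdx=130.0, t_min=2, t_opt=22, t_max=38, harvested=False
    ),
    "forest": CropParameters(
        "forest", prdx=150.0, t_min=2, t_opt=20, t_max=36,
        root_fraction=0.3, lignin_fraction=0.4, harvested=False
    ),
    "wetland": CropParameters(
        "wetland", prdx=140.0, t_min=2, t_opt=22, t_max=38, harvested=False
    ),
    "other": CropParameters(
        "other", prdx=60.0, t_min=2, t_opt=22, t_max=38, harvested=False
    ),
}


@dataclass(frozen=True)
class Management:
    """Field management: growing season window and stover export.

    ``stover_removal_rate`` is the fraction of produced stover exported at
    harvest; it applies only to harvested crops. ``nitrogen_limiting``
    defaults to False (auto-fertilization: N never limits growth); the
    toggle exists for completeness but no explicit N pools are simulated.
    """

    stover_removal_rate: float = 0.0
    planting_month: int = 5
    harvest_month: int = 10
    nitrogen_limiting: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.stover_removal_rate <= 1.0):
            raise ValueError("stover_removal_rate outside [0, 1]")
        if not (1 <= self.planting_month < self.harvest_month <= 12):
            raise ValueError("require 1 <= planting_month < harvest_month <= 12")


def _default_k() -> dict[str, float]:
    return {
        "structural": 0.076,
        "metabolic": 0.28,
        "active": 0.06,
        "slow": 0.005,
        "passive": 0.00018,
    }


def _default_resp() -> dict[str, float]:
    return {
        "structural": 0.55,
        "metabolic": 0.55,
        "active": 0.6,
        "slow": 0.55,
        "passive": 0.55,
    }


@dataclass(frozen=True)
class DecompositionParams:
    """First-order decomposition constants (per month) and routing.

    Non-respired decay flux is routed surface-litter → layer-1 SOM and
    active → slow → passive → active within each layer. The decomposition
    temperature response uses the same unimodal curve as production with a
    microbial optimum; moisture response is the capped supply/demand ratio.
    """

    k_month: dict[str, float] = field(default_factory=_default_k)
    respiration_fraction: dict[str, float] = field(default_factory=_default_resp)
    t_min: float = -10.0
    t_opt: float = 25.0
    t_max: float = 45.0
    # mm/month of evaporative demand per °C above zero, plus a floor:
    # demand = demand_base + demand_per_degc * max(t, 0)
    demand_base: float = 30.0
    demand_per_degc: float = 4.0
    # multiplier on decay rates in years under a harvested crop: tillage and
    # residue incorporation speed decomposition on cultivated fields
    cultivation_factor: float = 1.8
    # routing of the non-respired decay flux: structural litter splits
    # between slow (lignin-derived) and active; slow splits between passive
    # (stabilized) and active; metabolic→active and passive→active are fixed
    struct_to_slow: float = 0.3
    slow_to_passive: float = 0.07

    def __post_init__(self) -> None:
        for pool, k in self.k_month.items():
            if k < 0:
                raise ValueError(f"negative rate constant for {pool}")
        for pool, f in self.respiration_fraction.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"respiration fraction for {pool} outside [0,1]")
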