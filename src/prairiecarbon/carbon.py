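"""Monthly CENTURY/EDCM-family site carbon model.

The model tracks two surface litter pools (structural, metabolic), three
soil organic matter pools (active, slow, passive) in up to 10 soil layers,
and standing seasonal biomass. Plant production each growing-season month is
the product of a genetic potential (PRDX) with temperature, moisture, CO₂
and technology-enhancement multipliers; at harvest the seasonal biomass is
partitioned into grain, exported stover, surface residue and root input, and
all pools then decompose with first-order kinetics under shared climate
rate modifiers. Carbon is conserved exactly: every month,
inputs − respiration − exports = Δ(litter + SOM + standing biomass).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    ClimateSeries,
    CropParameters,
    DecompositionParams,
    Management,
)

__all__ = [
    "CarbonState",
    "MonthlyFluxes",
    "Trajectory",
    "temperature_scalar",
    "moisture_scalar",
    "co2_multiplier",
    "enhancement_multiplier",
    "production_month",
    "partition_harvest",
    "decompose_month",
    "initialize_state",
    "step_month",
    "run_site",
]

_POOL_NAMES = ("active", "slow", "passive")


@dataclass
class CarbonState:
    """Carbon stocks (kg C/m²) with a (year, month) stamp.

    ``som`` is shaped ``(n_layers, 3)`` with columns active/slow/passive;
    ``layer_thickness_m`` the corresponding layer depths.
    """

    litter_structural: float
    litter_metabolic: float
    som: np.ndarray                 # (n_layers, 3) kg C/m²
    layer_thickness_m: np.ndarray   # (n_layers,)
    standing_biomass: float = 0.0
    year: int = 0
    month: int = 1

    def __post_init__(self) -> None:
        self.som = np.array(self.som, dtype=float)
        self.layer_thickness_m = np.asarray(self.layer_thickness_m, dtype=float)
        if self.som.ndim != 2 or self.som.shape[1] != 3:
            raise ValueError("som must be (n_layers, 3)")
        if not (1 <= self.som.shape[0] <= 10):
            raise ValueError("number of layers must be in [1, 10]")
        if self.litter_structural < 0 or self.litter_metabolic < 0:
            raise ValueError("negative litter pool")
        if np.any(self.som < 0):
            raise ValueError("negative SOM pool")

    @property
    def n_layers(self) -> int:
        return self.som.shape[0]

    @property
    def soc_total(self) -> float:
        """Profile SOC density, kg C/m² (litter excluded)."""
        return float(self.som.sum())

    @property
    def total_carbon(self) -> float:
        """All tracked carbon incl. litter and standing biomass, kg C/m²."""
        return (
            self.litter_structural
            + self.litter_metabolic
            + float(self.som.sum())
            + self.standing_biomass
        )

    def copy(self) -> "CarbonState":
        return CarbonState(
            litter_structural=self.litter_structural,
            litter_metabolic=self.litter_metabolic,
            som=self.som.copy(),
            layer_thickness_m=self.layer_thickness_m.copy(),
            standing_biomass=self.standing_biomass,
            year=self.year,
            month=self.month,
        )


@dataclass(frozen=True)
class MonthlyFluxes:
    """Monthly carbon fluxes, g C/m²/month; all non-negative."""

    npp: float = 0.0
    heterotrophic_respiration: float = 0.0
    litter_input: float = 0.0
    harvested_grain: float = 0.0
    exported_stover: float = 0.0


@dataclass(frozen=True)
class Trajectory:
    """Annual outputs of a site run (kg C/m² throughout)."""

    years: np.ndarray
    soc: np.ndarray                # end-of-December profile SOC density
    grain: np.ndarray              # harvested grain yield
    stover_produced: np.ndarray    # aboveground non-grain biomass
    stover_exported: np.ndarray    # stover removed from the field
    npp: np.ndarray                # annual net primary production

    def __post_init__(self) -> None:
        if np.any(self.stover_exported > self.stover_produced + 1e-12):
            raise ValueError("exported stover exceeds production")


def _beta_scalar(t: float, t_min: float, t_opt: float, t_max: float) -> float:
    if t <= t_min or t >= t_max:
        return 0.0
    upper = (t_max - t) / (t_max - t_opt)
    lower = (t - t_min) / (t_opt - t_min)
    q = (t_opt - t_min) / (t_max - t_opt)
    return float(min(1.0, upper * lower ** q))


def temperature_scalar(t: float, params: CropParameters) -> float:
    """Unimodal temperature limitation in [0, 1].

    Generalized beta curve on (t_min, t_opt, t_max): zero at or beyond the
    cardinal limits, exactly 1 at the optimum. The exponent on the sub-optimal
    branch is chosen so the two branches peak together at ``t_opt``.
    """
    return _beta_scalar(t, params.t_min, params.t_opt, params.t_max)


def moisture_scalar(precip_mm: float, demand_mm: float) -> float:
    """Capped supply/demand water limitation: min(1, precip/demand)."""
    if demand_mm <= 0:
        raise ValueError("demand must be positive")
    return float(min(1.0, max(0.0, precip_mm) / demand_mm))


def co2_multiplier(co2: float, params: CropParameters) -> float:
    """Logarithmic CO₂ fertilization: 1 + β·ln(CO₂/CO₂_ref)."""
    if co2 <= 0:
        raise ValueError("CO2 must be positive")
    return float(1.0 + params.co2_beta * np.log(co2 / params.co2_ref))


def enhancement_multiplier(year: int, base_year: int, rate: float) -> float:
    """Compound technology trend on yields: (1+rate)^(year − base_year)."""
    if year < base_year:
        raise ValueError("year precedes base_year")
    return float((1.0 + rate) ** (year - base_year))


def _demand_mm(t: float, decomp: DecompositionParams) -> float:
    """Monthly evaporative demand from a temperature-indexed linear rule."""
    return decomp.demand_base + decomp.demand_per_degc * max(t, 0.0)


def production_month(
    crop: CropParameters,
    t: float,
    moisture: float,
    co2: float,
    year: int,
    base_year: int,
) -> float:
    """Monthly NPP (g C/m²/month) inside the growing season.

    npp = PRDX × f(T) × f(W) × f(CO₂) × f(technology); callers zero it
    outside the planting→harvest window.
    """
    ts = temperature_scalar(t, crop)
    fc = co2_multiplier(co2, crop)
    fe = enhancement_multiplier(year, base_year, crop.enhancement_rate)
    npp = crop.prdx * ts * moisture * fc * fe
    return float(max(0.0, npp))


def partition_harvest(
    season_npp: float,
    crop: CropParameters,
    mgmt: Management,
) -> tuple[float, float, float, float, float]:
    """Split seasonal NPP at harvest.

    Returns ``(grain, stover_produced, stover_exported, residue_to_litter,
    root_to_soil)``; the four sinks (grain, exported, residue, root) sum to
    ``season_npp`` exactly. With the corn stover:grain ratio of 1.0, stover
    equals grain. Unharvested covers get zero grain and no export: all
    aboveground biomass returns as residue.
    """
    if season_npp < 0:
        raise ValueError("season_npp must be non-negative")
    root = crop.root_fraction * season_npp
    aboveground = season_npp - root
    if crop.harvested:
        grain = aboveground / (1.0 + crop.harvest_index)
        stover = aboveground - grain
        exported = mgmt.stover_removal_rate * stover
    else:
        grain = 0.0
        stover = 0.0
        exported = 0.0
    residue = aboveground - grain - exported
    return grain, stover, exported, residue, root


def _scaled_rates(
    decomp: DecompositionParams, t_scalar: float, m_scalar: float,
    rate_multiplier: float = 1.0,
) -> tuple[float, float, float, float, float]:
    s = t_scalar * m_scalar * rate_multiplier
    k = decomp.k_month
    rates = (
        k["structural"] * s,
        k["metabolic"] * s,
        k["active"] * s,
        k["slow"] * s,
        k["passive"] * s,
    )
    if any(r > 1.0 for r in rates):
        raise ValueError("k·s > 1: monthly explicit step unstable")
    return rates


def decompose_month(
    state: CarbonState,
    t_scalar: float,
    m_scalar: float,
    decomp: DecompositionParams,
    rate_multiplier: float = 1.0,
) -> tuple[CarbonState, float]:
    """One month of first-order decomposition.

    Each pool loses flux = k·f(T)·f(W)·pool (times an optional cultivation
    multiplier); a pool-specific fraction of the flux is respired as CO₂ and
    the remainder transfers along structural→slow(1), metabolic→active(1),
    active→slow, slow→passive, passive→active. Returns the new state and
    heterotrophic respiration in kg C/m²; Δ(total pools) = −respiration
    exactly.
    """
    if not (0.0 <= t_scalar <= 1.0 and 0.0 <= m_scalar <= 1.0):
        raise ValueError("scalars must lie in [0, 1]")
    ks, km, ka, ksl, kp = _scaled_rates(decomp, t_scalar, m_scalar, rate_multiplier)
    rf = decomp.respiration_fraction

    new = state.copy()
    f_struct = ks * state.litter_structural
    f_metab = km * state.litter_metabolic
    f_active = ka * state.som[:, 0]
    f_slow = ksl * state.som[:, 1]
    f_passive = kp * state.som[:, 2]

    resp = (
        rf["structural"] * f_struct
        + rf["metabolic"] * f_metab
        + rf["active"] * float(f_active.sum())
        + rf["slow"] * float(f_slow.sum())
        + rf["passive"] * float(f_passive.sum())
    )

    new.litter_structural = state.litter_structural - f_struct
    new.litter_metabolic = state.litter_metabolic - f_metab
    new.som = state.som.copy()
    new.som[:, 0] -= f_active
    new.som[:, 1] -= f_slow
    new.som[:, 2] -= f_passive
    # surface litter products enter the top layer; the structural stream
    # splits between slow (lignin-derived) and active carbon
    struct_products = (1.0 - rf["structural"]) * f_struct
    new.som[0, 1] += decomp.struct_to_slow * struct_products
    new.som[0, 0] += (1.0 - decomp.struct_to_slow) * struct_products
    new.som[0, 0] += (1.0 - rf["metabolic"]) * f_metab
    # within-layer cascade: active→slow; slow mostly recycles to active with
    # a small stabilized share to passive; passive→active
    new.som[:, 1] += (1.0 - rf["active"]) * f_active
    slow_products = (1.0 - rf["slow"]) * f_slow
    new.som[:, 2] += decomp.slow_to_passive * slow_products
    new.som[:, 0] += (1.0 - decomp.slow_to_passive) * slow_products
    new.som[:, 0] += (1.0 - rf["passive"]) * f_passive

    if new.litter_structural < 0 or new.litter_metabolic < 0 or np.any(new.som < 0):
        raise RuntimeError("negative pool after decomposition (integration bug)")
    return new, float(resp)


def initialize_state(
    initial_soc: float,
    n_layers: int = 10,
    pool_fractions: tuple[float, float, float] = (0.05, 0.45, 0.50),
    layer_decay: float = 0.7,
) -> CarbonState:
    """Distribute an initial profile SOC density over layers and pools.

    Layer masses follow a normalized geometric series with ratio
    ``layer_decay`` (shallow layers hold more carbon); pool fractions default
    to active/slow/passive = 0.05/0.45/0.50. The pool total reproduces
    ``initial_soc`` exactly.
    """
    if initial_soc <= 0:
        raise ValueError("initial SOC must be positive")
    if not (1 <= n_layers <= 10):
        raise ValueError("n_layers must be in [1, 10]")
    pf = np.asarray(pool_fractions, dtype=float)
    if pf.min() < 0 or abs(pf.sum() - 1.0) > 1e-12:
        raise ValueError("pool fractions must be non-negative and sum to 1")
    w = layer_decay ** np.arange(n_layers)
    w /= w.sum()
    som = initial_soc * np.outer(w, pf)
    thickness = np.full(n_layers, 0.2)
    return CarbonState(
        litter_structural=0.0,
        litter_metabolic=0.0,
        som=som,
        layer_thickness_m=thickness,
        standing_biomass=0.0,
    )


def _add_residue(state: CarbonState, residue: float, root: float,
                 crop: CropParameters) -> None:
    """Route surface residue and root litter into the litter pools.

    Both streams split structural/metabolic by the species lignin fraction;
    their decay products then cascade into the layer SOM pools.
    """
    total = residue + root
    state.litter_structural += crop.lignin_fraction * total
    state.litter_metabolic += (1.0 - crop.lignin_fraction) * total


def step_month(
    state: CarbonState,
    precip_mm: float,
    tmean_c: float,
    co2_ppm: float,
    crop: CropParameters | None,
    mgmt: Management,
    decomp: DecompositionParams,
    year: int,
    month: int,
    base_year: int,
) -> tuple[CarbonState, MonthlyFluxes]:
    """Advance the site one month: production, harvest, decomposition."""
    if month != state.month or year != state.year:
        raise ValueError("calendar mismatch between state and forcing")
    new = state.copy()

    npp_g = 0.0
    grain_g = 0.0
    exported_g = 0.0
    litter_in_g = 0.0

    if crop is not None and mgmt.planting_month <= month <= mgmt.harvest_month:
        demand = _demand_mm(tmean_c, decomp)
        wm = moisture_scalar(precip_mm, demand)
        npp_g = production_month(crop, tmean_c, wm, co2_ppm, year, base_year)
        new.standing_biomass += npp_g / 1000.0

    if crop is not None and month == mgmt.harvest_month:
        season = new.standing_biomass
        grain, _stover, exported, residue, root = partition_harvest(season, crop, mgmt)
        _add_residue(new, residue, root, crop)
        new.standing_biomass = 0.0
        grain_g = grain * 1000.0
        exported_g = exported * 1000.0
        litter_in_g = (residue + root) * 1000.0

    td = _beta_scalar(tmean_c, decomp.t_min, decomp.t_opt, decomp.t_max)
    wd = moisture_scalar(precip_mm, _demand_mm(tmean_c, decomp))
    cult = decomp.cultivation_factor if (crop is not None and crop.harvested) else 1.0
    new, resp_kg = decompose_month(new, td, wd, decomp, rate_multiplier=cult)

    new.month = month % 12 + 1
    new.year = year + (1 if month == 12 else 0)
    fluxes = MonthlyFluxes(
        npp=npp_g,
        heterotrophic_respiration=resp_kg * 1000.0,
        litter_input=litter_in_g,
        harvested_grain=grain_g,
        exported_stover=exported_g,
    )
    return new, fluxes


def run_site(
    initial_soc: float,
    climate: ClimateSeries,
    schedule: list[str],
    mgmt: Management,
    crops: dict[str, CropParameters],
    decomp: DecompositionParams | None = None,
    removal_by_year: np.ndarray | None = None,
    n_layers: int = 10,
    base_year: int | None = None,
    check_balance: bool = False,
) -> Trajectory:
    """Run the site model over the climate span and report annual outputs.

    ``schedule`` names the land-cover/species for each year (one entry per
    climate year); ``removal_by_year`` optionally overrides the management
    stover removal rate per year (e.g. zero during a baseline period).
    With ``check_balance`` the cumulative mass-balance residual is asserted
    below 1e-9 relative each month.
    """
    if decomp is None:
        decomp = DecompositionParams()
    if len(schedule) != climate.n_years:
        raise ValueError("schedule length must match climate span")
    if removal_by_year is None:
        removal = np.full(climate.n_years, mgmt.stover_removal_rate)
    else:
        removal = np.asarray(removal_by_year, dtype=float)
        if removal.shape != (climate.n_years,):
            raise ValueError("removal_by_year length mismatch")
    if base_year is None:
        base_year = int(climate.years[0])

    state = initialize_state(initial_soc, n_layers=n_layers)
    state.year = int(climate.years[0])
    state.month = 1

    ny = climate.n_years
    soc = np.empty(ny)
    grain = np.zeros(ny)
    stov_prod = np.zeros(ny)
    stov_exp = np.zeros(ny)
    npp = np.zeros(ny)

    carbon0 = state.total_carbon
    cum_in = 0.0
    cum_out = 0.0

    for iy in range(ny):
        year = int(climate.years[iy])
        species = schedule[iy]
        crop = crops.get(species)
        if crop is None:
            raise KeyError(f"unknown land-use class {species!r}")
        mgmt_y = Management(
            stover_removal_rate=float(removal[iy]) if crop.harvested else 0.0,
            planting_month=mgmt.planting_month,
            harvest_month=mgmt.harvest_month,
            nitrogen_limiting=mgmt.nitrogen_limiting,
        )
        for im in range(12):
            state, fl = step_month(
                state,
                precip_mm=float(climate.precip_mm[iy, im]),
                tmean_c=float(climate.tmean_c[iy, im]),
                co2_ppm=float(climate.co2_ppm[iy]),
                crop=crop,
                mgmt=mgmt_y,
                decomp=decomp,
                year=year,
                month=im + 1,
                base_year=base_year,
            )
            npp[iy] += fl.npp / 1000.0
            grain[iy] += fl.harvested_grain / 1000.0
            stov_exp[iy] += fl.exported_stover / 1000.0
            cum_in += fl.npp / 1000.0
            cum_out += (
                fl.heterotrophic_respiration
                + fl.harvested_grain
                + fl.exported_stover
            ) / 1000.0
            if check_balance:
                resid = state.total_carbon - carbon0 - (cum_in - cum_out)
                if abs(resid) > 1e-9 * max(state.total_carbon, 1.0):
                    raise RuntimeError(f"mass balance violated: {resid:.3e}")
        # stover produced = grain × ratio for harvested crops
        if crop.harvested and grain[iy] > 0:
            stov_prod[iy] = grain[iy] * crop.harvest_index
        soc[iy] = state.soc_total

    return Trajectory(
        years=climate.years.copy(),
        soc=soc,
        grain=grain,
        stover_produced=stov_prod,
        stover_exported=stov_exp,
        npp=npp,
    )
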