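"""PRDX auto-calibration with the Shuffled Complex Evolution algorithm.

The genetic potential production parameter (PRDX) is the most sensitive
control on simulated plant production, so it is the single calibrated
parameter per species. The optimizer is the standard SCE-UA scheme
(shuffled complexes evolved by competitive complex evolution with
reflection/contraction/random replacement). Model skill is summarized by
percent bias (PB), the coefficient of determination (R²) and the root mean
square error (RMSE), reported separately for a calibration window (first
five observation years) and the subsequent validation years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ClimateSeries, CropParameters, DecompositionParams, Management
from .synthetic import LandUseSequence, LANDUSE_CODES, county_labels, per_area_outputs

__all__ = [
    "SCEConfig",
    "CalibrationResult",
    "percent_bias",
    "r_squared",
    "rmse",
    "split_periods",
    "sce_minimize",
    "calibrate_prdx",
]


def percent_bias(obs, sim) -> float:
    """Percent bias: 100·Σ(sim−obs)/Σobs."""
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if obs.shape != sim.shape or obs.size == 0:
        raise ValueError("obs and sim must be equal-length, non-empty")
    denom = obs.sum()
    if denom == 0:
        raise ZeroDivisionError("observation sum is zero; PB undefined")
    return float(100.0 * (sim - obs).sum() / denom)


def r_squared(obs, sim) -> float:
    """Squared Pearson correlation of observed and simulated values."""
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if obs.size < 2 or obs.shape != sim.shape:
        raise ValueError("need >= 2 paired values")
    if np.allclose(obs, obs[0]):
        raise ValueError("constant observations; R² undefined")
    r = np.corrcoef(obs, sim)[0, 1]
    return float(r * r)


def rmse(obs, sim) -> float:
    """Root mean square error in observation units."""
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if obs.shape != sim.shape or obs.size == 0:
        raise ValueError("obs and sim must be equal-length, non-empty")
    return float(np.sqrt(np.mean((sim - obs) ** 2)))


def split_periods(
    obs: pd.DataFrame, n_calibration_years: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split an observation table into calibration/validation by year.

    The first ``n_calibration_years`` observation years go to calibration,
    the remainder to validation (so a 2001–2009 yield table splits 5+4 and a
    2001–2010 NPP table 5+5). The two sets are disjoint and exhaustive.
    An empty validation set is legal but flagged with ``attrs['validation_empty']``.
    """
    if obs.empty:
        raise ValueError("empty observation table")
    years = np.sort(obs["year"].unique())
    cal_years = years[:n_calibration_years]
    cal = obs[obs["year"].isin(cal_years)].copy()
    val = obs[~obs["year"].isin(cal_years)].copy()
    val.attrs["validation_empty"] = bool(val.empty)
    return cal, val


@dataclass(frozen=True)
class SCEConfig:
    """SCE-UA hyper-parameters (standard defaults, fully seedable)."""

    n_complexes: int = 4
    points_per_complex: int | None = None   # default 2·dim+1
    max_evaluations: int = 2000
    convergence_tol: float = 1e-6           # relative best-objective change
    n_stagnant_loops: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_complexes < 2:
            raise ValueError("need at least 2 complexes")
        if self.max_evaluations <= 0:
            raise ValueError("max_evaluations must be positive")


@dataclass
class CalibrationResult:
    """Best PRDX with skill metrics on both periods."""

    species: str
    prdx: float
    objective: float
    metrics_calibration: dict[str, float]
    metrics_validation: dict[str, float]
    n_evaluations: int
    history: list[float] = field(default_factory=list)


def _cce_evolve(
    points: np.ndarray,
    values: np.ndarray,
    func,
    lower: np.ndarray,
    upper: np.ndarray,
    rng: np.random.Generator,
    n_steps: int,
    budget: list[int],
) -> None:
    """Competitive complex evolution of one complex, in place.

    Each step draws a subcomplex by triangular probability, reflects the
    worst point through the centroid of the rest (α=1), contracts toward it
    (β=0.5) if reflection fails, and falls back to a random in-bounds point.
    """
    m, dim = points.shape
    q = dim + 1
    weights = 2.0 * (m - np.arange(m)) / (m * (m + 1))
    for _ in range(n_steps):
        if budget[0] <= 0:
            return
        idx = rng.choice(m, size=min(q, m), replace=False, p=weights)
        idx = np.sort(idx)
        worst = idx[-1]
        others = idx[:-1]
        centroid = points[others].mean(axis=0)
        cand = 2.0 * centroid - points[worst]
        if np.any(cand < lower) or np.any(cand > upper):
            cand = lower + rng.random(dim) * (upper - lower)
        f_cand = func(cand)
        budget[0] -= 1
        if not np.isfinite(f_cand):
            raise ValueError(f"objective returned non-finite value at {cand}")
        if f_cand >= values[worst] and budget[0] > 0:
            cand = 0.5 * (centroid + points[worst])
            f_cand = func(cand)
            budget[0] -= 1
            if not np.isfinite(f_cand):
                raise ValueError(f"objective returned non-finite value at {cand}")
        if f_cand >= values[worst] and budget[0] > 0:
            cand = lower + rng.random(dim) * (upper - lower)
            f_cand = func(cand)
            budget[0] -= 1
            if not np.isfinite(f_cand):
                raise ValueError(f"objective returned non-finite value at {cand}")
        if f_cand < values[worst]:
            points[worst] = cand
            values[worst] = f_cand
        order = np.argsort(values, kind="stable")
        points[:] = points[order]
        values[:] = values[order]


def sce_minimize(
    objective,
    bounds,
    config: SCEConfig,
) -> tuple[np.ndarray, float, list[float]]:
    """Minimize a bounded objective with SCE-UA.

    Returns ``(best_point, best_value, history)`` where ``history`` records
    the best-so-far objective after each shuffling loop (monotone
    non-increasing). Ties are broken by evaluation order, so results are
    reproducible for a given seed.
    """
    bounds = np.asarray(bounds, dtype=float).reshape(-1, 2)
    lower, upper = bounds[:, 0], bounds[:, 1]
    if not np.all(np.isfinite(bounds)) or np.any(lower >= upper):
        raise ValueError("bounds must be finite with lower < upper")
    dim = lower.size
    rng = np.random.default_rng(config.seed)

    m = config.points_per_complex or (2 * dim + 1)
    p = config.n_complexes
    s = p * m

    def f(x: np.ndarray) -> float:
        v = float(objective(np.clip(x, lower, upper)))
        if not np.isfinite(v):
            raise ValueError(f"objective returned non-finite value at {x}")
        return v

    budget = [config.max_evaluations]
    points = lower + rng.random((s, dim)) * (upper - lower)
    points[0] = 0.5 * (lower + upper)  # include the box midpoint
    values = np.empty(s)
    for i in range(s):
        values[i] = f(points[i])
    budget[0] -= s
    order = np.argsort(values, kind="stable")
    points, values = points[order], values[order]

    history = [float(values[0])]
    stagnant = 0
    while budget[0] > 0:
        for k in range(p):
            sel = np.arange(k, s, p)
            cpts = points[sel].copy()
            cvls = values[sel].copy()
            _cce_evolve(cpts, cvls, f, lower, upper, rng, n_steps=2 * dim + 1,
                        budget=budget)
            points[sel] = cpts
            values[sel] = cvls
        order = np.argsort(values, kind="stable")
        points, values = points[order], values[order]
        best = float(values[0])
        prev = history[-1]
        history.append(best)
        rel = abs(prev - best) / max(abs(prev), 1e-12)
        stagnant = stagnant + 1 if rel < config.convergence_tol else 0
        if stagnant >= config.n_stagnant_loops:
            break

    return points[0].copy(), float(values[0]), history


def _county_totals(
    obs: pd.DataFrame,
    per_area_kg: np.ndarray,
    years: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair observed and simulated annual county totals (g C)."""
    year_to_idx = {int(y): i for i, y in enumerate(years)}
    obs_tot = obs["value_gC_m2"].to_numpy() * obs["area_m2"].to_numpy()
    sim_tot = np.array(
        [per_area_kg[year_to_idx[int(y)]] * 1000.0 * a
         for y, a in zip(obs["year"], obs["area_m2"])]
    )
    return obs_tot, sim_tot


def calibrate_prdx(
    species: str,
    obs: pd.DataFrame,
    climate: ClimateSeries,
    crops: dict[str, CropParameters],
    bounds: tuple[float, float] = (50.0, 400.0),
    sce: SCEConfig | None = None,
    objective: str = "rmse",
    initial_soc: float = 5.97,
    mgmt: Management | None = None,
    decomp: DecompositionParams | None = None,
    n_calibration_years: int = 5,
) -> CalibrationResult:
    """Calibrate one species' PRDX against county observations.

    Minimizes (by default) the RMSE between simulated and observed annual
    county totals over the calibration years, then reports PB/R²/RMSE on
    both the calibration and validation splits. ``objective`` may also be
    ``"neg_r2"`` or ``"abs_pb"``.
    """
    if sce is None:
        sce = SCEConfig()
    sp_obs = obs[obs["species"] == species]
    if sp_obs.empty:
        raise ValueError(f"no observations for species {species!r}")
    cal, val = split_periods(sp_obs, n_calibration_years)
    template = crops[species]

    def simulate(prdx: float) -> np.ndarray:
        trial = {species: template.with_prdx(prdx)}
        return per_area_outputs(
            trial, climate, [species], initial_soc, mgmt=mgmt, decomp=decomp
        )[species]

    n_eval = [0]

    def score(x: np.ndarray) -> float:
        n_eval[0] += 1
        per_area = simulate(float(x[0]))
        o, s = _county_totals(cal, per_area, climate.years)
        if objective == "rmse":
            return rmse(o, s)
        if objective == "neg_r2":
            return -r_squared(o, s)
        if objective == "abs_pb":
            return abs(percent_bias(o, s))
        raise ValueError(f"unknown objective {objective!r}")

    best, value, history = sce_minimize(score, [bounds], sce)
    prdx = float(best[0])

    per_area = simulate(prdx)

    def metrics(split: pd.DataFrame) -> dict[str, float]:
        if split.empty:
            return {"PB": float("nan"), "R2": float("nan"), "RMSE": float("nan")}
        o, s = _county_totals(split, per_area, climate.years)
        out = {"PB": percent_bias(o, s), "RMSE": rmse(o, s)}
        try:
            out["R2"] = r_squared(o, s)
        except ValueError:
            out["R2"] = float("nan")
        return out

    return CalibrationResult(
        species=species,
        prdx=prdx,
        objective=float(value),
        metrics_calibration=metrics(cal),
        metrics_validation=metrics(val),
        n_evaluations=n_eval[0],
        history=[float(h) for h in history],
    )
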