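"""Readers/writers for the package's plain-text and raster exchange formats.

Climate goes to CSV (year, month, precip_mm, tmean_c) and NetCDF; land use
to per-year single-band TIFF rasters with the integer class table in a JSON
sidecar; observations and trajectories to CSV; scenario runs to NetCDF with
(cell, year) dimensions. NetCDF is written through xarray's scipy backend.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import xarray as xr
import yaml

from .carbon import Trajectory
from .params import ClimateSeries, CropParameters
from .scenarios import RegionalRun, SampleSet, ScenarioSpec
from .synthetic import LANDUSE_CODES, LandUseSequence

__all__ = [
    "write_climate_csv",
    "read_climate_csv",
    "write_climate_netcdf",
    "write_landuse_rasters",
    "read_landuse_rasters",
    "write_observations_csv",
    "read_observations_csv",
    "write_trajectory_csv",
    "write_run_netcdf",
    "read_run_netcdf",
    "write_crop_yaml",
    "read_crop_yaml",
]


def write_climate_csv(climate: ClimateSeries, path: str | Path) -> None:
    ny = climate.n_years
    df = pd.DataFrame(
        {
            "year": np.repeat(climate.years, 12),
            "month": np.tile(np.arange(1, 13), ny),
            "precip_mm": climate.precip_mm.ravel(),
            "tmean_c": climate.tmean_c.ravel(),
            "co2_ppm": np.repeat(climate.co2_ppm, 12),
        }
    )
    df.to_csv(path, index=False)


def read_climate_csv(path: str | Path) -> ClimateSeries:
    df = pd.read_csv(path)
    years = np.sort(df["year"].unique())
    df = df.sort_values(["year", "month"])
    ny = years.size
    return ClimateSeries(
        years=years,
        precip_mm=df["precip_mm"].to_numpy().reshape(ny, 12),
        tmean_c=df["tmean_c"].to_numpy().reshape(ny, 12),
        co2_ppm=df.groupby("year")["co2_ppm"].first().to_numpy(),
    )


def write_climate_netcdf(climate: ClimateSeries, path: str | Path) -> None:
    ds = xr.Dataset(
        {
            "precip_mm": (("year", "month"), climate.precip_mm),
            "tmean_c": (("year", "month"), climate.tmean_c),
            "co2_ppm": (("year",), climate.co2_ppm),
        },
        coords={"year": climate.years, "month": np.arange(1, 13)},
    )
    ds.to_netcdf(path, engine="scipy")


def write_landuse_rasters(landuse: LandUseSequence, out_dir: str | Path) -> None:
    """One single-band TIFF per year plus a JSON class-code sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for iy, year in enumerate(landuse.years):
        tifffile.imwrite(out / f"landuse_{int(year)}.tif", landuse.codes[iy])
    (out / "landuse_classes.json").write_text(
        json.dumps(LANDUSE_CODES, indent=2) + "\n"
    )


def read_landuse_rasters(out_dir: str | Path) -> LandUseSequence:
    out = Path(out_dir)
    paths = sorted(out.glob("landuse_[0-9]*.tif"))
    if not paths:
        raise FileNotFoundError(f"no land-use rasters in {out}")
    years = np.array([int(p.stem.split("_")[1]) for p in paths])
    codes = np.stack([tifffile.imread(p) for p in paths])
    return LandUseSequence(years=years, codes=codes)


def write_observations_csv(obs: pd.DataFrame, path: str | Path) -> None:
    obs.to_csv(path, index=False)


def read_observations_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame(
        {
            "year": traj.years,
            "soc_kgC_m2": traj.soc,
            "grain_kgC_m2": traj.grain,
            "stover_kgC_m2": traj.stover_produced,
            "stover_exported_kgC_m2": traj.stover_exported,
        }
    ).to_csv(path, index=False)


def write_run_netcdf(run: RegionalRun, path: str | Path) -> None:
    ds = xr.Dataset(
        {
            "soc": (("cell", "year"), run.soc),
            "grain": (("cell", "year"), run.grain),
            "stover": (("cell", "year"), run.stover),
            "stover_exported": (("cell", "year"), run.stover_exported),
            "landuse_code": (("cell", "year"), run.landuse_codes.astype(np.int32)),
            "row": (("cell",), run.samples.rows.astype(np.int32)),
            "col": (("cell",), run.samples.cols.astype(np.int32)),
            "rep_area_m2": (("cell",), run.samples.rep_area_m2),
        },
        coords={"year": run.years, "cell": np.arange(run.samples.n_samples)},
        attrs={
            "scenario": run.spec.name,
            "track": run.spec.climate_landuse_track,
            "removal_rate": run.spec.stover_removal_rate,
            "interval": run.samples.interval,
            "grid_rows": run.samples.grid_shape[0],
            "grid_cols": run.samples.grid_shape[1],
            **{f"provenance_{k}": v for k, v in run.provenance.items()},
        },
    )
    ds.to_netcdf(path, engine="scipy")


def read_run_netcdf(path: str | Path) -> RegionalRun:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    samples = SampleSet(
        rows=ds["row"].values,
        cols=ds["col"].values,
        interval=int(ds.attrs["interval"]),
        rep_area_m2=ds["rep_area_m2"].values,
        grid_shape=(int(ds.attrs["grid_rows"]), int(ds.attrs["grid_cols"])),
    )
    spec = ScenarioSpec(ds.attrs["track"], float(ds.attrs["removal_rate"]))
    return RegionalRun(
        spec=spec,
        samples=samples,
        years=ds["year"].values,
        soc=ds["soc"].values,
        grain=ds["grain"].values,
        stover=ds["stover"].values,
        stover_exported=ds["stover_exported"].values,
        landuse_codes=ds["landuse_code"].values.astype(np.int8),
        provenance={
            k.removeprefix("provenance_"): v
            for k, v in ds.attrs.items()
            if k.startswith("provenance_")
        },
    )


def write_crop_yaml(crops: dict[str, CropParameters], path: str | Path) -> None:
    payload = {name: vars(c) for name, c in crops.items()}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_crop_yaml(path: str | Path) -> dict[str, CropParameters]:
    payload = yaml.safe_load(Path(path).read_text())
    return {name: CropParameters(**kw) for name, kw in payload.items()}
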