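"""Write the synthetic inputs to their exchange formats.

Exports climate (CSV + NetCDF), per-year land-use rasters (TIFF + JSON
class table) and county observations (CSV) for use by external tools.
"""

from pathlib import Path

import prairiecarbon as pc
from prairiecarbon import io

out = Path("scratch/example_inputs")
out.mkdir(parents=True, exist_ok=True)

cfg = pc.SyntheticConfig(seed=1, grid_rows=20, grid_cols=20,
                         start_year=2001, end_year=2010)
climate = pc.make_climate(cfg)
landuse = pc.make_landuse_sequence(cfg)
obs = pc.make_observations(pc.DEFAULT_CROPS, climate, landuse,
                           noise_cv=0.05, seed=2, blocks=(4, 4))

io.write_climate_csv(climate, out / "climate.csv")
io.write_climate_netcdf(climate, out / "climate.nc")
io.write_landuse_rasters(landuse, out / "landuse")
io.write_observations_csv(obs, out / "observations.csv")
io.write_crop_yaml(pc.DEFAULT_CROPS, out / "crops.yaml")

print(f"wrote inputs under {out}/")
print(" climate.csv / climate.nc : monthly precip, temperature, annual CO2")
print(" landuse/                 : one TIFF per year + class-code JSON")
print(" observations.csv         : county yield/NPP table")
print(" crops.yaml               : species parameter file")
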