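"""Run the nine climate × stover-removal scenarios and summarize them.

Generates a synthetic region per climate track, samples it at a 5-pixel
interval, runs the carbon model per sampled cell, and prints a summary
table (areas, stover capacity, SOC densities and sequestration rates).
"""

import prairiecarbon as pc

runs, landuse_by_track = {}, {}
for track in ("A1B", "A2", "B1"):
    cfg = pc.SyntheticConfig(seed=1, grid_rows=40, grid_cols=40,
                             climate_track=track,
                             start_year=2001, end_year=2050)
    climate = pc.make_climate(cfg)
    landuse = pc.make_landuse_sequence(cfg)
    soil = pc.make_soil_map(cfg)
    landuse_by_track[track] = landuse
    for spec in pc.build_scenarios(tracks=[track]):
        runs[spec.name] = pc.run_scenario(
            spec, landuse, climate, soil, pc.DEFAULT_CROPS, interval=5
        )

summary = pc.build_summary(runs, landuse_by_track)
cols = ["scenario", "corn_area_km2", "stover_capacity_TgC_yr",
        "cornfield_soc_density_kgC_m2", "cornfield_seq_rate_gC_m2_yr",
        "regional_seq_rate_gC_m2_yr"]
print(summary[cols].round(2).to_string(index=False))
print(f"\n2050 regional SOC storage range across scenarios: "
      f"{summary.attrs['regional_storage_range_TgC']:.1f} TgC")
print("Within each track, more stover removal lowers the corn-field SOC")
print("density and its sequestration rate; the range shows how much the")
print("scenario choice matters for the 2050 regional carbon stock.")
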