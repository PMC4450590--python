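# prairiecarbon

Monthly soil–plant carbon cycling of corn-belt landscapes under crop
residue (stover) harvesting, with auto-calibration and scenario accounting.

Corn stover is a leading cellulosic biofuel feedstock, but exporting it
removes carbon that would otherwise return to the soil. Whether a corn
field stays a carbon sink therefore depends on the stover removal rate,
the climate and land-use trajectory, CO₂ fertilization and yield-technology
trends. This package is for ecosystem modellers and carbon-accounting
analysts who want a transparent, fully tested implementation of that
question: a CENTURY-family monthly biogeochemical site model, an SCE-UA
calibrator for its production parameter, a nine-scenario regional engine,
and the bookkeeping that turns simulated soil organic carbon (SOC) into
sink/source maps and regional summary tables.

## The model in brief

Monthly net primary production of a species is

```
NPP = PRDX · f_T(T) · f_W(P) · f_CO2(CO₂) · f_tech(year)
```

where `PRDX` (g C/m²/month) is the genetic potential production — the
single calibrated parameter — `f_T` a unimodal (beta-type) temperature
response on cardinal temperatures (t_min, t_opt, t_max), `f_W = min(1,
P/demand)` a capped supply/demand moisture limitation, `f_CO2 = 1 +
β·ln(CO₂/CO₂_ref)` a logarithmic CO₂ response, and `f_tech = (1+r)^Δyr` a
compound yield-technology trend. At harvest the seasonal biomass splits
into grain, stover (corn stover:grain = 1:1 in carbon terms), exported
stover (the removal rate × stover), surface residue and root litter. Litter
and three soil organic matter pools (active/slow/passive, in up to 10
layers) decompose with first-order kinetics `flux = k · f_T · f_W · pool`,
each flux partly respired and partly transferred along a CENTURY-style
cascade. Carbon is conserved to 1 part in 10⁹ every month.

Calibration minimizes the RMSE between simulated and observed annual county
totals (grain yield for crops, NPP for unmanaged covers) with the Shuffled
Complex Evolution (SCE-UA) global optimizer, reporting percent bias (PB),
R² and RMSE on a 5-year calibration window and the following validation
years. Scenarios combine three climate/land-use tracks (A1B, A2, B1) with
three removal rates (30/50/70%); SOC change over 2010–2050 classifies each
location as sink (Δ > 0.5 kg C/m²), source (Δ < −0.5) or neutral.

## Worked example

```python
import prairiecarbon as pc

cfg = pc.SyntheticConfig(seed=1, start_year=2001, end_year=2050)
climate = pc.make_climate(cfg)
traj = pc.run_site(6.31, climate, ["corn"] * climate.n_years,
                   pc.Management(stover_removal_rate=0.5), pc.DEFAULT_CROPS)
print(round(traj.grain[9], 3), round(traj.soc[9], 2), round(traj.soc[-1], 2))
print(round(pc.sequestration_rate(traj.soc[9], traj.soc[-1], 40), 1))
```

prints `0.449 6.07 6.54` and `11.8`: a continuous-corn site yielding
0.45 kg C/m² of grain in 2010 holds 6.07 kg C/m² of SOC then, 6.54 by 2050,
i.e. it sequesters 11.8 g C/m²/yr even while half its stover is exported —
rising yields (CO₂ and technology trends) keep residue returns growing.
The `examples/` scripts walk through each capability: a site run,
PRDX calibration against noisy county observations, the nine-scenario
regional engine with its summary table, sink/source classification maps,
and input export to CSV/NetCDF/TIFF.

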