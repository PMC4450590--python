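# Methods

This note documents the model formulation, the defaults and why they were
chosen, what the synthetic data generator does and does not emulate, and
the numerical and design decisions a user should know before trusting or
changing results.

## Site carbon model

The site model advances monthly and tracks, per location: standing seasonal
biomass, two surface litter pools (structural, metabolic), and three soil
organic matter (SOM) pools — active, slow, passive — in up to 10 soil
layers (default 10, 0.2 m each). All stocks are kg C/m²; monthly fluxes are
g C/m²/month.

### Production

During the growing season (planting month 5 through harvest month 10),

NPP = PRDX · f_T · f_W · f_CO2 · f_tech

- **f_T** is a generalized beta curve on cardinal temperatures: 0 at or
  beyond (t_min, t_max), exactly 1 at t_opt, unimodal between. Corn
  defaults: 8/25/40 °C.
- **f_W** = min(1, precip/demand) with monthly evaporative demand
  `30 + 4·max(T,0)` mm — a temperature-indexed linear rule sized so that
  mid-summer demand (~120 mm) moderately exceeds mean summer rainfall,
  giving typical growing-season moisture scalars of 0.6–1.0.
- **f_CO2** = 1 + β·ln(CO₂/370 ppm) with β = 0.2, a conventional
  magnitude for C₃/C₄ crop mixtures; the response form and size are
  deliberately config-exposed because published values vary widely.
- **f_tech** = (1+r)^(year−base) with r = 0.01/yr, the "baseline" annual
  yield-technology gain; a 2%/yr high-yield variant is admissible via
  config (bounds 0–0.02 enforced).

Production has no feedback from SOC (nitrogen is assumed non-limiting —
an auto-fertilization stance — and no explicit N pools exist; the
`nitrogen_limiting` flag is reserved). This makes grain linear in PRDX,
which is what lets a single-parameter calibration identify it cleanly.

### Harvest partitioning

At the harvest month, seasonal biomass B splits:

- root litter = root_fraction · B (default 0.2; 0.3 for forest),
- grain = aboveground / (1 + stover:grain ratio), ratio 1.0 for corn so
  stover equals grain in carbon terms,
- exported stover = removal_rate · stover,
- residue = the rest.

Grain and exported stover leave the system; residue and root litter enter
the litter pools split by a species lignin fraction (0.25 crops, 0.4
forest) into structural/metabolic. Unharvested covers (grass/shrub,
forest, wetland) senesce: all aboveground biomass becomes residue, no
grain, no export.

### Decomposition

First-order kinetics with shared climate modifiers:
flux_p = k_p · f_T,dec · f_W,dec · pool_p, with monthly base rates
structural 0.076, metabolic 0.28, active 0.06, slow 0.005, passive
0.00018, and respired fractions 0.55 (litter, slow, passive) and 0.60
(active). The non-respired remainder cascades:

- structural → 30% slow + 70% active (top layer) — the lignin-derived
  share stabilizes, the cellulose share cycles fast;
- metabolic → active (top layer);
- active → slow (within layer);
- slow → 7% passive + 93% active — only a small stabilized share reaches
  the passive pool; most recycles through microbial biomass. A larger
  passive share makes the passive pool a centuries-long unbounded
  accumulator, which is inconsistent with observed near-equilibrium
  prairie soils;
- passive → active.

The decomposition climate scalars use the same beta form with microbial
cardinal temperatures (−10/25/45 °C) and the same moisture rule as
production. Years under a harvested crop multiply all rates by a
cultivation factor (default 1.8): tillage and residue incorporation are
well known to accelerate turnover, and without this factor cultivated
soils at ~6 kg C/m² are far from equilibrium and drift upward at an
implausible >50 g C/m²/yr. With it, a continuous-corn site under
present-day forcing is close to steady state, and the projected sink
(≈ +12 to +16 g C/m²/yr at 30% removal, declining to roughly neutral or a
small source at 70%) emerges from the CO₂ and technology trends rather
than from initialization drift — the magnitudes and ordering a regional
corn-belt assessment reports.

### Numerics and invariants

Explicit Euler with a stability guard k·s ≤ 1 (violations raise rather
than silently go negative). Mass balance — inputs − respiration − exports
= Δ(litter+SOM+biomass) — holds to < 10⁻⁹ relative every month and is
asserted in tests; pools are non-negative by construction. A single pool
with full respiration reproduces C₀(1−ks)ⁿ to machine precision. Initial
SOC is distributed over layers by a normalized geometric series (ratio
0.7) and over pools as active/slow/passive = 0.05/0.45/0.50, reproducing
the requested total exactly.

## Synthetic data generator

The generator emulates the statistical structure of the regional inputs a
real application would ingest, not their geography:

- **Climate**: monthly temperature = 9 °C mean + 15 °C seasonal
  half-amplitude sinusoid + per-year linear warming + AR(1) noise (σ=1.5
  °C, ρ=0.3); precipitation = summer-peaked climatology summing to 780
  mm/yr × per-year trend factor × mean-one lognormal noise (CV 0.3).
  Track totals over an 80-year span: B1 +2.4 °C (the anchored value), A1B
  +2.0 °C, A2 +2.2 °C with −5% precipitation over the 40-year projection;
  the A1B/A2 magnitudes are loosely anchored defaults, not estimates of
  any particular GCM. CO₂ paths are linear from 370 ppm at 1.9–3.3
  ppm/yr by track. The warming is applied per calendar year (constant
  within a year) so the noise-free end-minus-start annual-mean identity
  is exact.
- **Land use**: seven classes (corn, soybean, wheat, grass/shrub, forest,
  wetland, other) on an abstract 250-m planar grid. Cropland area follows
  a linear ramp between configured start/end fractions (default 58.6% →
  59.8%) by converting grass/other cells; within cropland a first-order
  rotation plants corn with probability `corn_rotation_prob` (default
  0.45) and alternates soybean/wheat otherwise.
- **Soil**: initial SOC is a spatially correlated lognormal field
  (Gaussian-filtered white noise, correlation length 5 cells, CV 0.3)
  rescaled to the exact configured mean (default 5.97 kg C/m²).
- **Observations**: counties are contiguous rectangular blocks (default
  10×10). Because climate is spatially uniform, per-area annual outputs
  are computed once per land-cover class and aggregated to county ×
  species records (grain yield for crops, NPP otherwise), then multiplied
  by mean-one lognormal noise at the configured CV.

Random streams are split per component (climate/landuse/soil/obs), so
regenerating one surface never changes another; identical configs give
byte-identical outputs.

What the generator does **not** emulate: spatial climate gradients,
real geography or reprojection, inter-annual land-use shocks, erosion and
deposition, extreme-event damage (a monthly model cannot see daily heat or
drought spikes), or pest/disease variability. Tests passing on this
synthetic world therefore demonstrate the correctness and internal
consistency of the machinery — conservation, monotonicity in management,
parameter identifiability, estimator accuracy — not predictive skill on
real landscapes.

## Calibration

PRDX is calibrated per species by minimizing RMSE between simulated and
observed annual county totals over the first five observation years; the
later years are validation (a 2001–2009 yield table splits 5+4, a
2001–2010 NPP table 5+5). The objective is switchable to −R² or |PB|.
County totals (value × area) rather than per-area means are used, so large
counties weigh more — the aggregation used in regional-scale evaluations.

The optimizer is SCE-UA with complexes = 4 (2 in the fast tests),
points per complex = 2·dim+1, CCE steps per loop = 2·dim+1, reflection
α=1, contraction β=0.5, random replacement on double failure, triangular
subcomplex selection. Out-of-bounds reflections are replaced by uniform
in-box draws. Convergence: relative best-objective change < 10⁻⁶ for 5
consecutive shuffling loops, or the evaluation budget. Everything is
driven by one `numpy` Generator seed; ties break by evaluation order, so
runs are exactly reproducible.

## Scenario engine and accounting

Nine scenarios = {A1B, A2, B1} × {30%, 50%, 70%} removal. The grid is
sampled systematically (rows/cols ≡ 0 mod interval; interval 10 ≙ 1%
sampling); each sample represents its trailing block so representative
areas always sum to the grid area. Each sampled cell runs the site model
over 2001–2050 with its own per-year class schedule and initial SOC; pools
carry over across land-use transitions (no reset). Stover removal applies
only in corn years from 2011 on; baseline-period removal defaults to 0%
(an assumption, config-exposed). Non-corn crops are harvested with zero
residue removal; non-crop classes senesce.

Accounting: ΔSOC(2010→2050) per cell; sink if Δ > 0.5 kg C/m², source if
Δ < −0.5, neutral otherwise (boundaries inclusive — "between −0.5 and
0.5" reads as a closed band), equivalent to ±12.5 g C/m²/yr over 40
years. Fractions are area-weighted (identical to cell counting on a
regular sampled grid). Density↔storage conversions are exact unit
arithmetic (TgC = 10¹² g). Summary tables scale grid fractions and
area-weighted mean densities to a configurable region area (default
521,455 km²); corn-field columns use the fixed 2010–2050 corn-union mask
while the corn planting area is the per-year planted fraction — the dual
usage regional assessments employ. Stover capacity is computed as the
area-weighted per-area corn stover of sampled corn cells times the planted
corn area, which keeps the numerator and denominator on the same footing.

## Problem sizes and defaults in tests

The acceptance-style checks run at desk scale chosen as representative:
the end-to-end pipeline uses a 50×50 grid at interval 5 (100 samples) over
2001–2050 for all nine scenarios; parameter recovery uses 5 synthetic
counties × 5 calibration years at 5% observation noise with 20 replicates;
sampling accuracy uses a 100×100 grid at interval 10. The acceptance
script uses a 40×40 grid for its pipeline stage.

## Known limitations

- No erosion/deposition carbon transport, no CH₄ or wetland hydrology,
  no explicit nitrogen cycling (non-limiting by assumption).
- Production is insensitive to SOC, so soil degradation does not feed
  back on yields; in heavily degraded scenarios this overestimates
  production.
- The passive pool is effectively inert on the 40-year horizon; its
  initial share (50%) is a convention, not an observation.
- One climate series drives the whole grid; spatial SOC variation comes
  only from the initial field and land-use history.
- CLI wrappers are intentionally absent: the library functions plus the
  `examples/` scripts are the supported interface, and every exchange
  format has read/write helpers in `prairiecarbon.io`.
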