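# pollensim

Desk-scale modelling of airborne allergenic pollen: a phenology-driven
emission model for oak and ragweed pollen coupled to an Eulerian
transport/fate solver that treats pollen grains as an inert coarse-mode
aerosol, plus pollen-season indices, station verification statistics and
two-scenario (historic vs. warmer climate) comparison. Everything runs on
synthetic meteorology, vegetation and station data generated by the package
itself, so the full pipeline is reproducible on a laptop.

The intended users are aerobiologists and exposure modellers who want a
transparent, testable implementation of the pollen emission–transport
chain — each physical process is a separate conservative operator with a
per-process budget — rather than a full chemical-transport model.

## The model

**Emission.** The hourly pollen flux per unit plant-covered area is

```
F_e = q_p · L_d · L_h · (K_e·LAI + C_r·K_r·(1+LAI)) / (1 + v_d·(1+LAI)/u★)
```

where `q_p` is the annual total emission flux (grains m⁻² yr⁻¹), `L_d` and
`L_h` are the daily and hourly flowering likelihoods (fractions of the
annual and daily release), `K_e` and `K_r` are lumped meteorology adjustment
factors for direct emission and resuspension, `C_r` a resuspension
proportionality factor, `LAI` the leaf area index, `v_d` the deposition
velocity (Stokes gravitational settling: 2.36 cm s⁻¹ for 28 μm oak grains,
0.98 cm s⁻¹ for 18 μm ragweed grains) and `u★` the friction velocity. The
grid-cell emission rate is `F_g = F_e · S_g · P_c` with `S_g` the cell area
(36 km × 36 km by default) and `P_c` the fractional plant coverage; emission
is injected entirely into the first model layer (0–60 m).

**Phenology.** Season onset is triggered when cumulative growing degree
days cross a threshold, so warmer springs start earlier; daily release is a
Gaussian in time around the onset, suppressed (not redistributed) by rain;
the diurnal cycle is a wrapped Gaussian peaking mid-morning.

**Transport.** Operator-split hourly stepping, in order: emission,
horizontal advection, vertical advection, horizontal diffusion, vertical
diffusion with dry deposition as a bottom-flux boundary condition, wet
scavenging (`Λ = a·P^b`). All operators are flux-form, positivity-preserving
and exactly conservative; per-process concentration changes are recorded so
that their sum closes against the total change each hour, and the global
budget (emitted = airborne + dry deposition + wet deposition + net boundary
outflow) closes to round-off.

**Evaluation and scenarios.** Model daily means are paired with (synthetic)
station observations on observed days only; scores are the fractional bias
`FB = 2(S−O)/(S+O)`, hit/false rates at 10/50/100 grains m⁻³, and Pearson
correlation of normalized seasonal means. Five season indices — mean hourly,
max hourly, start date, season length and exceedance hours above the
clinical threshold (13 grains m⁻³ oak, 30 ragweed) — are mapped per cell and
summarized per region as mean ± sd of the historic→future changes.

## Worked example

```python
from datetime import datetime, timezone
import pollensim as ps

grid = ps.build_grid(20, 15, 4, layer_tops=[60, 150, 400, 1000],
                     t0=datetime(2004, 3, 1, tzinfo=timezone.utc), n_hours=720)
synth = ps.SynthConfig()
met = ps.gen_meteorology(grid, synth, seed=1)
veg = ps.gen_vegetation(grid, synth, seed=2)
oak = ps.oak_params()

tendency, f_e, onset = ps.emission_field(grid, met, veg, ps.MetAdjustParams(), oak)
v_s = ps.settling_velocity(oak.d_p, oak.rho_p)
run = ps.run_simulation(grid, met, tendency, v_s)

maps = ps.season_metrics_grid(run.hourly[:, 0], grid, oak, coverage=veg.pc)
cells = ps.pick_station_cells(grid, 12, seed=3, coverage=veg.pc)
obs = ps.gen_observations(run.hourly[:, 0], grid, cells, seed=4,
                          noise_sd=0.5, days_per_week=3)
rep = ps.evaluate_stations(run.hourly[:, 0], grid, obs,
                           levels=oak.verification_levels)
```

On a 20×15×4-cell grid over 30 days of March this prints:

```
settling velocity v_s = 0.0236 m/s
onset day range (vegetated cells): 12..20
mass budget relative error: 9.50e-16
process budget closure error: 1.96e-15
defined cells: 240 of 300
peak mean hourly concentration: 2393 grains/m3
peak exceedance hours (>13 grains/m3): 654 h
stations evaluated: 12
median |FB|: 0.197
normalized Pearson r = 0.901 (p = 0.0001)
```

The flowering onset falls in mid-March (earlier in the warm south of the
synthetic domain); the mass and process budgets close to round-off; peak
seasonal-mean concentrations of a few thousand grains m⁻³ occur over the
densest vegetation patches; with 50 % multiplicative observation noise and a
3-day-per-week sampling schedule, the median |FB| of ~0.2 and high
cross-station correlation show the evaluation machinery recovering the
(known) truth up to the imposed noise.

## Command line

```bash
pollensim generate --config run.yaml --out inputs/           # synthetic drivers
pollensim simulate --config run.yaml --inputs inputs/ --out run_hist/
pollensim simulate --config run.yaml --inputs inputs/ --out run_fut/ --scenario perturbed
pollensim evaluate run_hist/ stations.csv --out report.csv   # or --self-obs
pollensim compare run_hist/ run_fut/ --regions inputs/regions.nc --out deltas.csv
```

An empty YAML file is a valid config (all defaults); unknown keys are
rejected by name. Exit codes: 0 ok, 1 validation error, 2 runtime failure.
Every run directory contains a `manifest.json` (seed, config, hash) from
which it can be reproduced exactly.

## Documentation

`docs/methods.md` describes the model assumptions, parameter choices,
numerical schemes and the limits of what the synthetic-data experiments can
show about real pollen seasons.
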