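"""Synthetic meteorology, vegetation, regions and station observations.

Stands in for climate-model-downscaled drivers and allergy-network station
counts so the full pipeline runs without external data. Temperature combines
a seasonal warming ramp, a diurnal sinusoid, a smooth spatial gradient and
AR(1) noise; winds are AR(1) in time and spatially smooth; precipitation
arrives as random events with exponential intensities; humidity is
anticorrelated with the temperature anomaly. The perturbed ("future")
scenario shifts temperature by a uniform delta and rescales precipitation
and wind, mimicking a warmer climate. Station observations are daily means
of the simulated truth with multiplicative lognormal noise and an
intermittent sampling schedule (stations typically count a minimum of three
days per week).

All randomness flows from one integer seed: same seed, bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
import pandas as pd

from .grid import GridDomain, MeteoFields, RegionMask, StationSeries, VegetationMap


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic-data generator (defaults: early-spring CONUS-ish)."""

    # climate baseline
    mean_temp_c: float = 12.0        # season-mean 2-m temperature, deg C
    diurnal_amplitude_c: float = 6.0
    seasonal_ramp_c: float = 8.0     # warming across the simulation window
    spatial_gradient_c: float = 4.0  # south-north temperature drop
    temp_noise_sd_c: float = 1.5
    temp_noise_rho: float = 0.9      # AR(1) hourly autocorrelation
    # wind regime
    wind_mean: tuple = (3.0, 1.0)    # (u, v) m/s
    wind_sd: float = 1.5
    wind_rho: float = 0.85
    # precipitation
    precip_event_rate: float = 0.05  # events per hour
    precip_mean_intensity: float = 2.0  # mm/h
    # humidity
    rh_base: float = 70.0
    rh_temp_slope: float = 1.5       # % decrease per deg C of warm anomaly
    # diffusivities
    kh: float = 500.0                # m^2/s
    kv: float = 10.0                 # m^2/s
    # vegetation patchiness
    n_patches: int = 6
    coverage_max: float = 0.8
    lai_range: tuple = (1.0, 4.0)
    min_zero_fraction: float = 0.2
    # stations
    n_stations: int = 12
    sampling_days_per_week: int = 3
    obs_noise_sd: float = 0.5        # sd of log-multiplicative noise
    # scenario perturbation (future climate)
    delta_t_c: float = 2.0
    precip_scale: float = 1.1
    wind_scale: float = 1.0

    def __post_init__(self):
        if self.precip_mean_intensity <= 0 or self.precip_event_rate < 0:
            raise ValueError("precipitation parameters must be non-negative")
        if not (0 <= self.coverage_max <= 1):
            raise ValueError("coverage_max must lie in [0, 1]")


def _smooth_field(rng: np.random.Generator, ny: int, nx: int,
                  scale: float = 1.0) -> np.ndarray:
    """Smooth random surface: low-order Fourier modes, zero mean, unit-ish sd."""
    y = np.linspace(0, 2 * np.pi, ny, endpoint=False)[:, None]
    x = np.linspace(0, 2 * np.pi, nx, endpoint=False)[None, :]
    f = np.zeros((ny, nx))
    for ky in range(2):
        for kx in range(2):
            if kx == 0 and ky == 0:
                continue
            amp = rng.normal(size=2) / (1 + kx + ky)
            f += amp[0] * np.sin(ky * y + kx * x) + amp[1] * np.cos(ky * y + kx * x)
    return scale * f


def gen_meteorology(grid: GridDomain, cfg: SynthConfig, seed: int,
                    scenario: str = "baseline") -> MeteoFields:
    """Hourly synthetic drivers for one scenario ("baseline" | "perturbed").

    The perturbed scenario uses the same random draws as the baseline for
    the same seed, shifted by ``delta_t_c`` and rescaled in precipitation
    and wind, so scenario differences are purely the prescribed climate
    signal.
    """
    if scenario not in ("baseline", "perturbed"):
        raise ValueError("scenario must be 'baseline' or 'perturbed'")
    rng = np.random.default_rng(seed)
    nt, ny, nx = grid.n_hours, grid.ny, grid.nx
    hours = np.arange(nt)

    # temperature: ramp + diurnal + spatial gradient + AR(1) noise
    ramp = cfg.seasonal_ramp_c * hours / max(nt - 1, 1)
    hod = (hours + grid.t0.hour) % 24
    diurnal = cfg.diurnal_amplitude_c * np.sin(2 * np.pi * (hod - 9) / 24.0)
    lat_gradient = -cfg.spatial_gradient_c * (np.arange(ny) / max(ny - 1, 1))
    spatial = lat_gradient[:, None] + _smooth_field(rng, ny, nx, 0.5)
    noise = np.empty(nt)
    noise[0] = rng.normal()
    innov = rng.normal(size=nt)
    sd_innov = np.sqrt(1 - cfg.temp_noise_rho**2)
    for t in range(1, nt):
        noise[t] = cfg.temp_noise_rho * noise[t - 1] + sd_innov * innov[t]
    t2m_c = (cfg.mean_temp_c + ramp + diurnal)[:, None, None] \
        + spatial[None] + cfg.temp_noise_sd_c * noise[:, None, None]

    # winds: AR(1) around the mean vector, spatially smooth modulation
    wind_innov = rng.normal(size=(2, nt))
    wind_anom = np.empty((2, nt))
    wind_anom[:, 0] = wind_innov[:, 0]
    sd_w = np.sqrt(1 - cfg.wind_rho**2)
    for t in range(1, nt):
        wind_anom[:, t] = cfg.wind_rho * wind_anom[:, t - 1] + sd_w * wind_innov[:, t]
    uw = _smooth_field(rng, ny, nx, 0.3)
    vw = _smooth_field(rng, ny, nx, 0.3)
    u10 = cfg.wind_mean[0] + cfg.wind_sd * wind_anom[0][:, None, None] + uw[None]
    v10 = cfg.wind_mean[1] + cfg.wind_sd * wind_anom[1][:, None, None] + vw[None]

    # precipitation: per-hour events, exponential intensity, smooth footprint
    events = rng.random(nt) < cfg.precip_event_rate
    intensity = rng.exponential(cfg.precip_mean_intensity, size=nt)
    footprint = np.clip(_smooth_field(rng, ny, nx, 1.0) + 0.5, 0.0, None)
    precip = np.where(events, intensity, 0.0)[:, None, None] * footprint[None]

    if scenario == "perturbed":
        t2m_c = t2m_c + cfg.delta_t_c
        precip = precip * cfg.precip_scale
        u10 = u10 * cfg.wind_scale
        v10 = v10 * cfg.wind_scale

    anomaly = t2m_c - t2m_c.mean()
    rh = np.clip(cfg.rh_base - cfg.rh_temp_slope * anomaly, 0.0, 100.0)

    return MeteoFields(t2m=t2m_c + 273.15, u10=u10, v10=v10, rh=rh,
                       precip=precip, kh=cfg.kh, kv=cfg.kv).validate(grid)


def gen_vegetation(grid: GridDomain, cfg: SynthConfig, seed: int) -> VegetationMap:
    """Patchy coverage map: Gaussian patches, hard zero elsewhere.

    At least ``min_zero_fraction`` of cells are exactly zero so long-range
    transport into uncovered areas is always exercised (the cutoff is raised
    to the required quantile if the patches would tile the whole domain).
    """
    rng = np.random.default_rng(seed)
    ny, nx = grid.ny, grid.nx
    pc = np.zeros((ny, nx))
    yy, xx = np.mgrid[0:ny, 0:nx]
    radius = max(min(ny, nx) / 6.0, 1.0)
    for _ in range(cfg.n_patches):
        cy, cx = rng.uniform(0, ny), rng.uniform(0, nx)
        amp = rng.uniform(0.3, 1.0) * cfg.coverage_max
        pc += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * radius**2))
    pc = np.clip(pc, 0.0, cfg.coverage_max)
    cutoff = 0.02 * cfg.coverage_max
    q = np.quantile(pc, cfg.min_zero_fraction)
    pc[pc <= max(cutoff, q)] = 0.0
    lai = np.where(pc > 0,
                   rng.uniform(cfg.lai_range[0], cfg.lai_range[1], size=pc.shape),
                   0.0)
    return VegetationMap(pc=pc, lai=lai).validate(grid)


def gen_regions(grid: GridDomain, n_regions: int = 9) -> RegionMask:
    """Contiguous tiling of the grid into near-equal rectangular regions."""
    if not (1 <= n_regions <= grid.nx * grid.ny):
        raise ValueError("n_regions must lie in [1, nx*ny]")
    a = int(np.sqrt(n_regions))
    while n_regions % a != 0:
        a -= 1
    b = n_regions // a
    rows, cols = (a, b) if grid.ny >= grid.nx else (b, a)
    labels = np.zeros((grid.ny, grid.nx), dtype=int)
    y_edges = np.linspace(0, grid.ny, rows + 1).astype(int)
    x_edges = np.linspace(0, grid.nx, cols + 1).astype(int)
    rid = 1
    for r in range(rows):
        for c in range(cols):
            labels[y_edges[r]:y_edges[r + 1], x_edges[c]:x_edges[c + 1]] = rid
            rid += 1
    return RegionMask(labels=labels).validate(grid)


def pick_station_cells(grid: GridDomain, n: int, seed: int,
                       coverage: np.ndarray | None = None) -> List[tuple]:
    """n distinct station cells, preferring vegetated cells when a map is given."""
    rng = np.random.default_rng(seed)
    cells = [(i, j) for j in range(grid.ny) for i in range(grid.nx)]
    if coverage is not None:
        veg_cells = [(i, j) for (i, j) in cells if coverage[j, i] > 0]
        if len(veg_cells) >= n:
            cells = veg_cells
    idx = rng.choice(len(cells), size=min(n, len(cells)), replace=False)
    return [cells[k] for k in idx]


def gen_observations(sim_surface: np.ndarray, grid: GridDomain,
                     station_cells: Sequence[tuple], seed: int,
                     noise_sd: float = 0.5,
                     days_per_week: int = 3) -> List[StationSeries]:
    """Noisy, intermittently sampled station series from the simulated truth.

    Daily means of the layer-1 truth at each station cell, multiplied by
    lognormal noise with median 1 (``exp(N(0, noise_sd))``); only
    ``days_per_week`` weekdays per week are retained. ``noise_sd=0`` with
    ``days_per_week=7`` reproduces the truth exactly.
    """
    if not (1 <= days_per_week <= 7):
        raise ValueError("days_per_week must lie in 1..7")
    rng = np.random.default_rng(seed)
    times = grid.times
    keep_weekdays = set(range(days_per_week))  # fixed weekday schedule
    out = []
    for k, (i, j) in enumerate(station_cells):
        if not (0 <= i < grid.nx and 0 <= j < grid.ny):
            raise ValueError(f"station cell ({i}, {j}) outside domain")
        hourly = pd.Series(sim_surface[:, j, i], index=times)
        counts = hourly.resample("D").count()
        daily = hourly.resample("D").mean()[counts == 24]
        if noise_sd > 0:
            noise = np.exp(rng.normal(0.0, noise_sd, size=len(daily)))
        else:
            noise = np.ones(len(daily))
        vals = daily.values * noise
        sampled = pd.Series(
            np.where([d.weekday() in keep_weekdays for d in daily.index],
                     vals, np.nan),
            index=daily.index,
        )
        out.append(StationSeries(station_id=f"ST{k:03d}", i=i, j=j,
                                 series=sampled).validate(grid))
    return out
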