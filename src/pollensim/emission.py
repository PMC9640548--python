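"""Pollen emission fluxes.

The per-unit-area hourly flux from plant-covered ground is

    F_e = q_p * L_d * L_h * (K_e*LAI + C_r*K_r*(1+LAI)) / (1 + v_d*(1+LAI)/u*)

with q_p the annual total emission flux (grains m^-2 yr^-1), L_d/L_h the
daily and hourly flowering likelihoods, K_e/K_r lumped meteorology adjustment
factors for direct emission and resuspension, C_r the resuspension
proportionality factor, LAI the leaf area index, v_d the deposition velocity
(gravitational settling for coarse pollen) and u* the friction velocity.
The grid-cell emission rate is F_g = F_e * S_g * P_c with S_g the cell area
and P_c the fractional plant coverage; the flux is injected entirely into
the first model layer (0-60 m by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grid import GridDomain, MeteoFields, VegetationMap
from .phenology import (PhenologyParams, daily_release_curve, diurnal_profile,
                        growing_degree_days, onset_day)

KAPPA = 0.4           # von Karman constant
G = 9.81              # m s^-2
MU_AIR = 1.81e-5      # dynamic viscosity of air, Pa s
RHO_AIR = 1.2         # kg m^-3
USTAR_FLOOR = 0.01    # m s^-1, keeps Eq. 2's denominator finite in calm air


@dataclass(frozen=True)
class MetAdjustSet:
    """One clamped linear meteorology response (used for both K_e and K_r).

    K = clamp(1 + a_t*(T - t_ref) + a_w*(W - w_ref) - a_rh*(RH - rh_ref)),
    non-decreasing in temperature and wind, non-increasing in humidity.
    """

    t_ref: float = 15.0    # deg C
    a_t: float = 0.05      # per deg C
    w_ref: float = 3.0     # m s^-1
    a_w: float = 0.05      # per m s^-1
    rh_ref: float = 60.0   # %
    a_rh: float = 0.01     # per %
    k_min: float = 0.0
    k_max: float = 2.0

    def __post_init__(self):
        if self.k_min < 0 or self.k_min > self.k_max:
            raise ValueError("need 0 <= k_min <= k_max")


@dataclass(frozen=True)
class MetAdjustParams:
    """Parameter sets for the two adjustment factors plus roughness length."""

    ke: MetAdjustSet = field(default_factory=MetAdjustSet)
    # resuspension is driven mainly by wind
    kr: MetAdjustSet = field(default_factory=lambda: MetAdjustSet(a_t=0.02, a_w=0.15))
    z0: float = 0.5  # m, roughness length for the neutral log wind profile

    def __post_init__(self):
        if not (0 < self.z0 < 10):
            raise ValueError("roughness length z0 must lie in (0, 10) m")


@dataclass(frozen=True)
class TaxonParams:
    """Per-species constants.

    Grain diameters, clinical thresholds, verification levels and season
    windows follow the published oak/ragweed configuration; annual
    production q_p and the resuspension factor C_r are model parameters.
    """

    name: str
    q_p: float                      # grains m^-2 yr^-1 of plant-covered area
    c_r: float = 0.1                # resuspension proportionality factor
    d_p: float = 28.0               # grain diameter, um
    rho_p: float = 1000.0           # grain density, kg m^-3
    clinical_threshold: float = 13.0  # grains m^-3
    verification_levels: tuple = (10.0, 50.0, 100.0)
    season_window: tuple = ((3, 1), (4, 30))  # ((month, day), (month, day))
    phenology: PhenologyParams = field(default_factory=PhenologyParams)
    sigma_g: float = 2.2            # coarse-mode geometric sd (metadata only)

    def __post_init__(self):
        if self.q_p <= 0 or self.d_p <= 0 or self.rho_p <= 0:
            raise ValueError("q_p, d_p, rho_p must be positive")
        if self.clinical_threshold <= 0 or any(v <= 0 for v in self.verification_levels):
            raise ValueError("thresholds must be positive")


def oak_params(**overrides) -> TaxonParams:
    """Oak: spring-flowering tree, 28 um grains, 13 grains/m^3 threshold."""
    base = TaxonParams(
        name="oak", q_p=1e8, d_p=28.0, clinical_threshold=13.0,
        season_window=((3, 1), (4, 30)),
        phenology=PhenologyParams(t_base=5.0, gdd_onset=100.0, season_spread=7.0,
                                  peak_offset=10.0, diurnal_peak_hour=11.0),
    )
    return replace(base, **overrides) if overrides else base


def ragweed_params(**overrides) -> TaxonParams:
    """Ragweed: late-summer weed, 18 um grains, 30 grains/m^3 threshold."""
    base = TaxonParams(
        name="ragweed", q_p=4e8, d_p=18.0, clinical_threshold=30.0,
        season_window=((8, 1), (9, 30)),
        phenology=PhenologyParams(t_base=10.0, gdd_onset=450.0, season_spread=10.0,
                                  peak_offset=15.0, diurnal_peak_hour=14.0),
    )
    return replace(base, **overrides) if overrides else base


TAXA = {"oak": oak_params, "ragweed": ragweed_params}


def met_adjust_factor(t, w, rh, p: MetAdjustSet):
    """Lumped meteorology adjustment factor K (dimensionless, clamped)."""
    k = (1.0 + p.a_t * (np.asarray(t, dtype=float) - p.t_ref)
         + p.a_w * (np.asarray(w, dtype=float) - p.w_ref)
         - p.a_rh * (np.asarray(rh, dtype=float) - p.rh_ref))
    return np.clip(k, p.k_min, p.k_max)


def friction_velocity(w10, z0: float):
    """Neutral log-law friction velocity u* = kappa*W10/ln(10/z0), floored."""
    if not (0 < z0 < 10):
        raise ValueError("z0 must lie in (0, 10) m")
    w10 = np.asarray(w10, dtype=float)
    if np.any(w10 < 0):
        raise ValueError("wind speed must be non-negative")
    ustar = KAPPA * w10 / np.log(10.0 / z0)
    return np.maximum(ustar, USTAR_FLOOR)


def settling_velocity(d_p_um: float, rho_p: float = 1000.0,
                      mu_air: float = MU_AIR, rho_air: float = RHO_AIR) -> float:
    """Stokes terminal settling velocity (m/s) for a d_p micrometre sphere.

    Valid in the Stokes regime; the particle Reynolds number is checked and
    diameters above 100 um are rejected.
    """
    if d_p_um > 100.0:
        raise ValueError("Stokes settling only supported for d_p <= 100 um")
    d = d_p_um * 1e-6
    v_s = rho_p * G * d * d / (18.0 * mu_air)
    reynolds = rho_air * v_s * d / mu_air
    if reynolds >= 1.0:
        raise ValueError(f"particle Reynolds number {reynolds:.2f} outside Stokes regime")
    return v_s


def unit_emission_flux(q_p, l_d, l_h, k_e, k_r, c_r, lai, v_d, ustar):
    """F_e (grains m^-2 h^-1) from plant-covered ground."""
    ustar = np.asarray(ustar, dtype=float)
    if np.any(ustar <= 0):
        raise ValueError("u* must be positive (the calm-air floor prevents zero)")
    canopy = k_e * np.asarray(lai, dtype=float) + c_r * k_r * (1.0 + np.asarray(lai))
    denom = 1.0 + v_d * (1.0 + np.asarray(lai)) / ustar
    return q_p * np.asarray(l_d) * np.asarray(l_h) * canopy / denom


def grid_emission(f_e, grid: GridDomain, p_c):
    """Scale the unit flux to the cell: returns (F_g, layer-1 tendency).

    F_g = F_e * S_g * P_c (grains per hour per cell); the tendency is the
    layer-1 concentration increase rate F_e*P_c/h1 (grains m^-3 h^-1),
    zero in all other layers.
    """
    p_c = np.asarray(p_c, dtype=float)
    if np.any(p_c < 0) or np.any(p_c > 1):
        raise ValueError("coverage fraction must lie in [0, 1]")
    f_e = np.asarray(f_e, dtype=float)
    f_g = f_e * grid.cell_area * p_c
    tendency = f_e * p_c / grid.layer_thickness[0]
    return f_g, tendency


def season_mask(grid: GridDomain, taxon: TaxonParams) -> np.ndarray:
    """Boolean mask over simulated days inside the taxon's season window."""
    days = grid.times[::24][:grid.n_days].normalize()
    (m0, d0), (m1, d1) = taxon.season_window
    md = list(zip(days.month, days.day))
    return np.array([(m0, d0) <= t <= (m1, d1) for t in md])


def emission_field(grid: GridDomain, met: MeteoFields, veg: VegetationMap,
                   met_adjust: MetAdjustParams, taxon: TaxonParams):
    """Hourly emission maps for a full run.

    Composes growing-degree-day onset, the daily and diurnal flowering
    likelihoods, the K_e/K_r meteorology factors, friction velocity and the
    Stokes deposition velocity into F_e, then scales by coverage to the
    layer-1 concentration tendency. Deterministic given its inputs.

    Returns
    -------
    tendency : ndarray (n_hours, ny, nx)
        Layer-1 concentration tendency, grains m^-3 h^-1.
    f_e : ndarray (n_hours, ny, nx)
        Unit-area flux, grains m^-2 h^-1.
    onset : ndarray (ny, nx)
        Per-cell onset day index (-1 where the GDD threshold is not crossed).
    """
    met.validate(grid)
    veg.validate(grid)
    n_days = grid.n_days
    if n_days < 1:
        raise ValueError("simulation shorter than one full day")
    nh = n_days * 24

    t2m_c = met.t2m[:nh] - 273.15
    t_daily = t2m_c.reshape(n_days, 24, grid.ny, grid.nx).mean(axis=1)
    p_daily = met.precip[:nh].reshape(n_days, 24, grid.ny, grid.nx).sum(axis=1)

    phen = taxon.phenology
    gdd = growing_degree_days(t_daily, phen.t_base)
    onset = onset_day(gdd, phen.gdd_onset)

    in_season = season_mask(grid, taxon)
    l_d = daily_release_curve(n_days, onset, phen, p_daily=p_daily)
    l_d *= in_season[:, None, None]
    l_h24 = diurnal_profile(phen)

    w = np.hypot(met.u10[:nh], met.v10[:nh])
    k_e = met_adjust_factor(t2m_c, w, met.rh[:nh], met_adjust.ke)
    k_r = met_adjust_factor(t2m_c, w, met.rh[:nh], met_adjust.kr)
    ustar = (met.ustar[:nh] if met.ustar is not None
             else friction_velocity(w, met_adjust.z0))
    v_d = settling_velocity(taxon.d_p, taxon.rho_p)

    day_idx = np.arange(nh) // 24
    hod = (np.arange(nh) + grid.t0.hour) % 24
    l_dh = l_d[day_idx] * l_h24[hod][:, None, None]

    f_e = unit_emission_flux(taxon.q_p, l_dh, 1.0, k_e, k_r, taxon.c_r,
                             veg.lai, v_d, ustar)
    if nh < grid.n_hours:  # trailing partial day: no phenology defined, no release
        pad = np.zeros((grid.n_hours - nh, grid.ny, grid.nx))
        f_e = np.concatenate([f_e, pad], axis=0)
    _, tendency = grid_emission(f_e, grid, veg.pc)
    return tendency, f_e, onset
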