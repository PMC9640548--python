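"""Flowering phenology: season onset and daily/hourly flowering likelihoods.

The daily likelihood L_d is the fraction of a taxon's annual pollen release
that occurs on a given day; the hourly likelihood L_h is the fraction of a
day's release in a given hour. Onset is triggered when cumulative growing
degree days cross a threshold, so a warmer spring moves the season earlier —
the mechanism through which temperature changes shift season timing. Release
is spread around onset + peak_offset as a Gaussian in time, normalized to
unit seasonal sum in the absence of rain; precipitation suppresses release
and the suppressed fraction is lost, not redistributed (rained-out pollen is
never airborne).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PhenologyParams:
    """Tunable phenology constants.

    t_base : base temperature for growing degree days (deg C)
    gdd_onset : cumulative degree-day threshold for season start (deg C day)
    season_spread : standard deviation of the daily release curve (days)
    peak_offset : days from onset to peak release
    diurnal_peak_hour : hour of maximum hourly release (0-23)
    diurnal_width : standard deviation of the diurnal release curve (hours)
    precip_suppression : fractional reduction of L_d per mm of daily rain
    """

    t_base: float = 5.0
    gdd_onset: float = 100.0
    season_spread: float = 7.0
    peak_offset: float = 10.0
    diurnal_peak_hour: float = 11.0
    diurnal_width: float = 3.0
    precip_suppression: float = 0.05

    def __post_init__(self):
        if self.season_spread <= 0:
            raise ValueError("season_spread must be positive")
        if self.diurnal_width <= 0:
            raise ValueError("diurnal_width must be positive")
        if self.precip_suppression < 0:
            raise ValueError("precip_suppression must be non-negative")


def growing_degree_days(t_daily: np.ndarray, t_base: float) -> np.ndarray:
    """Cumulative growing degree days along axis 0.

    GDD_t = sum_{s<=t} max(T_s - t_base, 0); non-decreasing by construction.
    """
    t_daily = np.asarray(t_daily, dtype=float)
    if t_daily.size == 0:
        raise ValueError("empty temperature series")
    return np.cumsum(np.maximum(t_daily - t_base, 0.0), axis=0)


def onset_day(gdd: np.ndarray, gdd_onset: float) -> np.ndarray:
    """First day index where cumulative GDD >= threshold; -1 if never reached."""
    gdd = np.asarray(gdd, dtype=float)
    crossed = gdd >= gdd_onset
    idx = np.argmax(crossed, axis=0).astype(int)
    never = ~crossed.any(axis=0)
    idx = np.where(never, -1, idx)
    return idx


def daily_release_curve(n_days: int, onset: np.ndarray,
                        params: PhenologyParams,
                        p_daily: np.ndarray | None = None) -> np.ndarray:
    """L_d for every simulated day; shape (n_days,) + onset.shape.

    Gaussian in time around onset + peak_offset, normalized so the no-rain
    seasonal sum over the n_days window is 1, then multiplied by the rain
    suppression factor max(0, 1 - precip_suppression * P_daily). Cells with
    onset < 0 (threshold never crossed) release nothing.
    """
    onset = np.asarray(onset)
    days = np.arange(n_days, dtype=float).reshape((n_days,) + (1,) * onset.ndim)
    mu = onset + params.peak_offset
    g = np.exp(-0.5 * ((days - mu) / params.season_spread) ** 2)
    norm = g.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ld = np.where(norm > 0, g / norm, 0.0)
    ld = np.where(onset < 0, 0.0, ld)
    if p_daily is not None:
        p_daily = np.asarray(p_daily, dtype=float)
        supp = np.maximum(0.0, 1.0 - params.precip_suppression * p_daily)
        ld = ld * supp
    return ld


def daily_flowering_likelihood(day_index, onset, params: PhenologyParams,
                               p_daily: float = 0.0, n_days: int | None = None):
    """L_d for one day (scalar interface over :func:`daily_release_curve`).

    ``n_days`` sets the normalization window; defaults to a window long
    enough (onset + peak_offset + 8 sigma) to carry essentially all mass.
    """
    if n_days is None:
        n_days = int(np.max(onset) + params.peak_offset
                     + 8 * params.season_spread) + 1
    curve = daily_release_curve(n_days, np.asarray(onset), params)
    ld = curve[int(day_index)]
    return ld * max(0.0, 1.0 - params.precip_suppression * p_daily)


def hourly_flowering_likelihood(hour_of_day, params: PhenologyParams) -> np.ndarray:
    """L_h: single-peaked circular (wrapped-Gaussian) diurnal profile.

    Sums to 1 over the 24 hours of a day; flat (1/24) in the wide-width
    limit.
    """
    profile = diurnal_profile(params)
    return profile[np.asarray(hour_of_day, dtype=int)]


def diurnal_profile(params: PhenologyParams) -> np.ndarray:
    """The full 24-value L_h profile (sums to exactly 1)."""
    hours = np.arange(24.0)
    # wrap enough periods for wide profiles to converge to uniform
    ks = np.arange(-5, 6) * 24.0
    d = hours[:, None] - params.diurnal_peak_hour + ks[None, :]
    w = np.exp(-0.5 * (d / params.diurnal_width) ** 2).sum(axis=1)
    return w / w.sum()
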