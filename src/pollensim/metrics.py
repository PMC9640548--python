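"""Pollen-season indices, model-vs-observation statistics, scenario deltas.

Five season indices per cell/station: mean hourly concentration, maximum
hourly concentration, season start date, season length and exceedance hours
above the taxon's clinical threshold. Evaluation against daily station
counts uses fractional bias FB = 2(S-O)/(S+O), hit/false rates at fixed
verification levels and Pearson correlation of normalized seasonal means.
Scenario comparison reports per-region mean +/- sd of the historic-to-future
changes in the five indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grid import GridDomain, RegionMask, StationSeries
from .emission import TaxonParams, season_mask


# ---------------------------------------------------------------------------
# elementary operations

def daily_mean(hourly: pd.Series) -> pd.Series:
    """Daily arithmetic means of an hourly series; incomplete days dropped.

    A day enters only with all 24 hourly values present (UTC days).
    """
    counts = hourly.resample("D").count()
    means = hourly.resample("D").mean()
    return means[counts == 24]


def season_bounds(daily: np.ndarray, q_lo: float = 0.025, q_hi: float = 0.975):
    """Season start/end as cumulative-sum quantiles of the daily series.

    start = first day with cumulative sum >= q_lo * total,
    end   = first day with cumulative sum >= q_hi * total,
    length = end - start + 1 (scale-invariant).
    """
    daily = np.asarray(daily, dtype=float)
    total = daily.sum()
    if total <= 0:
        raise ValueError("season undefined: daily series sums to zero")
    cum = np.cumsum(daily)
    start = int(np.searchsorted(cum, q_lo * total))
    end = int(np.searchsorted(cum, q_hi * total))
    return start, end, end - start + 1


def exceedance_hours(hourly: np.ndarray, threshold: float) -> int:
    """Hours with concentration strictly above the clinical threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return int((np.asarray(hourly, dtype=float) > threshold).sum())


def normalize(values: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, sample (ddof=1) standard deviation 1."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values to normalize")
    s = values.std(ddof=1)
    if s == 0:
        raise ValueError("cannot normalize a constant vector")
    return (values - values.mean()) / s


def pearson_with_p(x, y):
    """Pearson r with a two-sided p-value from the t-transform (n-2 dof)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least three paired values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def fractional_bias(sc_sim: float, sc_obs: float) -> float:
    """FB = 2(S-O)/(S+O), bounded in [-2, 2]; positive = overestimation."""
    if sc_sim < 0 or sc_obs < 0:
        raise ValueError("seasonal counts must be non-negative")
    denom = sc_sim + sc_obs
    if denom == 0:
        raise ValueError("fractional bias undefined for two zero counts")
    return 2.0 * (sc_sim - sc_obs) / denom


def hit_false_rates(sim_daily: np.ndarray, obs_daily: np.ndarray, level: float):
    """Exceedance verification over paired days (exceedance: value >= level).

    hit rate  = TP / (TP + FN)  (probability of detection),
    false rate = FP / (TP + FP) (false-alarm ratio);
    each is NaN when its denominator is zero. Days with missing observations
    are excluded pairwise.
    """
    sim = np.asarray(sim_daily, dtype=float)
    obs = np.asarray(obs_daily, dtype=float)
    paired = np.isfinite(sim) & np.isfinite(obs)
    if not paired.any():
        raise ValueError("no paired days")
    s = sim[paired] >= level
    o = obs[paired] >= level
    tp = int((s & o).sum())
    fp = int((s & ~o).sum())
    fn = int((~s & o).sum())
    hit = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    false = fp / (tp + fp) if (tp + fp) > 0 else float("nan")
    return hit, false


# ---------------------------------------------------------------------------
# season metrics

@dataclass
class SeasonMetrics:
    mean_hourly: float       # grains m^-3 over the season window
    max_hourly: float
    start_day: int           # day-of-year
    season_length: int       # days
    exceedance_hours: int
    defined: bool = True


def season_metrics(hourly: pd.Series, taxon: TaxonParams) -> SeasonMetrics:
    """The five indices for one cell/station from its hourly series.

    The series is restricted to the taxon's season window; an all-zero
    series yields ``defined=False`` (such cells are excluded from maps and
    regional statistics, as are cells without plant coverage).
    """
    idx = pd.DatetimeIndex(hourly.index)
    (m0, d0), (m1, d1) = taxon.season_window
    md = list(zip(idx.month, idx.day))
    in_win = np.array([(m0, d0) <= t <= (m1, d1) for t in md])
    windowed = hourly[in_win]
    if len(windowed) == 0 or float(windowed.sum()) <= 0:
        return SeasonMetrics(0.0, 0.0, -1, 0, 0, defined=False)
    daily = daily_mean(windowed)
    start_i, end_i, length = season_bounds(daily.values)
    start_doy = int(pd.Timestamp(daily.index[start_i]).dayofyear)
    return SeasonMetrics(
        mean_hourly=float(windowed.mean()),
        max_hourly=float(windowed.max()),
        start_day=start_doy,
        season_length=int(length),
        exceedance_hours=exceedance_hours(windowed.values, taxon.clinical_threshold),
    )


INDEX_NAMES = ("mean_hourly", "max_hourly", "start_date", "season_length",
               "exceedance_hours")


def season_metrics_grid(hourly_surface: np.ndarray, grid: GridDomain,
                        taxon: TaxonParams,
                        coverage: Optional[np.ndarray] = None) -> dict:
    """Vectorized five-index maps from the layer-1 history (n_hours, ny, nx).

    Returns a dict of (ny, nx) arrays plus a boolean ``defined`` mask
    (coverage > 0 where a coverage map is given, and a nonzero season).
    """
    hourly = np.asarray(hourly_surface, dtype=float)
    in_win = np.repeat(season_mask(grid, taxon), 24)
    nh = len(in_win)
    win = hourly[:nh][in_win]                     # (n_win_hours, ny, nx)
    if win.shape[0] == 0:
        raise ValueError("season window does not intersect the simulation")
    n_win_days = win.shape[0] // 24
    daily = win[:n_win_days * 24].reshape(n_win_days, 24, grid.ny, grid.nx).mean(axis=1)
    total = daily.sum(axis=0)
    defined = total > 0
    if coverage is not None:
        defined &= np.asarray(coverage) > 0

    cum = np.cumsum(daily, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        start_i = (cum >= 0.025 * total).argmax(axis=0)
        end_i = (cum >= 0.975 * total).argmax(axis=0)
    win_days = grid.times[::24][:grid.n_days][season_mask(grid, taxon)]
    doy0 = np.asarray(win_days.dayofyear)
    out = {
        "mean_hourly": win.mean(axis=0),
        "max_hourly": win.max(axis=0),
        "start_date": np.where(defined, doy0[np.clip(start_i, 0, len(doy0) - 1)], -1),
        "season_length": np.where(defined, end_i - start_i + 1, 0),
        "exceedance_hours": (win > taxon.clinical_threshold).sum(axis=0),
        "defined": defined,
    }
    return out


# ---------------------------------------------------------------------------
# scenario comparison

def scenario_delta(hist: dict, fut: dict, regions: RegionMask) -> pd.DataFrame:
    """Tables-style regional mean +/- sd of historic-to-future changes.

    Percentage deltas 100*(fut-hist)/hist for mean/max/exceedance (cells
    with zero or undefined historic value excluded); day deltas fut-hist for
    start date and season length. Unweighted sample statistics per region;
    regions with no included cells are flagged with NaN.
    """
    included = hist["defined"] & fut["defined"]
    deltas = {}
    for name in ("mean_hourly", "max_hourly", "exceedance_hours"):
        h = hist[name].astype(float)
        f = fut[name].astype(float)
        ok = included & (h > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 100.0 * (f - h) / h
        deltas[name + "_pct"] = (d, ok)
    for name in ("start_date", "season_length"):
        d = fut[name].astype(float) - hist[name].astype(float)
        deltas[name + "_day"] = (d, included)

    rows = []
    for rid in regions.region_ids:
        in_region = regions.labels == rid
        row = {"region": int(rid)}
        for col, (d, ok) in deltas.items():
            sel = d[in_region & ok]
            if sel.size == 0:
                row[f"{col}_mean"], row[f"{col}_sd"] = np.nan, np.nan
            else:
                row[f"{col}_mean"] = float(sel.mean())
                row[f"{col}_sd"] = float(sel.std(ddof=1)) if sel.size > 1 else 0.0
            row[f"{col}_n"] = int(sel.size)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# evaluation against stations

@dataclass
class EvaluationReport:
    stations: pd.DataFrame   # per-station FB, hit/false per level, n_days
    pearson_r: float         # pooled normalized seasonal means
    pearson_p: float
    n_stations: int

    def to_csv(self, path) -> None:
        self.stations.to_csv(path, index=False)


def evaluate_stations(sim_surface: np.ndarray, grid: GridDomain,
                      observations: List[StationSeries],
                      levels: Sequence[float] = (10.0, 50.0, 100.0)) -> EvaluationReport:
    """Model-vs-observation statistics at monitoring stations.

    Simulated daily means in each station's grid cell (layer 1) are paired
    with the station's observed days only; seasonal counts (sums of daily
    concentration over paired days) feed the fractional bias, daily pairs
    feed the hit/false rates, and seasonal mean concentrations across
    stations feed the normalized Pearson correlation.
    """
    times = grid.times
    rows = []
    sim_means, obs_means = [], []
    for st in observations:
        st.validate(grid)
        sim_hourly = pd.Series(sim_surface[:, st.j, st.i], index=times)
        sim_daily = daily_mean(sim_hourly)
        obs = st.series.dropna()
        paired = sim_daily.index.intersection(pd.DatetimeIndex(obs.index).normalize())
        if len(paired) == 0:
            continue
        s = sim_daily.loc[paired].values
        o = obs.loc[paired].values
        row = {"station_id": st.station_id, "n_days": len(paired)}
        sc_sim, sc_obs = float(s.sum()), float(o.sum())
        row["fb"] = (fractional_bias(sc_sim, sc_obs)
                     if (sc_sim + sc_obs) > 0 else np.nan)
        for lev in levels:
            hit, false = hit_false_rates(s, o, lev)
            row[f"hit_rate_{lev:g}"] = hit
            row[f"false_rate_{lev:g}"] = false
        rows.append(row)
        sim_means.append(s.mean())
        obs_means.append(o.mean())

    if not rows:
        raise ValueError("no stations with paired observation days")
    df = pd.DataFrame(rows)
    if len(sim_means) >= 3 and np.std(sim_means) > 0 and np.std(obs_means) > 0:
        r, p = pearson_with_p(normalize(np.array(sim_means)),
                              normalize(np.array(obs_means)))
    else:
        r, p = np.nan, np.nan
    return EvaluationReport(stations=df, pearson_r=r, pearson_p=p,
                            n_stations=len(df))
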