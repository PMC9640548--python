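"""NetCDF / CSV input-output.

Gridded fields travel as CF-style NetCDF (dimensions time/z/y/x, ``units``
attributes required on every variable); stations as CSV with columns
``station_id, x_m, y_m`` (or ``i, j``), ``date`` (ISO-8601) and
``concentration_grains_m3`` (empty = missing). Files are written with
xarray's scipy backend (NetCDF3 classic), which round-trips float64 arrays
and attributes losslessly.
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridDomain, MeteoFields, RegionMask, StationSeries, VegetationMap

_ENGINE = "scipy"

_METEO_UNITS = {
    "t2m": "K", "u10": "m s-1", "v10": "m s-1", "rh": "%",
    "precip": "mm h-1", "kh": "m2 s-1", "kv": "m2 s-1",
    "u": "m s-1", "v": "m s-1", "w": "m s-1",
}


def _grid_attrs(grid: GridDomain) -> dict:
    return {
        "dx": grid.dx,
        "dy": grid.dy,
        "layer_tops": list(grid.layer_tops),
        "t0": grid.t0.isoformat(),
        "n_hours": grid.n_hours,
    }


def grid_from_attrs(attrs: dict, ny: int, nx: int) -> GridDomain:
    tops = tuple(np.atleast_1d(attrs["layer_tops"]).tolist())
    return GridDomain(
        nx=nx, ny=ny, nz=len(tops), dx=float(attrs["dx"]), dy=float(attrs["dy"]),
        layer_tops=tops, t0=datetime.fromisoformat(str(attrs["t0"])),
        n_hours=int(attrs["n_hours"]),
    )


def write_meteo(path, met: MeteoFields, grid: GridDomain) -> None:
    met.validate(grid)
    data = {}
    for name in ("t2m", "u10", "v10", "rh", "precip"):
        data[name] = (("time", "y", "x"), getattr(met, name),
                      {"units": _METEO_UNITS[name]})
    for name in ("kh", "kv"):
        a = getattr(met, name)
        if np.ndim(a) == 0:
            data[name] = ((), float(a), {"units": _METEO_UNITS[name]})
        else:
            data[name] = (("time", "z", "y", "x"), a, {"units": _METEO_UNITS[name]})
    for name in ("u", "v", "w"):
        a = getattr(met, name)
        if a is not None:
            data[name] = (("time", "z", "y", "x"), a, {"units": _METEO_UNITS[name]})
    ds = xr.Dataset(data, attrs=_grid_attrs(grid))
    ds.to_netcdf(path, engine=_ENGINE)


def read_meteo(path, grid: GridDomain | None = None) -> tuple:
    """Read meteorology; returns (MeteoFields, GridDomain)."""
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    required = ("t2m", "u10", "v10", "rh", "precip")
    for name in required + ("kh", "kv"):
        if name not in ds:
            raise ValueError(f"meteorology file missing required variable '{name}'")
        if "units" not in ds[name].attrs:
            raise ValueError(f"variable '{name}' missing units attribute")
    g = grid_from_attrs(ds.attrs, ds.sizes["y"], ds.sizes["x"])
    if grid is not None and (g.shape3d != grid.shape3d or g.n_hours != grid.n_hours):
        raise ValueError("meteorology file does not conform to the given grid")
    kwargs = {name: ds[name].values for name in required}
    for name in ("kh", "kv"):
        v = ds[name].values
        kwargs[name] = float(v) if v.ndim == 0 else v
    for name in ("u", "v", "w"):
        if name in ds:
            kwargs[name] = ds[name].values
    met = MeteoFields(**kwargs).validate(grid or g)
    return met, g


def write_vegetation(path, veg: VegetationMap, grid: GridDomain,
                     taxon: str = "") -> None:
    veg.validate(grid)
    ds = xr.Dataset(
        {
            "pc": (("y", "x"), veg.pc, {"units": "1", "long_name": "coverage fraction"}),
            "lai": (("y", "x"), veg.lai, {"units": "1", "long_name": "leaf area index"}),
        },
        attrs={**_grid_attrs(grid), "taxon": taxon},
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_vegetation(path, grid: GridDomain) -> VegetationMap:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    for name in ("pc", "lai"):
        if name not in ds:
            raise ValueError(f"vegetation file missing required variable '{name}'")
    return VegetationMap(pc=ds["pc"].values, lai=ds["lai"].values).validate(grid)


def write_regions(path, regions: RegionMask, grid: GridDomain) -> None:
    regions.validate(grid)
    ds = xr.Dataset(
        {"region": (("y", "x"), regions.labels.astype("int32"), {"units": "1"})},
        attrs=_grid_attrs(grid),
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_regions(path, grid: GridDomain) -> RegionMask:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    if "region" not in ds:
        raise ValueError("regions file missing required variable 'region'")
    return RegionMask(labels=ds["region"].values.astype(int)).validate(grid)


def write_concentration(path, history: np.ndarray, grid: GridDomain,
                        dry_dep: np.ndarray | None = None,
                        wet_dep: np.ndarray | None = None) -> None:
    """Write an hourly concentration history (time, z, y, x) plus deposition maps."""
    data = {
        "conc": (("time", "z", "y", "x"), np.asarray(history, dtype=float),
                 {"units": "grains m-3"}),
    }
    if dry_dep is not None:
        data["dry_dep"] = (("y", "x"), np.asarray(dry_dep, dtype=float),
                          {"units": "grains m-2"})
    if wet_dep is not None:
        data["wet_dep"] = (("y", "x"), np.asarray(wet_dep, dtype=float),
                          {"units": "grains m-2"})
    xr.Dataset(data, attrs=_grid_attrs(grid)).to_netcdf(path, engine=_ENGINE)


def read_concentration(path) -> tuple:
    """Returns (history array, dry_dep or None, wet_dep or None, GridDomain)."""
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    if "conc" not in ds:
        raise ValueError("concentration file missing required variable 'conc'")
    g = grid_from_attrs(ds.attrs, ds.sizes["y"], ds.sizes["x"])
    dry = ds["dry_dep"].values if "dry_dep" in ds else None
    wet = ds["wet_dep"].values if "wet_dep" in ds else None
    return ds["conc"].values, dry, wet, g


def write_stations(path, stations: List[StationSeries], grid: GridDomain) -> None:
    rows = []
    for st in stations:
        st.validate(grid)
        for date, val in st.series.items():
            rows.append({
                "station_id": st.station_id,
                "i": st.i,
                "j": st.j,
                "date": pd.Timestamp(date).date().isoformat(),
                "concentration_grains_m3": "" if pd.isna(val) else val,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_stations(path, grid: GridDomain) -> List[StationSeries]:
    df = pd.read_csv(path, dtype={"station_id": str})
    if df.empty:
        raise ValueError(f"station file {path} is empty")
    required = {"station_id", "date", "concentration_grains_m3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"station file missing columns: {sorted(missing)}")
    if not {"i", "j"} <= set(df.columns):
        if not {"x_m", "y_m"} <= set(df.columns):
            raise ValueError("station file needs either (i, j) or (x_m, y_m) columns")
        from .grid import locate_station
        ij = [locate_station(grid, x, y) for x, y in zip(df["x_m"], df["y_m"])]
        df["i"] = [p[0] for p in ij]
        df["j"] = [p[1] for p in ij]
    df["date"] = pd.to_datetime(df["date"])
    out = []
    for sid, sub in df.groupby("station_id", sort=True):
        series = pd.Series(
            pd.to_numeric(sub["concentration_grains_m3"], errors="coerce").values,
            index=pd.DatetimeIndex(sub["date"]),
            name=sid,
        ).sort_index()
        out.append(StationSeries(station_id=str(sid), i=int(sub["i"].iloc[0]),
                                 j=int(sub["j"].iloc[0]), series=series).validate(grid))
    return out


def write_manifest(path, config_dict: dict, seed: int) -> None:
    """Run manifest: enough to reproduce the run byte-for-byte."""
    import hashlib
    blob = json.dumps(config_dict, sort_keys=True, default=str)
    manifest = {
        "seed": seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
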