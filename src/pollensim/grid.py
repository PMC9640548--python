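"""Grid/time discretization and the gridded data model shared by all modules.

Conventions (used everywhere in the package):

* 0-based cell indices, cell-centered values, half-open intervals in space
  ``[i*dx, (i+1)*dx)`` and time.
* Array axis order is ``(z, y, x)`` for 3-D fields and ``(time, ...)`` for
  histories; surface fields are ``(y, x)``.
* Timestamps are UTC, output is hourly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Optional, Union

import numpy as np
import pandas as pd

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class GridDomain:
    """Geometry and time axis of a simulation.

    Parameters
    ----------
    nx, ny : int
        Horizontal cell counts (x = first horizontal direction).
    nz : int
        Number of vertical layers.
    dx, dy : float
        Horizontal cell edge lengths in metres (default 36 km).
    layer_tops : tuple of float
        Heights of layer tops above ground (m), strictly increasing; the
        first layer spans 0..layer_tops[0] (default top 60 m, where
        emissions are injected).
    t0 : datetime
        Start of the simulation (UTC).
    n_hours : int
        Number of hourly steps.
    """

    nx: int
    ny: int
    nz: int
    dx: float = 36_000.0
    dy: float = 36_000.0
    layer_tops: tuple = (60.0,)
    t0: datetime = field(
        default_factory=lambda: datetime(2004, 3, 1, tzinfo=timezone.utc)
    )
    n_hours: int = 24
    dt_out: float = 3600.0  # output interval (s), fixed at 1 h

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1 or self.nz < 1:
            raise ValueError("nx, ny, nz must all be >= 1")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("dx and dy must be positive")
        tops = np.asarray(self.layer_tops, dtype=float)
        if tops.size != self.nz:
            raise ValueError(f"layer_tops must have nz={self.nz} entries")
        if tops[0] <= 0 or np.any(np.diff(tops) <= 0):
            raise ValueError("layer_tops must be strictly increasing and positive")
        if self.n_hours < 1:
            raise ValueError("n_hours must be >= 1")
        if self.t0.tzinfo is None:
            object.__setattr__(self, "t0", self.t0.replace(tzinfo=timezone.utc))
        object.__setattr__(self, "layer_tops", tuple(float(t) for t in tops))

    @property
    def cell_area(self) -> float:
        """Horizontal cell area S_g = dx*dy (m^2)."""
        return self.dx * self.dy

    @property
    def layer_thickness(self) -> np.ndarray:
        """Layer thicknesses (m), shape (nz,)."""
        tops = np.asarray(self.layer_tops)
        return np.diff(tops, prepend=0.0)

    @property
    def times(self) -> pd.DatetimeIndex:
        """Timestamps of the hourly output steps (start of each hour).

        Returned timezone-naive but meaning UTC, so they compare directly
        with dates parsed from station CSV files.
        """
        return pd.date_range(self.t0.replace(tzinfo=None),
                             periods=self.n_hours, freq="h")

    @property
    def n_days(self) -> int:
        return self.n_hours // 24

    @property
    def shape3d(self) -> tuple:
        return (self.nz, self.ny, self.nx)

    @property
    def shape2d(self) -> tuple:
        return (self.ny, self.nx)


def build_grid(nx, ny, nz, dx=36_000.0, dy=36_000.0, layer_tops=(60.0,),
               t0=None, n_hours=24) -> GridDomain:
    """Validated :class:`GridDomain` constructor (functional form)."""
    kwargs = dict(nx=nx, ny=ny, nz=nz, dx=dx, dy=dy,
                  layer_tops=tuple(layer_tops), n_hours=n_hours)
    if t0 is not None:
        kwargs["t0"] = t0
    return GridDomain(**kwargs)


def locate_station(grid: GridDomain, x: float, y: float) -> tuple:
    """Index (i, j) of the cell containing point (x, y) in metres.

    Cells are half-open: ``[i*dx, (i+1)*dx) x [j*dy, (j+1)*dy)``.
    """
    if not (0 <= x < grid.nx * grid.dx) or not (0 <= y < grid.ny * grid.dy):
        raise ValueError(f"point ({x}, {y}) outside domain footprint")
    return int(x // grid.dx), int(y // grid.dy)


@dataclass
class MeteoFields:
    """Hourly gridded meteorological drivers.

    Surface fields have shape ``(n_hours, ny, nx)``: 2-m temperature ``t2m``
    (K), 10-m winds ``u10``/``v10`` (m/s), relative humidity ``rh`` (%),
    precipitation rate ``precip`` (mm/h). Eddy diffusivities ``kh``/``kv``
    (m^2/s) and layer winds ``u``/``v``/``w`` may be full
    ``(n_hours, nz, ny, nx)`` arrays or scalars/None (scalar diffusivity,
    winds defaulting to the 10-m winds replicated in z and w = 0).
    """

    t2m: np.ndarray
    u10: np.ndarray
    v10: np.ndarray
    rh: np.ndarray
    precip: np.ndarray
    kh: ArrayLike = 0.0
    kv: ArrayLike = 0.0
    u: Optional[np.ndarray] = None
    v: Optional[np.ndarray] = None
    w: Optional[np.ndarray] = None
    ustar: Optional[np.ndarray] = None

    def validate(self, grid: GridDomain) -> "MeteoFields":
        surf = (grid.n_hours, grid.ny, grid.nx)
        full = (grid.n_hours, grid.nz, grid.ny, grid.nx)
        for name in ("t2m", "u10", "v10", "rh", "precip"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != surf:
                raise ValueError(f"{name} must have shape {surf}, got {a.shape}")
            setattr(self, name, a)
        if np.any(self.rh < 0) or np.any(self.rh > 100):
            raise ValueError("rh must lie in [0, 100]")
        if np.any(self.precip < 0):
            raise ValueError("precip must be non-negative")
        for name in ("kh", "kv"):
            a = getattr(self, name)
            if np.ndim(a) == 0:
                if float(a) < 0:
                    raise ValueError(f"{name} must be non-negative")
            else:
                a = np.asarray(a, dtype=float)
                if a.shape != full:
                    raise ValueError(f"{name} must be scalar or shape {full}")
                if np.any(a < 0):
                    raise ValueError(f"{name} must be non-negative")
                setattr(self, name, a)
        for name in ("u", "v", "w"):
            a = getattr(self, name)
            if a is not None and np.asarray(a).shape != full:
                raise ValueError(f"{name} must be None or shape {full}")
        return self

    def layer_wind(self, name: str, hour: int, grid: GridDomain) -> np.ndarray:
        """3-D wind component (nz, ny, nx) at a given hour.

        Falls back to the 10-m wind replicated in the vertical for u/v and
        to zero for w when no 3-D field is provided.
        """
        a = getattr(self, name)
        if a is not None:
            return np.asarray(a[hour], dtype=float)
        if name == "w":
            return np.zeros(grid.shape3d)
        surf = {"u": self.u10, "v": self.v10}[name][hour]
        return np.broadcast_to(surf, grid.shape3d).copy()

    def diffusivity(self, name: str, hour: int, grid: GridDomain) -> np.ndarray:
        a = getattr(self, name)
        if np.ndim(a) == 0:
            return np.full(grid.shape3d, float(a))
        return np.asarray(a[hour], dtype=float)


@dataclass
class VegetationMap:
    """Per-cell fractional plant coverage P_c and leaf area index."""

    pc: np.ndarray   # (ny, nx), in [0, 1]
    lai: np.ndarray  # (ny, nx), >= 0

    def validate(self, grid: GridDomain) -> "VegetationMap":
        self.pc = np.asarray(self.pc, dtype=float)
        self.lai = np.asarray(self.lai, dtype=float)
        if self.pc.shape != grid.shape2d or self.lai.shape != grid.shape2d:
            raise ValueError(f"vegetation fields must have shape {grid.shape2d}")
        if np.any(self.pc < 0) or np.any(self.pc > 1):
            raise ValueError("coverage fraction P_c must lie in [0, 1]")
        if np.any(self.lai < 0):
            raise ValueError("LAI must be non-negative")
        return self


@dataclass
class RegionMask:
    """Integer region labels per surface cell; 0 marks unlabelled cells."""

    labels: np.ndarray  # (ny, nx) int, values in {0..R}

    def validate(self, grid: GridDomain) -> "RegionMask":
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != grid.shape2d:
            raise ValueError(f"region labels must have shape {grid.shape2d}")
        if np.any(self.labels < 0):
            raise ValueError("region labels must be >= 0 (0 = missing)")
        return self

    @property
    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class StationSeries:
    """Daily mean observed concentration at one monitoring station."""

    station_id: str
    i: int
    j: int
    series: pd.Series  # date-indexed daily grains m^-3; NaN = missing

    def validate(self, grid: GridDomain) -> "StationSeries":
        if not (0 <= self.i < grid.nx and 0 <= self.j < grid.ny):
            raise ValueError(f"station {self.station_id} cell outside grid")
        vals = self.series.dropna()
        if (vals < 0).any():
            raise ValueError(f"station {self.station_id}: negative concentrations")
        days = pd.DatetimeIndex(self.series.index)
        lo = grid.times[0].normalize()
        hi = grid.times[-1].normalize()
        if len(days) and (days.min() < lo or days.max() > hi):
            raise ValueError(
                f"station {self.station_id}: dates outside simulation window"
            )
        return self
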