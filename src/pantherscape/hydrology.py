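"""Seasonal water-depth surfaces from gauge stages and ground elevation.

Water depth at a point on a day is the interpolated stage (water-surface
elevation in a common vertical datum) minus the ground elevation there;
positive values mean standing water, negative values a water table below
the surface.  Stages are interpolated between gauging stations by inverse
distance weighting (configurable power, default 2), which is exact at the
stations themselves and linear in the stage values.  Per-cell seasonal
depths average a small subgrid of sample points within the cell over every
in-season day of the averaging period.

The wet season is June–October and the dry season November–May; a dry
season therefore spans the year boundary and is labelled by its ending
year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import Grid
from .raster import AsciiGrid

logger = logging.getLogger(__name__)

WET_MONTHS = frozenset({6, 7, 8, 9, 10})
DRY_MONTHS = frozenset({11, 12, 1, 2, 3, 4, 5})


@dataclass
class GaugeSeries:
    """One gauging station: location plus a daily stage record."""

    station_id: str
    x: float
    y: float
    records: pd.Series  # index: DatetimeIndex (daily), values: stage_m

    def __post_init__(self) -> None:
        idx = pd.DatetimeIndex(self.records.index)
        if idx.has_duplicates:
            raise ValueError(f"duplicate dates in gauge {self.station_id}")
        if not np.all(np.isfinite(self.records.to_numpy(dtype=float))):
            raise ValueError(f"non-finite stage in gauge {self.station_id}")
        self.records = pd.Series(self.records.to_numpy(dtype=float), index=idx).sort_index()


@dataclass(frozen=True)
class SeasonConfig:
    """Season month sets and the averaging period (inclusive years)."""

    wet_months: frozenset[int] = WET_MONTHS
    dry_months: frozenset[int] = DRY_MONTHS
    start_year: int = 2005
    end_year: int = 2006

    def __post_init__(self) -> None:
        if self.wet_months | self.dry_months != frozenset(range(1, 13)):
            raise ValueError("wet and dry months must partition the 12 months")
        if self.wet_months & self.dry_months:
            raise ValueError("wet and dry months must be disjoint")
        if self.start_year > self.end_year:
            raise ValueError("averaging period start after end")

    def season_of(self, date: pd.Timestamp) -> str:
        return "wet" if date.month in self.wet_months else "dry"


def interpolate_stage(
    gauges: list[GaugeSeries],
    date,
    points: np.ndarray,
    power: float = 2.0,
) -> np.ndarray:
    """IDW stage estimate at (n, 2) points for one day.

    Stations without a record on the date are skipped.  A point coincident
    with a station returns that station's stage exactly.
    """
    date = pd.Timestamp(date)
    xs, ys, stages = [], [], []
    for g in gauges:
        if date in g.records.index:
            xs.append(g.x)
            ys.append(g.y)
            stages.append(g.records.loc[date])
    if not stages:
        raise ValueError(f"no gauge has a stage record on {date.date()}")
    return _idw(np.column_stack([xs, ys]), np.asarray(stages, dtype=float), np.atleast_2d(points), power)


def _idw(stations: np.ndarray, values: np.ndarray, points: np.ndarray, power: float) -> np.ndarray:
    d = np.sqrt(((points[:, None, :] - stations[None, :, :]) ** 2).sum(axis=2))
    out = np.empty(len(points))
    exact = d < 1e-9
    any_exact = exact.any(axis=1)
    with np.errstate(divide="ignore"):
        w = 1.0 / d**power
    w[~np.isfinite(w)] = 0.0
    sw = w.sum(axis=1)
    out = (w @ values) / np.where(sw > 0, sw, 1.0)
    if any_exact.any():
        first = np.argmax(exact, axis=1)
        out[any_exact] = values[first[any_exact]]
    return out


def _cell_sample_points(grid: Grid, cells: list[tuple[int, int]], n_side: int) -> np.ndarray:
    """(n_cells * n_side², 2) sample points on an n×n subgrid per cell."""
    s = grid.cell_size
    offs = (np.arange(n_side) + 0.5) / n_side * s
    ox, oy = np.meshgrid(offs, offs)
    offsets = np.column_stack([ox.ravel(), oy.ravel()])
    origins = np.array(
        [[grid.x0 + c * s, grid.y0 + r * s] for c, r in cells], dtype=float
    )
    return (origins[:, None, :] + offsets[None, :, :]).reshape(-1, 2)


def seasonal_depth(
    gauges: list[GaugeSeries],
    elevation: AsciiGrid,
    grid: Grid,
    season: SeasonConfig | None = None,
    cells: list[tuple[int, int]] | None = None,
    power: float = 2.0,
    samples_per_cell_side: int = 3,
) -> pd.DataFrame:
    """Mean wet- and dry-season water depth (m) per cell.

    For each in-season day, depth at a sample point is interpolated stage
    minus elevation; the cell value is the mean over the per-cell sample
    subgrid and all in-season days in the averaging period.  Cells over
    elevation nodata come back NaN (flagged, never silently zero).

    Because IDW is linear in the stages and station positions are fixed,
    days sharing the same set of reporting stations are averaged in stage
    space first — mathematically identical to averaging daily depths, but
    one interpolation per availability pattern instead of per day.
    """
    season = season or SeasonConfig()
    if cells is None:
        cells = list(grid.cell_ids())
    if not gauges:
        raise ValueError("no gauges supplied")
    pts = _cell_sample_points(grid, cells, samples_per_cell_side)
    elev = elevation.sample(pts)
    n_pts_per_cell = samples_per_cell_side**2
    if np.isnan(elev).any():
        bad = np.unique(np.where(np.isnan(elev))[0] // n_pts_per_cell)
        logger.warning("elevation nodata under %d cells; depths set NaN", len(bad))

    start = pd.Timestamp(year=season.start_year, month=1, day=1)
    end = pd.Timestamp(year=season.end_year, month=12, day=31)
    all_dates = pd.date_range(start, end, freq="D")
    stations = np.array([[g.x, g.y] for g in gauges], dtype=float)
    # availability matrix: station has a record on the day
    avail = np.zeros((len(all_dates), len(gauges)), dtype=bool)
    stage_mat = np.zeros((len(all_dates), len(gauges)))
    for k, g in enumerate(gauges):
        rec = g.records.reindex(all_dates)
        have = rec.notna().to_numpy()
        avail[:, k] = have
        stage_mat[have, k] = rec.to_numpy(dtype=float)[have]

    out = {}
    months = all_dates.month
    for name, month_set in (("wet", season.wet_months), ("dry", season.dry_months)):
        in_season = np.isin(months, list(month_set)) & avail.any(axis=1)
        if not in_season.any():
            raise ValueError(f"no {name}-season days with gauge data in the averaging period")
        day_idx = np.where(in_season)[0]
        # group days by availability pattern; IDW weights are constant per pattern
        acc = np.zeros(len(pts))
        n_days = 0
        patterns: dict[bytes, list[int]] = {}
        for d in day_idx:
            patterns.setdefault(avail[d].tobytes(), []).append(d)
        for key, days in patterns.items():
            mask = np.frombuffer(key, dtype=bool)
            mean_stage = stage_mat[days][:, mask].mean(axis=0)
            interp = _idw(stations[mask], mean_stage, pts, power)
            acc += interp * len(days)
            n_days += len(days)
        mean_point_depth = acc / n_days - elev
        out[f"{name}_depth"] = mean_point_depth.reshape(len(cells), n_pts_per_cell).mean(axis=1)

    index = pd.MultiIndex.from_tuples(cells, names=["col", "row"])
    return pd.DataFrame(out, index=index)[["dry_depth", "wet_depth"]]
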