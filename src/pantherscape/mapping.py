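"""Habitat map, zone accounting and carrying-capacity arithmetic.

Cells whose predicted probability of presence reaches the selected cutoff
are breeding habitat; with 1-km² cells, habitat area in km² equals the cell
count.  Zone summaries intersect the habitat map with comparison polygons
(e.g. previously published Primary/Secondary conservation zones) by the
cell-center rule; ownership/protection overlays reduce to the same
machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from .grid import Grid


@dataclass
class HabitatMap:
    """Per-cell P and habitat flag at a fixed threshold."""

    table: pd.DataFrame  # columns: P, habitat (bool); index (col, row)
    threshold: float
    strict: bool

    @property
    def habitat_km2(self) -> float:
        # 1-km² cells: area equals count
        return float(self.table["habitat"].sum())


def classify_map(
    table: pd.DataFrame,
    threshold: float,
    p_column: str = "P",
    strict: bool = False,
) -> HabitatMap:
    """Flag habitat cells at a probability cutoff.

    ``strict=False`` (default) uses ``P >= threshold``; ``strict=True``
    uses ``P > threshold``.  The two differ only for cells exactly at the
    cutoff.
    """
    if not np.isfinite(threshold) or threshold < 0:
        raise ValueError("threshold must be a non-negative number")
    if p_column not in table.columns:
        raise ValueError(f"table lacks column {p_column!r}")
    p = table[p_column].to_numpy(dtype=float)
    flag = p > threshold if strict else p >= threshold
    out = pd.DataFrame({"P": p, "habitat": flag}, index=table.index)
    return HabitatMap(table=out, threshold=float(threshold), strict=strict)


def zone_summary(
    habitat_map: HabitatMap,
    zones: dict[str, Polygon],
    grid: Grid,
) -> pd.DataFrame:
    """Habitat area, share of total habitat and mean P per zone.

    Zones must not overlap; cells whose center falls in no zone are
    reported under ``"other"``.  Areas and shares are conserved: zone rows
    plus "other" sum to the whole-map totals.
    """
    names = list(zones)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            inter = zones[a].intersection(zones[b])
            if inter.area > 1e-6:
                raise ValueError(f"zones {a!r} and {b!r} overlap")
    prepared = {name: prep(poly) for name, poly in zones.items()}
    assignment = []
    for cid in habitat_map.table.index:
        cx, cy = grid.cell_center(*cid)
        zone = "other"
        for name in names:
            if prepared[name].contains(Point(cx, cy)):
                zone = name
                break
        assignment.append(zone)
    df = habitat_map.table.copy()
    df["zone"] = assignment
    total_habitat = habitat_map.habitat_km2
    rows = []
    for name in names + ["other"]:
        sub = df[df["zone"] == name]
        habitat = float(sub["habitat"].sum())
        rows.append(
            {
                "zone": name,
                "habitat_km2": habitat,
                "habitat_share": habitat / total_habitat if total_habitat > 0 else np.nan,
                "mean_P": float(sub["P"].mean()) if len(sub) else np.nan,
                "n_cells": int(len(sub)),
            }
        )
    return pd.DataFrame(rows)


def capacity(habitat_km2: float, density_per_100km2: float = 2.80) -> float:
    """Expected number of adults supportable by the habitat area.

    ``density_per_100km2`` defaults to 2.80 adults per 100 km², the maximum
    adult puma density reported in the literature — an upper bound on the
    population the mapped habitat could hold.
    """
    if habitat_km2 < 0 or density_per_100km2 < 0:
        raise ValueError("inputs must be non-negative")
    return habitat_km2 * density_per_100km2 / 100.0


def area_table(category_areas: pd.Series, total_area: float) -> pd.DataFrame:
    """Category area and percent-of-total table.

    ``percent`` carries the unrounded machine value; ``percent_display``
    is rounded to one decimal for reporting.
    """
    if total_area <= 0:
        raise ValueError("total area must be positive")
    if (category_areas < 0).any():
        raise ValueError("category areas must be non-negative")
    percent = 100.0 * category_areas / total_area
    return pd.DataFrame(
        {
            "area_km2": category_areas,
            "percent": percent,
            "percent_display": percent.round(1),
        }
    ).sort_values("area_km2", ascending=False)
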