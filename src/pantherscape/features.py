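"""Per-cell landscape covariates: cover fractions, forest edge, human and road density.

All operations take the analysis :class:`~pantherscape.grid.Grid` plus vector
layers in planar metric coordinates and return pandas objects indexed by
``(col, row)`` cell id.  Geometry is exact (shapely overlays), not
raster-sampled; Monte-Carlo point-sampling oracles are used in the test
suite to cross-check the overlay arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import LineString, MultiLineString, Polygon, box
from shapely.geometry.base import BaseGeometry

from .cover import CATEGORIES, COVER_ABBREV, CategoryMap, EdgeRules
from .grid import Grid

#: road class codes ignored when computing road density — they do not
#: represent enough disturbance to matter
DEFAULT_EXCLUDED_ROAD_CLASSES = frozenset(
    {"four_wheel_drive", "bike_trail", "pedestrian_trail"}
)


@dataclass
class CoverLayer:
    """Polygonal land-cover layer: geometries + raw class codes + the code map."""

    geometries: list[Polygon]
    codes: list[str]
    category_map: CategoryMap = field(default_factory=CategoryMap.identity)

    def __post_init__(self) -> None:
        if len(self.geometries) != len(self.codes):
            raise ValueError("geometries and codes must have equal length")
        for i, g in enumerate(self.geometries):
            if g is None or g.is_empty or not g.is_valid:
                raise ValueError(f"invalid geometry for polygon {i} (code {self.codes[i]!r})")
        # resolve every code up front so unmapped codes fail at load
        self.categories = [self.category_map.category(c) for c in self.codes]

    def __len__(self) -> int:
        return len(self.geometries)

    def total_area_by_category(self) -> pd.Series:
        areas = pd.Series(0.0, index=list(CATEGORIES))
        for geom, cat in zip(self.geometries, self.categories):
            areas[cat] += geom.area
        return areas


def _cell_index(grid: Grid, cells: list[tuple[int, int]] | None) -> pd.MultiIndex:
    ids = list(grid.cell_ids()) if cells is None else list(cells)
    return pd.MultiIndex.from_tuples(ids, names=["col", "row"])


def cover_fractions(
    grid: Grid,
    layer: CoverLayer,
    cells: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Fraction of each cell covered by each of the 10 categories.

    ``fraction(cell, cat) = area(cell ∩ polygons of cat) / cell area``;
    for a fully tessellated cell the 10 fractions sum to 1.
    """
    index = _cell_index(grid, cells)
    tree = STRtree(layer.geometries)
    cell_area = grid.cell_size**2
    out = np.zeros((len(index), len(CATEGORIES)), dtype=float)
    cat_pos = {c: k for k, c in enumerate(CATEGORIES)}
    for i, (col, row) in enumerate(index):
        cell = grid.cell_box(col, row)
        for j in tree.query(cell):
            geom = layer.geometries[j]
            inter = cell.intersection(geom)
            if not inter.is_empty:
                out[i, cat_pos[layer.categories[j]]] += inter.area
    return pd.DataFrame(out / cell_area, index=index, columns=list(CATEGORIES))


def _overlap_check(layer: CoverLayer, tree: STRtree, tol: float = 1e-6) -> None:
    """Reject layers where polygons of different categories overlap with area."""
    for i, geom in enumerate(layer.geometries):
        for j in tree.query(geom):
            if j <= i:
                continue
            if layer.categories[j] == layer.categories[i]:
                continue
            inter = geom.intersection(layer.geometries[j])
            if inter.area > tol:
                raise ValueError(
                    f"ambiguous boundary: polygons {i} and {int(j)} of different "
                    "categories overlap"
                )


def _line_parts(geom: BaseGeometry) -> list[LineString]:
    """Extract 1-dimensional components of an intersection result."""
    if geom.is_empty:
        return []
    if isinstance(geom, LineString):
        return [geom]
    if isinstance(geom, MultiLineString):
        return list(geom.geoms)
    if hasattr(geom, "geoms"):  # GeometryCollection
        parts: list[LineString] = []
        for g in geom.geoms:
            parts.extend(_line_parts(g))
        return parts
    return []  # points etc.


def assign_line_lengths(
    grid: Grid,
    lines: list[BaseGeometry],
    cells: list[tuple[int, int]] | None = None,
) -> pd.Series:
    """Split lines by the grid and total length (km) per cell.

    A piece running exactly along a grid line is counted once, in the cell
    with the smaller (col, row) index, so per-cell lengths add up to the
    un-gridded total.
    """
    index = _cell_index(grid, cells)
    member = set(index)
    totals = dict.fromkeys(index, 0.0)
    s = grid.cell_size
    for line in lines:
        if line.is_empty:
            continue
        xmin, ymin, xmax, ymax = line.bounds
        c0 = max(0, int(np.floor((xmin - grid.x0) / s)) - 1)
        c1 = min(grid.n_cols - 1, int(np.floor((xmax - grid.x0) / s)) + 1)
        r0 = max(0, int(np.floor((ymin - grid.y0) / s)) - 1)
        r1 = min(grid.n_rows - 1, int(np.floor((ymax - grid.y0) / s)) + 1)
        for col in range(c0, c1 + 1):
            for row in range(r0, r1 + 1):
                piece = grid.cell_box(col, row).intersection(line)
                for part in _line_parts(piece):
                    mid = part.interpolate(0.5, normalized=True)
                    owner = grid.assign(mid.x, mid.y)
                    if owner == (col, row) and owner in member:
                        totals[owner] += part.length
    return pd.Series(totals, name="length_km").div(1000.0).reindex(index, fill_value=0.0)


def edge_segments(layer: CoverLayer, rules: EdgeRules | None = None) -> list[LineString]:
    """Extract forest-edge line segments from a planar cover tessellation.

    A shared boundary qualifies when one side is forest and the other is an
    edge-forming category, or when the two sides are upland and wetland
    forest.  Boundaries between two polygons of the same category are never
    edge.
    """
    rules = rules or EdgeRules()
    tree = STRtree(layer.geometries)
    _overlap_check(layer, tree)
    segments: list[LineString] = []
    for i, geom in enumerate(layer.geometries):
        bdy_i = geom.boundary
        for j in tree.query(geom):
            if j <= i:
                continue
            if not rules.is_edge_pair(layer.categories[i], layer.categories[int(j)]):
                continue
            shared = bdy_i.intersection(layer.geometries[int(j)].boundary)
            segments.extend(_line_parts(shared))
    return segments


def forest_edge(
    grid: Grid,
    layer: CoverLayer,
    rules: EdgeRules | None = None,
    cells: list[tuple[int, int]] | None = None,
) -> pd.Series:
    """Per-cell forest-edge length in km (prey-availability proxy)."""
    segs = edge_segments(layer, rules)
    out = assign_line_lengths(grid, segs, cells)
    out.name = "For_Edge"
    return out


def human_density(
    grid: Grid,
    blocks: list[tuple[Polygon, float]],
    cells: list[tuple[int, int]] | None = None,
) -> pd.Series:
    """Area-weighted average human density (people/km²) per cell.

    ``blocks`` are (polygon, population-count) pairs; block density is
    population / block area.  Uncovered area contributes zero people.
    """
    index = _cell_index(grid, cells)
    geoms = [g for g, _ in blocks]
    dens = []
    for k, (g, pop) in enumerate(blocks):
        if pop < 0:
            raise ValueError(f"negative population in block {k}")
        dens.append(pop / (g.area / 1e6))  # people per km^2
    tree = STRtree(geoms)
    cell_area = grid.cell_size**2
    out = np.zeros(len(index))
    for i, (col, row) in enumerate(index):
        cell = grid.cell_box(col, row)
        for j in tree.query(cell):
            inter = cell.intersection(geoms[int(j)])
            if not inter.is_empty:
                out[i] += dens[int(j)] * inter.area / cell_area
    return pd.Series(out, index=index, name="Pop_Dens")


def road_density(
    grid: Grid,
    roads: list[tuple[LineString, str]],
    excluded_classes: frozenset[str] = DEFAULT_EXCLUDED_ROAD_CLASSES,
    cells: list[tuple[int, int]] | None = None,
) -> pd.Series:
    """Per-cell length (km) of roads, skipping excluded road classes."""
    kept = [geom for geom, cls in roads if cls not in excluded_classes]
    out = assign_line_lengths(grid, kept, cells)
    out.name = "Rd_Dens"
    return out


def feature_diagnostics(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Squared Pearson correlation for requested covariate pairs.

    Collinearity screen — e.g. forest edge vs total forest cover, or the
    two seasonal depth surfaces.  Zero-variance covariates give NaN with a
    warning rather than an error.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 cells for correlation diagnostics")
    rows = []
    for a, b in pairs:
        xa = table[a].to_numpy(dtype=float)
        xb = table[b].to_numpy(dtype=float)
        if np.std(xa) == 0 or np.std(xb) == 0:
            warnings.warn(f"zero-variance covariate in pair ({a}, {b}); R² undefined")
            r2 = np.nan
        else:
            r2 = float(np.corrcoef(xa, xb)[0, 1] ** 2)
        rows.append({"var_a": a, "var_b": b, "r_squared": r2})
    return pd.DataFrame(rows)


def assemble_features(
    grid: Grid,
    layer: CoverLayer,
    blocks: list[tuple[Polygon, float]],
    roads: list[tuple[LineString, str]],
    rules: EdgeRules | None = None,
    cells: list[tuple[int, int]] | None = None,
    excluded_road_classes: frozenset[str] = DEFAULT_EXCLUDED_ROAD_CLASSES,
) -> pd.DataFrame:
    """Build the non-hydrologic part of the feature table.

    Returns a DataFrame indexed by (col, row) with the 10 cover-fraction
    columns (abbreviated names), For_Edge, Pop_Dens and Rd_Dens.  The
    hydrology module adds dry_depth / wet_depth; the telemetry module adds
    the presence column.
    """
    fracs = cover_fractions(grid, layer, cells)
    fracs = fracs.rename(columns=COVER_ABBREV)
    fracs["For_Edge"] = forest_edge(grid, layer, rules, cells)
    fracs["Pop_Dens"] = human_density(grid, blocks, cells)
    fracs["Rd_Dens"] = road_density(grid, roads, excluded_road_classes, cells)
    return fracs
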