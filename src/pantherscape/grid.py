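"""Analysis grid: square 1-km cells covering a study area.

The study area is partitioned into square cells (1.0 km on a side by
default).  Every per-cell quantity in the pipeline (cover fractions, forest
edge, water depths, presence labels, predicted probabilities) is keyed by
``(col, row)`` cell indices on this grid.

Boundary convention
-------------------
A point lying strictly inside a cell belongs to that cell.  A point lying
exactly on a shared cell boundary is assigned to the neighbouring cell with
the smaller ``(col, row)`` index ("lower-left rule"), except along the
grid's own lower/left edge where the boundary belongs to the first cell.
The same rule is applied to line segments that run exactly along a grid
line, which makes per-cell totals (edge length, road length) add up to the
un-gridded totals with no double counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from shapely.geometry import Polygon, box
from shapely.prepared import prep


@dataclass(frozen=True)
class Grid:
    """Regular square grid in planar metric coordinates.

    Parameters
    ----------
    x0, y0 : float
        Coordinates of the lower-left corner, metres.
    n_cols, n_rows : int
        Grid dimensions.
    cell_size : float
        Cell side length in metres (default 1000, i.e. 1-km cells).
    """

    x0: float
    y0: float
    n_cols: int
    n_rows: int
    cell_size: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.x0,
            self.y0,
            self.x0 + self.n_cols * self.cell_size,
            self.y0 + self.n_rows * self.cell_size,
        )

    def cell_ids(self) -> Iterator[tuple[int, int]]:
        """Iterate cells row-major: (0,0), (1,0), ..., (n_cols-1, n_rows-1)."""
        for row in range(self.n_rows):
            for col in range(self.n_cols):
                yield (col, row)

    def cell_box(self, col: int, row: int) -> Polygon:
        s = self.cell_size
        x = self.x0 + col * s
        y = self.y0 + row * s
        return box(x, y, x + s, y + s)

    def cell_center(self, col: int, row: int) -> tuple[float, float]:
        s = self.cell_size
        return (self.x0 + (col + 0.5) * s, self.y0 + (row + 0.5) * s)

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of centers in cell_ids() order."""
        cols, rows = np.meshgrid(np.arange(self.n_cols), np.arange(self.n_rows))
        cx = self.x0 + (cols.ravel() + 0.5) * self.cell_size
        cy = self.y0 + (rows.ravel() + 0.5) * self.cell_size
        return np.column_stack([cx, cy])

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.bounds
        return xmin <= x <= xmax and ymin <= y <= ymax

    def assign(self, x: float, y: float) -> tuple[int, int]:
        """Cell index for a point, applying the lower-left boundary rule.

        Raises ``ValueError`` for points outside the grid bounds.
        """
        if not self.contains(x, y):
            raise ValueError(f"point ({x}, {y}) outside grid bounds {self.bounds}")
        col = _axis_index(x - self.x0, self.cell_size, self.n_cols)
        row = _axis_index(y - self.y0, self.cell_size, self.n_rows)
        return (col, row)

    def assign_many(self, xy: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`assign`; returns (n, 2) int array of (col, row)."""
        xy = np.asarray(xy, dtype=float)
        cols = _axis_index_vec(xy[:, 0] - self.x0, self.cell_size, self.n_cols)
        rows = _axis_index_vec(xy[:, 1] - self.y0, self.cell_size, self.n_rows)
        return np.column_stack([cols, rows])


def _axis_index(u: float, s: float, n: int) -> int:
    """Index along one axis with boundary points assigned to the lower cell."""
    i = int(np.ceil(u / s)) - 1
    return min(max(i, 0), n - 1)


def _axis_index_vec(u: np.ndarray, s: float, n: int) -> np.ndarray:
    i = np.ceil(u / s).astype(int) - 1
    return np.clip(i, 0, n - 1)


def build_grid(study_area: Polygon, cell_size: float = 1000.0) -> tuple[Grid, list[tuple[int, int]]]:
    """Build the analysis grid over a study-area polygon.

    The grid origin snaps to multiples of ``cell_size`` so that grids built
    from overlapping polygons align.  A cell is part of the study area when
    its *center* lies inside the polygon, which makes the cell count
    approximate the polygon area in cell units.

    Returns the bounding :class:`Grid` and the list of member cell ids.
    """
    if study_area is None or study_area.is_empty or not study_area.is_valid:
        raise ValueError("study area polygon is empty or invalid")
    if study_area.area <= cell_size**2:
        raise ValueError("study area smaller than a single grid cell")
    xmin, ymin, xmax, ymax = study_area.bounds
    x0 = np.floor(xmin / cell_size) * cell_size
    y0 = np.floor(ymin / cell_size) * cell_size
    n_cols = int(np.ceil((xmax - x0) / cell_size))
    n_rows = int(np.ceil((ymax - y0) / cell_size))
    grid = Grid(x0, y0, n_cols, n_rows, cell_size)
    prepared = prep(study_area)
    from shapely.geometry import Point

    members = [
        (col, row)
        for (col, row) in grid.cell_ids()
        if prepared.contains(Point(*grid.cell_center(col, row)))
    ]
    if not members:
        raise ValueError("no cell centers fall inside the study area")
    return grid, members
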