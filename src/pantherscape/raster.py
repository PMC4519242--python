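"""Minimal single-band raster in ESRI ASCII grid format.

Ground-elevation surfaces are exchanged as plain-text ESRI ASCII grids
(``.asc``): a 6-line header (ncols, nrows, xllcorner, yllcorner, cellsize,
NODATA_value) followed by rows of values, first row = northernmost.
The sampler interpolates bilinearly between cell centers, which is what the
water-depth module needs to evaluate elevation at arbitrary points.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class AsciiGrid:
    """Raster with values ``data[i, j]`` at row i (north to south), col j."""

    data: np.ndarray  # (nrows, ncols), float, NaN = nodata
    xllcorner: float
    yllcorner: float
    cellsize: float

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.xllcorner,
            self.yllcorner,
            self.xllcorner + self.ncols * self.cellsize,
            self.yllcorner + self.nrows * self.cellsize,
        )

    def sample(self, xy: np.ndarray) -> np.ndarray:
        """Bilinear sample at (n, 2) points; NaN outside data or at nodata."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        # fractional position in cell-center coordinates
        fx = (xy[:, 0] - self.xllcorner) / self.cellsize - 0.5
        fy = (xy[:, 1] - self.yllcorner) / self.cellsize - 0.5
        # clamp to the center lattice so edge points extrapolate flat
        fx = np.clip(fx, 0.0, self.ncols - 1.0)
        fy = np.clip(fy, 0.0, self.nrows - 1.0)
        j0 = np.clip(np.floor(fx).astype(int), 0, self.ncols - 2) if self.ncols > 1 else np.zeros(len(fx), int)
        i0s = np.clip(np.floor(fy).astype(int), 0, self.nrows - 2) if self.nrows > 1 else np.zeros(len(fy), int)
        tx = fx - j0
        ty = fy - i0s
        # row 0 of data is the *top* (max y); convert south-based index
        def val(i_south, j):
            i = self.nrows - 1 - i_south
            return self.data[i, j]

        if self.ncols == 1:
            j1 = j0
        else:
            j1 = j0 + 1
        if self.nrows == 1:
            i1 = i0s
        else:
            i1 = i0s + 1
        v00 = val(i0s, j0)
        v10 = val(i0s, j1)
        v01 = val(i1, j0)
        v11 = val(i1, j1)
        out = (
            v00 * (1 - tx) * (1 - ty)
            + v10 * tx * (1 - ty)
            + v01 * (1 - tx) * ty
            + v11 * tx * ty
        )
        xmin, ymin, xmax, ymax = self.bounds
        outside = (xy[:, 0] < xmin) | (xy[:, 0] > xmax) | (xy[:, 1] < ymin) | (xy[:, 1] > ymax)
        out = np.where(outside, np.nan, out)
        return out

    def write(self, path: str | Path, nodata: float = -9999.0) -> None:
        data = np.where(np.isfinite(self.data), self.data, nodata)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.xllcorner:.6f}\n"
            f"yllcorner {self.yllcorner:.6f}\n"
            f"cellsize {self.cellsize:.6f}\n"
            f"NODATA_value {nodata:.1f}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            for row in data:
                fh.write(" ".join(f"{v:.4f}" for v in row) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "AsciiGrid":
        with open(path) as fh:
            hdr = {}
            for _ in range(6):
                key, value = fh.readline().split()
                hdr[key.lower()] = float(value)
            data = np.loadtxt(fh, dtype=float)
        data = np.atleast_2d(data)
        nodata = hdr.get("nodata_value", -9999.0)
        data = np.where(data == nodata, np.nan, data)
        if data.shape != (int(hdr["nrows"]), int(hdr["ncols"])):
            raise ValueError(f"ASCII grid shape mismatch in {path}")
        return cls(
            data=data,
            xllcorner=hdr["xllcorner"],
            yllcorner=hdr["yllcorner"],
            cellsize=hdr["cellsize"],
        )

    @classmethod
    def constant(cls, value: float, bounds: tuple[float, float, float, float], cellsize: float) -> "AsciiGrid":
        """Flat raster covering ``bounds`` — convenient for tests."""
        xmin, ymin, xmax, ymax = bounds
        ncols = max(1, int(np.ceil((xmax - xmin) / cellsize)))
        nrows = max(1, int(np.ceil((ymax - ymin) / cellsize)))
        return cls(np.full((nrows, ncols), float(value)), xmin, ymin, cellsize)
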