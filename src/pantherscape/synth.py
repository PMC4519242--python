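"""Synthetic study systems with known ground truth.

Generates every input the pipeline consumes — a polygonal land-cover
tessellation, a smooth elevation surface with gauging stations, census
blocks and roads, and telemetry from simulated animals — for a
mostly-wetland landscape patterned on the south-Florida study system: ten
cover categories at realistic proportions, an urban/road gradient
concentrated in one corner, saltwater wetland along one edge, and animals
whose utilisation follows planted effects (forest edge and wetland forest
positive, human density, roads and agriculture negative, and a water-depth
optimum just below the ground surface).  Because the preference structure
is known exactly, every downstream stage — feature engineering, the forest
classifier, importance ranking, sensitivity sweeps — can be tested for
parameter recovery.

All generators are pure functions of the configuration (including its
seed): the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Voronoi
from shapely.geometry import LineString, Polygon, box

from . import cover as cov
from .cover import CATEGORIES, DEFAULT_COVER_MIX, CategoryMap
from .features import CoverLayer
from .grid import Grid
from .hydrology import GaugeSeries, SeasonConfig
from .raster import AsciiGrid

logger = logging.getLogger(__name__)

#: planted effect sizes on standardized covariates (logit scale).  Grass and
#: Up_Shrub are deliberate nulls (β = 0) so importance-ranking recovery can
#: be tested against ground truth.
DEFAULT_PREFERENCE_COEFS: dict[str, float] = {
    "For_Edge": 1.5,
    "Wet_For": 1.3,
    "Pop_Dens": -2.0,
    "Rd_Dens": -1.0,
    "Ag": -1.3,
    "Grass": 0.0,
    "Up_Shrub": 0.0,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic world."""

    extent_km: int = 60
    cell_km: float = 1.0
    cover_mix: dict = field(default_factory=lambda: dict(DEFAULT_COVER_MIX))
    n_animals: int = 20
    fixes_per_animal: int = 330
    preference_coefs: dict = field(default_factory=lambda: dict(DEFAULT_PREFERENCE_COEFS))
    depth_optimum_m: float = -0.6
    depth_curvature: float = 2.5  # logit penalty per m² away from the optimum
    intercept: float = 0.5
    movement_radius_km: float = 6.0
    n_gauges: int = 12
    start_year: int = 2005
    end_year: int = 2006
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.cover_mix) != set(CATEGORIES):
            raise ValueError("cover_mix must cover exactly the 10 cover categories")
        if abs(sum(self.cover_mix.values()) - 1.0) > 1e-9:
            raise ValueError("cover_mix fractions must sum to 1")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.fixes_per_animal < 50:
            raise ValueError("fixes_per_animal must be >= 50")
        if self.cell_km != 1.0:
            raise ValueError("cell size is fixed at 1 km")

    @property
    def extent_m(self) -> float:
        return self.extent_km * 1000.0

    @property
    def grid(self) -> Grid:
        return Grid(0.0, 0.0, self.extent_km, self.extent_km, self.cell_km * 1000.0)

    @property
    def urban_corner(self) -> tuple[float, float]:
        return (self.extent_m, self.extent_m)

    def rng(self, stream: str) -> np.random.Generator:
        streams = ["cover", "hydro", "anthro", "telemetry"]
        children = np.random.SeedSequence(self.seed).spawn(len(streams))
        return np.random.default_rng(children[streams.index(stream)])


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    utilization: pd.Series  # per-cell weight, >= 0
    preference_coefs: dict
    depth_optimum_m: float
    depth_curvature: float
    home_range_centers: list[tuple[float, float]]
    true_dry_depth: pd.Series | None = None
    true_wet_depth: pd.Series | None = None

    def __post_init__(self) -> None:
        w = self.utilization.to_numpy(dtype=float)
        if not np.isfinite(w).all() or (w < 0).any():
            raise ValueError("utilization weights must be finite and non-negative")
        if not (w > 0).any():
            raise ValueError("no habitable cells")

    def as_dict(self) -> dict:
        return {
            "preference_coefs": self.preference_coefs,
            "depth_optimum_m": self.depth_optimum_m,
            "depth_curvature": self.depth_curvature,
            "home_range_centers": [list(c) for c in self.home_range_centers],
            "utilization": {f"{c}_{r}": float(w) for (c, r), w in self.utilization.items()},
        }


# ---------------------------------------------------------------------------
# land cover


def _bounded_voronoi(points: np.ndarray, extent: float) -> tuple[list[Polygon], list[tuple[int, int]]]:
    """Voronoi cells of ``points`` clipped to [0, extent]², plus adjacency.

    The classic mirroring trick: reflecting the points across all four
    edges bounds every original cell inside the extent.
    """
    mirrored = [points]
    for axis, bound in ((0, 0.0), (0, extent), (1, 0.0), (1, extent)):
        m = points.copy()
        m[:, axis] = 2 * bound - m[:, axis]
        mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    n = len(points)
    world = box(0.0, 0.0, extent, extent)
    polys: list[Polygon] = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        verts = vor.vertices[region]
        hull = ConvexHull(verts)
        poly = Polygon(verts[hull.vertices]).intersection(world)
        polys.append(poly)
    adjacency = [
        (int(a), int(b))
        for a, b in vor.ridge_points
        if a < n and b < n
    ]
    return polys, adjacency


def _grow_regions(
    polys: list[Polygon],
    adjacency: list[tuple[int, int]],
    targets: dict[str, float],
    seeds: dict[str, list[int]],
    rng: np.random.Generator,
) -> list[str]:
    """Seeded region growing on the Voronoi adjacency graph.

    Repeatedly grows the category with the largest remaining area deficit
    by one adjacent unassigned cell, producing spatially autocorrelated
    patches whose realized areas track the targets to within a cell or two.
    """
    n = len(polys)
    areas = np.array([p.area for p in polys])
    neighbours: list[list[int]] = [[] for _ in range(n)]
    for a, b in adjacency:
        neighbours[a].append(b)
        neighbours[b].append(a)
    assigned: list[str | None] = [None] * n
    grown = {cat: 0.0 for cat in targets}
    frontier: dict[str, list[int]] = {cat: [] for cat in targets}
    for cat, idxs in seeds.items():
        for i in idxs:
            if assigned[i] is None:
                assigned[i] = cat
                grown[cat] += areas[i]
                frontier[cat].extend(j for j in neighbours[i] if assigned[j] is None)
    n_left = assigned.count(None)
    while n_left:
        deficits = {cat: targets[cat] - grown[cat] for cat in targets}
        cat = max(deficits, key=lambda c: deficits[c])
        # pop a random unassigned frontier cell; reseed if exhausted
        cell = None
        front = frontier[cat]
        while front:
            j = front.pop(int(rng.integers(len(front))))
            if assigned[j] is None:
                cell = j
                break
        if cell is None:
            unassigned = [i for i in range(n) if assigned[i] is None]
            cell = int(unassigned[rng.integers(len(unassigned))])
        assigned[cell] = cat
        grown[cat] += areas[cell]
        front.extend(j for j in neighbours[cell] if assigned[j] is None)
        n_left -= 1
    return assigned  # type: ignore[return-value]


def generate_cover(config: SyntheticConfig) -> CoverLayer:
    """Gap-free, overlap-free polygon tessellation at the configured mix.

    Urban grows from one corner, saltwater wetland along the south edge,
    the other categories from scattered seeds, all by region growing over a
    Voronoi tessellation — spatially autocorrelated patches, polygon-native
    like real cover databases.
    """
    if config.extent_km < 5:
        raise ValueError("landscape too small: extent_km must be >= 5")
    rng = config.rng("cover")
    L = config.extent_m
    n_pts = max(60, config.extent_km**2)
    points = rng.uniform(0.0, L, size=(n_pts, 2))
    polys, adjacency = _bounded_voronoi(points, L)
    total = L * L
    targets = {cat: frac * total for cat, frac in config.cover_mix.items() if frac > 0}

    seeds: dict[str, list[int]] = {cat: [] for cat in targets}
    taken: set[int] = set()

    def nearest_free(target_xy: np.ndarray) -> int:
        d = np.linalg.norm(points - target_xy, axis=1)
        for i in np.argsort(d):
            if int(i) not in taken:
                return int(i)
        raise RuntimeError("no free seed point")

    if cov.URBAN in targets:
        i = nearest_free(np.array(config.urban_corner))
        seeds[cov.URBAN].append(i)
        taken.add(i)
    if cov.SALTWATER_WETLAND in targets:
        for fx in (0.2, 0.5, 0.8):  # several seeds strung along the south edge
            i = nearest_free(np.array([fx * L, 0.0]))
            seeds[cov.SALTWATER_WETLAND].append(i)
            taken.add(i)
    # patch seeds scale with the landscape so small test extents stay valid
    patch_budget = max(10, min(120, n_pts // 3))
    for cat, target in targets.items():
        if seeds[cat]:
            continue
        n_patches = max(1, int(round(patch_budget * target / total)) + 1)
        for _ in range(n_patches):
            free = [i for i in range(n_pts) if i not in taken]
            if not free:
                break
            i = int(free[rng.integers(len(free))])
            seeds[cat].append(i)
            taken.add(i)

    assigned = _grow_regions(polys, adjacency, targets, seeds, rng)
    # raw class codes: a few synthetic sub-codes per category, so the
    # downstream many->10 CategoryMap is exercised
    mapping: dict[str, str] = {}
    codes: list[str] = []
    for cat in targets:
        for sub in range(3):
            mapping[f"{cat}.c{sub}"] = cat
    for i, cat in enumerate(assigned):
        codes.append(f"{cat}.c{int(rng.integers(3))}")
    keep = [i for i, p in enumerate(polys) if not p.is_empty and p.area > 0]
    return CoverLayer(
        geometries=[polys[i] for i in keep],
        codes=[codes[i] for i in keep],
        category_map=CategoryMap(mapping),
    )


# ---------------------------------------------------------------------------
# hydrology


def elevation_function(config: SyntheticConfig):
    """Analytic ground-elevation surface (m): gradient rising toward the
    urban corner plus low-frequency ripple.  Calibrated together with the
    stage regime so seasonal depths span roughly -5.2 to +2.6 m."""
    L = config.extent_m

    def elev(x, y):
        u = (np.asarray(x) + np.asarray(y)) / (2 * L)
        ripple = 0.2 * np.sin(6 * np.pi * np.asarray(x) / L) * np.cos(4 * np.pi * np.asarray(y) / L)
        return -2.0 + 7.6 * u + ripple

    return elev


def _wet_season_rise(x, y, L: float):
    """Wet-season stage rise (m) above the dry-season base.

    Averages 0.3 m but varies across the landscape (well-drained areas see
    a small rise, sloughs a large one), so the two seasonal depth surfaces
    are highly but not perfectly correlated, as in real hydrology.
    """
    return 0.30 + 0.35 * np.sin(2 * np.pi * np.asarray(x) / L) * np.cos(
        2 * np.pi * np.asarray(y) / L
    )


def _stage_series(
    dates: pd.DatetimeIndex, x: float, y: float, L: float, offset: float, season: SeasonConfig
) -> np.ndarray:
    wet = np.isin(dates.month, list(season.wet_months))
    base = np.where(wet, 0.45 + _wet_season_rise(x, y, L), 0.45)
    doy = dates.dayofyear.to_numpy()
    return base + 0.05 * np.sin(2 * np.pi * doy / 365.0) + offset


def generate_hydrology(
    config: SyntheticConfig,
) -> tuple[AsciiGrid, list[GaugeSeries], pd.DataFrame]:
    """Elevation raster, gauge stage records, and the true depth field.

    Gauges sit both inside and outside the extent (to avoid interpolation
    edge effects) and record daily stages for the configured years; the
    regional stage is nearly flat in space so the depth field is dominated
    by topography.  The returned frame holds the generating (true) mean
    seasonal depth per cell, for recovery tests.
    """
    if config.n_gauges < 4:
        raise ValueError("need at least 4 gauges")
    rng = config.rng("hydro")
    L = config.extent_m
    elev = elevation_function(config)

    res = 250.0
    n_px = int(np.ceil(L / res))
    xs = (np.arange(n_px) + 0.5) * res
    ys = (np.arange(n_px) + 0.5) * res
    gx, gy = np.meshgrid(xs, ys)
    data = elev(gx, gy)[::-1, :]  # first raster row is the north edge
    raster = AsciiGrid(data=data, xllcorner=0.0, yllcorner=0.0, cellsize=res)

    season = SeasonConfig(start_year=config.start_year, end_year=config.end_year)
    dates = pd.date_range(
        f"{config.start_year}-01-01", f"{config.end_year}-12-31", freq="D"
    )
    n_inside = max(4, int(round(config.n_gauges * 0.75)))
    gauges: list[GaugeSeries] = []
    for k in range(config.n_gauges):
        if k < n_inside:
            x, y = rng.uniform(0.05 * L, 0.95 * L, size=2)
        else:  # exterior stations just beyond a random edge
            edge = int(rng.integers(4))
            off = rng.uniform(0.02 * L, 0.1 * L)
            t = rng.uniform(0.0, L)
            x, y = {
                0: (-off, t),
                1: (L + off, t),
                2: (t, -off),
                3: (t, L + off),
            }[edge]
        offset = rng.normal(0.0, 0.03)
        stages = _stage_series(dates, x, y, L, offset, season)
        gauges.append(
            GaugeSeries(
                station_id=f"G{k:02d}",
                x=float(x),
                y=float(y),
                records=pd.Series(stages, index=dates),
            )
        )

    grid = config.grid
    centers = grid.cell_centers()
    cell_elev = elev(centers[:, 0], centers[:, 1])
    wet_mask = np.isin(dates.month, list(season.wet_months))
    doy = dates.dayofyear.to_numpy()
    annual = 0.05 * np.sin(2 * np.pi * doy / 365.0)
    mean_stage_dry = 0.45 + float(annual[~wet_mask].mean())
    mean_stage_wet = (
        0.45
        + _wet_season_rise(centers[:, 0], centers[:, 1], L)
        + float(annual[wet_mask].mean())
    )
    index = pd.MultiIndex.from_tuples(list(grid.cell_ids()), names=["col", "row"])
    truth = pd.DataFrame(
        {
            "true_dry_depth": mean_stage_dry - cell_elev,
            "true_wet_depth": mean_stage_wet - cell_elev,
        },
        index=index,
    )
    return raster, gauges, truth


# ---------------------------------------------------------------------------
# census blocks and roads


def generate_anthropogenic(
    config: SyntheticConfig,
) -> tuple[list[tuple[Polygon, float]], list[tuple[LineString, str]]]:
    """Census blocks with a corner-decaying density gradient, plus roads.

    Block densities fall off from ~8000 people/km² at the urban corner to
    zero in the wild interior.  The road layer mixes a dense urban street
    grid, a few highways crossing the whole landscape, and trails carrying
    excluded class codes (four-wheel drive / bike / pedestrian) that the
    road-density covariate must ignore.  A cover mix with no urban fraction
    produces an uninhabited, road-free wilderness (trails only).
    """
    rng = config.rng("anthro")
    L = config.extent_m
    ux, uy = config.urban_corner
    wilderness = config.cover_mix.get(cov.URBAN, 0.0) == 0.0

    block_size = 2000.0
    n_blocks = int(np.ceil(L / block_size))
    # main city at the urban corner plus a few seeded satellite towns, so
    # population varies across the landscape rather than in one corner only
    settlements = [(ux, uy, 8000.0, 7000.0)]
    for _ in range(4):
        tx, ty = rng.uniform(0.1 * L, 0.9 * L, size=2)
        amp = float(rng.uniform(200.0, 1500.0))
        sig = float(rng.uniform(2000.0, 4000.0))
        settlements.append((tx, ty, amp, sig))
    blocks: list[tuple[Polygon, float]] = []
    for bi in range(n_blocks):
        for bj in range(n_blocks):
            x0, y0 = bi * block_size, bj * block_size
            poly = box(x0, y0, min(x0 + block_size, L), min(y0 + block_size, L))
            cx, cy = x0 + block_size / 2, y0 + block_size / 2
            dens = 0.0
            for sx, sy, amp, sig in settlements:
                d2 = (cx - sx) ** 2 + (cy - sy) ** 2
                dens += amp * np.exp(-d2 / (2 * sig**2))
            dens *= float(rng.lognormal(0.0, 0.3))
            if wilderness or dens < 1.0:
                dens = 0.0
            blocks.append((poly, dens * poly.area / 1e6))

    roads: list[tuple[LineString, str]] = []
    if not wilderness:
        # sparse highways crossing the wild interior
        roads.append((LineString([(0.0, 0.62 * L), (L, 0.62 * L)]), "highway"))
        roads.append((LineString([(0.35 * L, 0.0), (0.35 * L, L)]), "highway"))
        roads.append((LineString([(0.0, 0.0), (L, L)]), "highway"))
        # minor roadways scattered through the interior — even undeveloped
        # country is crossed by secondary roads
        for _ in range(8):
            t1, t2 = rng.uniform(0.0, L, size=2)
            if rng.random() < 0.5:
                roads.append((LineString([(0.0, t1), (L, t2)]), "secondary"))
            else:
                roads.append((LineString([(t1, 0.0), (t2, L)]), "secondary"))
        # dense street grid in the urban corner
        u0 = L - 12000.0
        step = 1500.0
        ticks = np.arange(u0, L + step / 2, step)
        for t in ticks:
            roads.append((LineString([(t, u0), (t, L)]), "local"))
            roads.append((LineString([(u0, t), (L, t)]), "local"))
    # trails with excluded class codes — generated even in wilderness so the
    # exclusion rule is always exercised
    roads.append((LineString([(0.0, 0.25 * L), (L, 0.30 * L)]), "bike_trail"))
    roads.append((LineString([(0.1 * L, 0.0), (0.15 * L, L)]), "four_wheel_drive"))
    roads.append((LineString([(0.0, 0.8 * L), (0.6 * L, L)]), "pedestrian_trail"))
    return blocks, roads


# ---------------------------------------------------------------------------
# telemetry


def utilization_weights(config: SyntheticConfig, features: pd.DataFrame) -> pd.Series:
    """Per-cell true utilisation weight from the planted preference structure.

    ``w = logistic(b0 + Σ β_j z_j - γ (dry_depth - optimum)²)`` where the
    ``z_j`` are covariates standardized over cells and the depth term is a
    quadratic in raw metres peaking at the configured optimum.
    """
    eta = np.full(len(features), config.intercept, dtype=float)
    for name, beta in config.preference_coefs.items():
        if beta == 0.0:
            continue
        if name not in features.columns:
            raise ValueError(f"preference covariate {name!r} not in feature table")
        x = features[name].to_numpy(dtype=float)
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        eta += beta * z
    depth = features["dry_depth"].to_numpy(dtype=float)
    eta -= config.depth_curvature * (depth - config.depth_optimum_m) ** 2
    w = 1.0 / (1.0 + np.exp(-eta))
    return pd.Series(w, index=features.index, name="utilization")


def simulate_telemetry(
    config: SyntheticConfig,
    features: pd.DataFrame,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Telemetry fixes from animals whose use follows the planted weights.

    Each animal's home-range center cell is drawn proportional to the
    utilisation weight; its fixes are drawn (independently, weighted) from
    cells within the movement radius of that center, uniformly within the
    chosen cell.  Fix timestamps fall in 2004–2013 at a few-day cadence and
    every animal is a breeding-age adult (>= 3 years old at every fix).
    """
    rng = config.rng("telemetry")
    grid = config.grid
    w = utilization_weights(config, features)
    wv = w.to_numpy(dtype=float)
    if not (wv > 1e-12).any():
        raise ValueError("no habitable cells")
    centers_xy = np.array([grid.cell_center(c, r) for c, r in features.index])
    probs = wv / wv.sum()
    radius = config.movement_radius_km * 1000.0

    rows = []
    hr_centers: list[tuple[float, float]] = []
    for a in range(config.n_animals):
        ci = int(rng.choice(len(probs), p=probs))
        jitter = rng.uniform(-grid.cell_size / 2, grid.cell_size / 2, size=2)
        center = centers_xy[ci] + jitter
        hr_centers.append((float(center[0]), float(center[1])))
        d = np.linalg.norm(centers_xy - center, axis=1)
        local = np.where(d <= radius)[0]
        lw = wv[local]
        if lw.sum() <= 0:
            local = np.array([ci])
            lw = np.array([1.0])
        lp = lw / lw.sum()
        cells = rng.choice(local, size=config.fixes_per_animal, p=lp)
        offs = rng.uniform(0.0, grid.cell_size, size=(config.fixes_per_animal, 2))
        xy = np.array(
            [
                [
                    grid.x0 + c * grid.cell_size,
                    grid.y0 + r * grid.cell_size,
                ]
                for c, r in (features.index[k] for k in cells)
            ]
        ) + offs
        # keep the whole track inside the 2004-2013 study window
        span_days = 4 * config.fixes_per_animal
        first_max = max(1, (pd.Timestamp("2013-12-31") - pd.Timestamp("2004-01-01")).days - span_days)
        first = pd.Timestamp("2004-01-01") + pd.Timedelta(days=int(rng.integers(0, first_max)))
        gaps = rng.integers(2, 5, size=config.fixes_per_animal).cumsum()
        times = first + pd.to_timedelta(gaps - gaps[0], unit="D")
        birth = first - pd.Timedelta(days=int((3.0 + rng.uniform(0.0, 8.0)) * 365.25) + 1)
        sex = "F" if rng.random() < 0.6 else "M"
        for k in range(config.fixes_per_animal):
            rows.append(
                {
                    "animal_id": f"P{a:03d}",
                    "sex": sex,
                    "birth_date": birth,
                    "fix_datetime": times[k],
                    "x": xy[k, 0],
                    "y": xy[k, 1],
                }
            )
    fixes = pd.DataFrame(rows)
    truth = GroundTruth(
        utilization=w,
        preference_coefs=dict(config.preference_coefs),
        depth_optimum_m=config.depth_optimum_m,
        depth_curvature=config.depth_curvature,
        home_range_centers=hr_centers,
    )
    return fixes, truth
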