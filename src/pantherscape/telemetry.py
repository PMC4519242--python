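"""Telemetry filtering, MCP home ranges, presence labels and home-range summaries.

Radio-telemetry fixes (animal id, sex, birth date, timestamp, x, y) are
filtered to resident breeding adults: fixes inside the study window and
study area, animal at least 3 years old at the fix, and animals with at
least 50 qualifying fixes.  Each retained animal gets a 100% minimum convex
polygon (convex hull) home range.  A grid cell containing at least one
filtered fix is labelled present; all other cells are true absences under
the presence–absence design.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from .grid import Grid

logger = logging.getLogger(__name__)

FIX_COLUMNS = ["animal_id", "sex", "birth_date", "fix_datetime", "x", "y"]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class FilterRules:
    """Residency filters for the presence–absence design."""

    window_start: pd.Timestamp = pd.Timestamp("2004-01-01")
    window_end: pd.Timestamp = pd.Timestamp("2013-12-31")
    min_age_years: float = 3.0
    min_fixes: int = 50

    def __post_init__(self) -> None:
        if self.min_fixes < 1:
            raise ValueError("min_fixes must be >= 1")
        if self.window_start >= self.window_end:
            raise ValueError("filter window start must precede end")


@dataclass
class HomeRange:
    """100% minimum convex polygon home range for one animal."""

    animal_id: str
    sex: str
    mcp: Polygon
    n_fixes: int
    mean_P: float | None = None

    @property
    def area_km2(self) -> float:
        return self.mcp.area / 1e6


def _validate_fixes(fixes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FIX_COLUMNS if c not in fixes.columns]
    if missing:
        raise ValueError(f"telemetry frame missing columns: {missing}")
    fixes = fixes.copy()
    fixes["birth_date"] = pd.to_datetime(fixes["birth_date"])
    fixes["fix_datetime"] = pd.to_datetime(fixes["fix_datetime"])
    if (fixes["fix_datetime"] <= fixes["birth_date"]).any():
        raise ValueError("fix timestamps must postdate birth dates")
    if not np.isfinite(fixes[["x", "y"]].to_numpy(dtype=float)).all():
        raise ValueError("non-finite fix coordinates")
    return fixes


def filter_fixes(
    fixes: pd.DataFrame,
    rules: FilterRules | None = None,
    study_area: Polygon | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Apply the residency filters; returns (kept fixes, per-animal counts).

    Order matters only in that the per-animal minimum-fix cut happens after
    all per-fix filters: window, study-area membership, and age >= 3 years
    (continuous age at fix time).
    """
    rules = rules or FilterRules()
    fixes = _validate_fixes(fixes)
    keep = (fixes["fix_datetime"] >= rules.window_start) & (
        fixes["fix_datetime"] <= rules.window_end
    )
    age_years = (fixes["fix_datetime"] - fixes["birth_date"]).dt.total_seconds() / (
        86400.0 * DAYS_PER_YEAR
    )
    keep &= age_years >= rules.min_age_years
    if study_area is not None:
        prepared = prep(study_area)
        inside = np.array(
            [prepared.intersects(Point(x, y)) for x, y in zip(fixes["x"], fixes["y"])]
        )
        keep &= inside
    kept = fixes.loc[keep]
    counts = kept.groupby("animal_id").size()
    good_animals = counts[counts >= rules.min_fixes].index
    dropped = counts.index.difference(good_animals)
    if len(dropped):
        logger.info("dropping %d animals with < %d fixes", len(dropped), rules.min_fixes)
    kept = kept[kept["animal_id"].isin(good_animals)].reset_index(drop=True)
    if kept.empty:
        logger.warning("no fixes survive the residency filters")
    return kept, counts.reindex(good_animals)


def mcp_home_range(fixes: pd.DataFrame) -> HomeRange:
    """100% minimum convex polygon (convex hull) of one animal's fixes."""
    animals = fixes["animal_id"].unique()
    if len(animals) != 1:
        raise ValueError("mcp_home_range expects fixes from a single animal")
    pts = fixes[["x", "y"]].to_numpy(dtype=float)
    unique_pts = np.unique(pts, axis=0)
    if len(unique_pts) < 3 or _collinear(unique_pts):
        raise ValueError(f"degenerate home range for {animals[0]}: need >= 3 non-collinear fixes")
    hull = ConvexHull(unique_pts)
    poly = Polygon(unique_pts[hull.vertices])
    return HomeRange(
        animal_id=str(animals[0]),
        sex=str(fixes["sex"].iloc[0]),
        mcp=poly,
        n_fixes=len(fixes),
    )


def _collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    d = pts[1:] - pts[0]
    norms = np.hypot(d[:, 0], d[:, 1])
    if norms.max() == 0:
        return True
    ref = d[np.argmax(norms)]
    cross = d[:, 0] * ref[1] - d[:, 1] * ref[0]
    span = max(norms.max(), 1.0)
    return bool(np.abs(cross).max() <= tol * span**2)


def label_presence(
    grid: Grid,
    fixes: pd.DataFrame,
    cells: list[tuple[int, int]] | None = None,
) -> pd.Series:
    """Presence (1) for cells containing >= 1 filtered fix, else absence (0).

    Fixes outside the grid produce a warning and are ignored; a fix exactly
    on a shared cell boundary counts in the lower-left cell only.
    """
    ids = list(grid.cell_ids()) if cells is None else list(cells)
    index = pd.MultiIndex.from_tuples(ids, names=["col", "row"])
    presence = pd.Series(0, index=index, name="presence", dtype=int)
    if len(fixes) == 0:
        return presence
    member = set(index)
    xy = fixes[["x", "y"]].to_numpy(dtype=float)
    inside = np.array([grid.contains(x, y) for x, y in xy])
    n_out = int((~inside).sum())
    if n_out:
        logger.warning("%d fixes outside the grid ignored", n_out)
    if inside.any():
        assigned = grid.assign_many(xy[inside])
        for col, row in map(tuple, assigned):
            if (col, row) in member:
                presence.loc[(col, row)] = 1
    return presence


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact permutation distribution of the rank sum (on midranks) when the
    combined sample size is <= 20; otherwise the normal approximation with
    tie correction.  Stated explicitly so reported p-values are exactly
    reproducible.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    w_obs = ranks[:n1].sum()
    n = n1 + n2
    if n <= 20:
        # exact: enumerate all C(n, n1) assignments of ranks to group a
        total = math.comb(n, n1)
        mean = n1 * (n + 1) / 2.0
        count = 0
        obs_dev = abs(w_obs - mean)
        for combo in itertools.combinations(range(n), n1):
            w = ranks[list(combo)].sum()
            if abs(w - mean) >= obs_dev - 1e-12:
                count += 1
        return count / total
    # tie-corrected normal approximation
    mean = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    from scipy.stats import norm

    z = (w_obs - mean) / math.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


def home_range_P(
    home_ranges: list[HomeRange],
    table: pd.DataFrame,
    grid: Grid,
    p_column: str = "P",
) -> tuple[pd.DataFrame, dict]:
    """Mean predicted P within each home range, sex medians, rank-sum test.

    A cell is inside a home range when its center lies inside the MCP.
    Animals whose MCP contains no cell centers are flagged and excluded
    from the group summaries.
    """
    if p_column not in table.columns:
        raise ValueError(f"feature table lacks a fitted {p_column!r} column")
    centers = {cid: grid.cell_center(*cid) for cid in table.index}
    rows = []
    for hr in home_ranges:
        prepared = prep(hr.mcp)
        member = [
            cid for cid, (cx, cy) in centers.items() if prepared.contains(Point(cx, cy))
        ]
        if not member:
            logger.warning("home range %s contains no cell centers", hr.animal_id)
            rows.append(
                {"animal_id": hr.animal_id, "sex": hr.sex, "n_cells": 0, "mean_P": np.nan}
            )
            continue
        mean_p = float(table.loc[member, p_column].mean())
        hr.mean_P = mean_p
        rows.append(
            {"animal_id": hr.animal_id, "sex": hr.sex, "n_cells": len(member), "mean_P": mean_p}
        )
    per_animal = pd.DataFrame(rows)
    valid = per_animal.dropna(subset=["mean_P"])
    males = valid.loc[valid["sex"] == "M", "mean_P"].to_numpy()
    females = valid.loc[valid["sex"] == "F", "mean_P"].to_numpy()
    summary = {
        "median_P": float(valid["mean_P"].median()) if len(valid) else np.nan,
        "median_P_male": float(np.median(males)) if len(males) else np.nan,
        "median_P_female": float(np.median(females)) if len(females) else np.nan,
        "rank_sum_p": (
            wilcoxon_rank_sum(males, females) if len(males) and len(females) else np.nan
        ),
    }
    return per_animal, summary
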