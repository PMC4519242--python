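"""Stratified one-at-a-time sensitivity analysis of the fitted model.

Classic one-at-a-time response curves hold the other covariates at a single
central value, but in a real landscape no cell has every covariate at its
median simultaneously — good habitat has the beneficial covariates high and
the detrimental ones low, and vice versa.  The analysis therefore
stratifies cells into excellent (P = 0.85–0.95), medium (P = 0.45–0.55) and
poor (P = 0.05–0.15) habitat, fixes the non-swept covariates at the
*stratum-specific* means, and sweeps each covariate over its observed range
within each stratum's context.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import FittedHabitatModel

logger = logging.getLogger(__name__)

#: default habitat strata as closed P intervals
DEFAULT_STRATA: dict[str, tuple[float, float]] = {
    "excellent": (0.85, 0.95),
    "medium": (0.45, 0.55),
    "poor": (0.05, 0.15),
}


@dataclass
class SensitivityStrata:
    """Cells grouped by predicted P, with per-stratum covariate means."""

    ranges: dict[str, tuple[float, float]]
    members: dict[str, pd.Index]
    means: dict[str, pd.Series]  # stratum -> mean covariate vector

    def non_empty(self) -> list[str]:
        return [s for s, m in self.members.items() if len(m) > 0]


@dataclass
class ResponseCurve:
    covariate: str
    stratum: str
    x: np.ndarray
    P: np.ndarray

    @property
    def delta_P(self) -> float:
        return float(self.P.max() - self.P.min())


def build_strata(
    table: pd.DataFrame,
    model: FittedHabitatModel,
    ranges: dict[str, tuple[float, float]] | None = None,
    p_column: str = "P",
) -> SensitivityStrata:
    """Group cells into habitat-quality strata and average their covariates.

    Interval bounds are closed (a cell at exactly P = 0.85 belongs to the
    excellent stratum).  An empty stratum is flagged, not an error, unless
    all strata are empty.
    """
    ranges = dict(ranges or DEFAULT_STRATA)
    _check_disjoint(ranges)
    if p_column not in table.columns:
        raise ValueError(f"feature table lacks a fitted {p_column!r} column")
    p = table[p_column]
    members: dict[str, pd.Index] = {}
    means: dict[str, pd.Series] = {}
    for name, (lo, hi) in ranges.items():
        mask = (p >= lo) & (p <= hi)
        members[name] = table.index[mask]
        if mask.any():
            means[name] = table.loc[mask, model.feature_names].mean()
        else:
            logger.warning("stratum %r (P in [%.2f, %.2f]) is empty", name, lo, hi)
            means[name] = pd.Series(np.nan, index=model.feature_names)
    if all(len(m) == 0 for m in members.values()):
        raise ValueError("model range too narrow: all sensitivity strata are empty")
    return SensitivityStrata(ranges=ranges, members=members, means=means)


def _check_disjoint(ranges: dict[str, tuple[float, float]]) -> None:
    spans = sorted(ranges.values())
    for (a_lo, a_hi), (b_lo, b_hi) in zip(spans, spans[1:]):
        if b_lo <= a_hi:
            raise ValueError("strata P-ranges must be non-overlapping")


def sweep(
    model: FittedHabitatModel,
    strata: SensitivityStrata,
    table: pd.DataFrame,
    covariate: str,
    n_points: int = 50,
) -> list[ResponseCurve]:
    """Response curves for one covariate, one per non-empty stratum.

    Synthetic predictor rows are the stratum mean vector with the target
    covariate replaced by each of ``n_points`` equally spaced values over
    its observed range in the full table.  Cover fractions are swept
    without renormalising sibling fractions — the one-at-a-time design,
    accepting compositionally impossible rows.
    """
    if covariate not in model.feature_names:
        raise ValueError(f"{covariate!r} is not a model covariate")
    lo = float(table[covariate].min())
    hi = float(table[covariate].max())
    xs = np.linspace(lo, hi, n_points)
    j = model.feature_names.index(covariate)
    curves = []
    for name in strata.ranges:
        if len(strata.members[name]) == 0:
            warnings.warn(f"stratum {name!r} empty; sweep skipped")
            continue
        base = strata.means[name].to_numpy(dtype=float)
        rows = np.tile(base, (n_points, 1))
        rows[:, j] = xs
        curves.append(ResponseCurve(covariate=covariate, stratum=name, x=xs, P=model.predict_P(rows)))
    return curves


def report_effects(curves: list[ResponseCurve], flat_tol: float = 1e-9) -> pd.DataFrame:
    """Effect-size table: ΔP, direction and extremum location per curve.

    Direction is "none" for a flat curve, "positive"/"negative" when the
    overall trend (P at range end minus range start) is monotone-signed,
    and "peaked" when the curve's extremum lies strictly inside the range.
    """
    rows = []
    for c in curves:
        dp = c.delta_P
        if dp <= flat_tol:
            direction = "none"
            argext = c.x[0]
        else:
            i_max = int(np.argmax(c.P))
            i_min = int(np.argmin(c.P))
            end_diff = c.P[-1] - c.P[0]
            interior_peak = 0 < i_max < len(c.x) - 1 and c.P[i_max] > max(c.P[0], c.P[-1]) + flat_tol
            if interior_peak:
                direction = "peaked"
                argext = c.x[i_max]
            elif end_diff > 0:
                direction = "positive"
                argext = c.x[i_max]
            else:
                direction = "negative"
                argext = c.x[i_min]
        rows.append(
            {
                "covariate": c.covariate,
                "stratum": c.stratum,
                "delta_P": dp,
                "direction": direction,
                "extremum_x": float(argext),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        # stratum of maximal effect per covariate
        idx = df.groupby("covariate")["delta_P"].idxmax()
        df["max_effect_stratum"] = df["covariate"].map(
            df.loc[idx].set_index("covariate")["stratum"]
        )
    return df


def curves_to_frame(curves: list[ResponseCurve]) -> pd.DataFrame:
    """Tidy (covariate, stratum, x, P) frame for CSV export / plotting."""
    frames = [
        pd.DataFrame(
            {"covariate": c.covariate, "stratum": c.stratum, "x": c.x, "P": c.P}
        )
        for c in curves
    ]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["covariate", "stratum", "x", "P"]
    )


def plot_curves(curves: list[ResponseCurve], path) -> None:
    """Line plots of the response curves, one panel per covariate."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    covs = sorted({c.covariate for c in curves})
    n = len(covs)
    ncols = min(3, max(1, n))
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows), squeeze=False)
    for k, cov in enumerate(covs):
        ax = axes[k // ncols][k % ncols]
        for c in (c for c in curves if c.covariate == cov):
            ax.plot(c.x, c.P, label=c.stratum)
        ax.set_title(cov)
        ax.set_ylim(0, 1)
        ax.set_ylabel("P")
    for k in range(n, nrows * ncols):
        axes[k // ncols][k % ncols].axis("off")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
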