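"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a quantity by the most naive correct method —
confusion-matrix arithmetic, pairwise concordance counts, point-sampling
Monte Carlo, O(n³) extreme-point enumeration — sharing no code with the
implementation paths they validate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import Point


def confusion_and_auc_oracle(labels, probs, threshold):
    """(pcc, sens, spec, kappa, auc) by direct counting."""
    labels = np.asarray(labels)
    probs = np.asarray(probs)
    pred = probs >= threshold
    tp = np.sum(pred & (labels == 1))
    tn = np.sum(~pred & (labels == 0))
    fp = np.sum(pred & (labels == 0))
    fn = np.sum(~pred & (labels == 1))
    n = len(labels)
    pcc = 100 * (tp + tn) / n
    sens = 100 * tp / (tp + fn)
    spec = 100 * tn / (tn + fp)
    p_o = (tp + tn) / n
    p_yes = ((tp + fp) / n) * ((tp + fn) / n)
    p_no = ((fn + tn) / n) * ((fp + tn) / n)
    kappa = (p_o - (p_yes + p_no)) / (1 - (p_yes + p_no))
    conc = 0.0
    npairs = 0
    for i in np.where(labels == 1)[0]:
        for j in np.where(labels == 0)[0]:
            npairs += 1
            if probs[i] > probs[j]:
                conc += 1
            elif probs[i] == probs[j]:
                conc += 0.5
    return pcc, sens, spec, kappa, conc / npairs


def mc_cover_fractions(grid, layer, n_points=100_000, seed=0):
    """Per-cell category fractions by point-in-polygon sampling."""
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = grid.bounds
    pts = rng.uniform([xmin, ymin], [xmax, ymax], size=(n_points, 2))
    tree = STRtree(layer.geometries)
    cats = np.empty(n_points, dtype=object)
    for i, (x, y) in enumerate(pts):
        p = Point(x, y)
        for j in tree.query(p):
            if layer.geometries[int(j)].covers(p):
                cats[i] = layer.categories[int(j)]
                break
    cells = grid.assign_many(pts)
    df = pd.DataFrame({"col": cells[:, 0], "row": cells[:, 1], "cat": cats})
    return df.groupby(["col", "row"])["cat"].value_counts(normalize=True)


def mc_human_density(grid, blocks, n_points=100_000, seed=0):
    """Per-cell mean density by point sampling of the block mosaic."""
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = grid.bounds
    pts = rng.uniform([xmin, ymin], [xmax, ymax], size=(n_points, 2))
    geoms = [g for g, _ in blocks]
    dens = np.array([pop / (g.area / 1e6) for g, pop in blocks])
    tree = STRtree(geoms)
    sampled = np.zeros(n_points)
    for i, (x, y) in enumerate(pts):
        p = Point(x, y)
        for j in tree.query(p):
            if geoms[int(j)].covers(p):
                sampled[i] = dens[int(j)]
                break
    cells = grid.assign_many(pts)
    df = pd.DataFrame({"col": cells[:, 0], "row": cells[:, 1], "d": sampled})
    return df.groupby(["col", "row"])["d"].mean()


def hull_vertices_oracle(pts: np.ndarray) -> set[tuple[float, float]]:
    """Convex-hull vertex set by O(n³) edge enumeration."""
    import itertools

    out = set()
    n = len(pts)
    for a, b in itertools.permutations(range(n), 2):
        d = pts - pts[a]
        e = pts[b] - pts[a]
        cross = d[:, 0] * e[1] - d[:, 1] * e[0]
        if (cross >= -1e-9).all() or (cross <= 1e-9).all():
            out.add((round(pts[a][0], 6), round(pts[a][1], 6)))
            out.add((round(pts[b][0], 6), round(pts[b][1], 6)))
    return out


def random_cell_tessellation(seed=0, n_polys=20):
    """Random ~20-polygon Voronoi tessellation of a single 1-km cell."""
    from pantherscape.cover import CATEGORIES, CategoryMap
    from pantherscape.features import CoverLayer
    from pantherscape.synth import _bounded_voronoi

    rng = np.random.default_rng(seed)
    pts = rng.uniform(0.0, 1000.0, size=(n_polys, 2))
    polys, _ = _bounded_voronoi(pts, 1000.0)
    cats = [CATEGORIES[i] for i in rng.integers(0, len(CATEGORIES), n_polys)]
    keep = [i for i, p in enumerate(polys) if not p.is_empty and p.area > 0]
    return CoverLayer([polys[i] for i in keep], [cats[i] for i in keep], CategoryMap.identity())
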