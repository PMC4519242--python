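"""Shared fixtures: a small synthetic world, reused across test modules.

The session-scoped ``small_world`` landscape (20 km x 20 km, 8 animals) is
big enough for the classifier to find the planted signal but cheap enough
to build once and share.  Tests that need the full-size default landscape
build it themselves.
"""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import box

import pantherscape.model as pmodel
import pantherscape.synth as psynth
from pantherscape.cover import EdgeRules
from pantherscape.features import assemble_features
from pantherscape.hydrology import SeasonConfig, seasonal_depth
from pantherscape.synth import SyntheticConfig
from pantherscape.telemetry import filter_fixes, label_presence


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        extent_km=20, n_animals=8, fixes_per_animal=150, seed=7
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """Dict with every artifact of a small end-to-end synthetic build."""
    sc = small_config
    layer = psynth.generate_cover(sc)
    elevation, gauges, depth_truth = psynth.generate_hydrology(sc)
    blocks, roads = psynth.generate_anthropogenic(sc)
    grid = sc.grid
    table = assemble_features(grid, layer, blocks, roads, EdgeRules())
    season = SeasonConfig(start_year=sc.start_year, end_year=sc.end_year)
    table = table.join(seasonal_depth(gauges, elevation, grid, season))
    fixes, truth = psynth.simulate_telemetry(sc, table)
    kept, counts = filter_fixes(fixes, study_area=box(*grid.bounds))
    table["presence"] = label_presence(grid, kept)
    return {
        "config": sc,
        "layer": layer,
        "elevation": elevation,
        "gauges": gauges,
        "blocks": blocks,
        "roads": roads,
        "grid": grid,
        "table": table,
        "fixes": kept,
        "truth": truth,
        "season": season,
    }


@pytest.fixture(scope="session")
def small_model(small_world):
    """Forest fitted on the small world, with OOB P attached to the table."""
    table = small_world["table"]
    fitted = pmodel.fit(table, pmodel.ModelConfig(seed=7))
    table = table.copy()
    table["P"] = fitted.oob_P
    return fitted, table


def random_labels_probs(rng: np.random.Generator, n: int):
    """Random binary labels (both classes present) with uniform scores."""
    while True:
        labels = rng.integers(0, 2, size=n)
        if 0 < labels.sum() < n:
            return labels, rng.random(n)
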