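"""Land-cover vocabulary: the 10 aggregated categories, code mapping, edge rules.

Raw cover polygons carry fine-grained class codes (in south Florida these
come from the FLUCCS taxonomy, 124 classes).  The analysis aggregates them
into 10 major categories chosen for their meaning to panthers: cover
(forest, shrub), openness, human disturbance (urban, agriculture) and
avoided types (open water, saltwater wetland).  The mapping from raw codes
to categories is configuration, not code.
"""

from __future__ import annotations

from dataclasses import dataclass

# canonical category keys, in the conventional reporting order
OPEN_FRESHWATER_WETLAND = "open_freshwater_wetland"
WETLAND_FOREST = "wetland_forest"
AGRICULTURE = "agriculture"
SALTWATER_WETLAND = "saltwater_wetland"
GRASSLAND = "grassland"
WET_SHRUB = "wet_shrub"
URBAN = "urban"
UPLAND_FOREST = "upland_forest"
OPEN_WATER = "open_water"
UPLAND_SHRUB = "upland_shrub"

CATEGORIES: tuple[str, ...] = (
    OPEN_FRESHWATER_WETLAND,
    WETLAND_FOREST,
    AGRICULTURE,
    SALTWATER_WETLAND,
    GRASSLAND,
    WET_SHRUB,
    URBAN,
    UPLAND_FOREST,
    OPEN_WATER,
    UPLAND_SHRUB,
)

# short column labels used in the exported feature table / importance plots
COVER_ABBREV: dict[str, str] = {
    OPEN_FRESHWATER_WETLAND: "FW_Wet",
    WETLAND_FOREST: "Wet_For",
    AGRICULTURE: "Ag",
    SALTWATER_WETLAND: "SW_Wet",
    GRASSLAND: "Grass",
    WET_SHRUB: "Wet_Shrub",
    URBAN: "Urban",
    UPLAND_FOREST: "Up_For",
    OPEN_WATER: "Water",
    UPLAND_SHRUB: "Up_Shrub",
}

# the 5 non-cover covariates, same abbreviation convention
EXTRA_COVARIATES: tuple[str, ...] = (
    "For_Edge",   # forest edge, km per cell
    "dry_depth",  # mean dry-season water depth, m
    "wet_depth",  # mean wet-season water depth, m
    "Pop_Dens",   # area-weighted human density, people/km^2
    "Rd_Dens",    # road length, km per cell
)

#: all 15 model covariates, in reporting order
COVARIATES: tuple[str, ...] = tuple(COVER_ABBREV[c] for c in CATEGORIES) + EXTRA_COVARIATES

#: study-area composition used as the default synthetic cover mix
#: (fractions of total area; mostly-wetland landscape)
DEFAULT_COVER_MIX: dict[str, float] = {
    OPEN_FRESHWATER_WETLAND: 0.343,
    WETLAND_FOREST: 0.147,
    AGRICULTURE: 0.097,
    SALTWATER_WETLAND: 0.088,
    GRASSLAND: 0.076,
    WET_SHRUB: 0.082,
    URBAN: 0.069,
    UPLAND_FOREST: 0.054,
    OPEN_WATER: 0.023,
    UPLAND_SHRUB: 0.021,
}


@dataclass(frozen=True)
class CategoryMap:
    """Total mapping raw class code -> one of the 10 categories."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad = {cat for cat in self.mapping.values() if cat not in CATEGORIES}
        if bad:
            raise ValueError(f"unknown categories in mapping: {sorted(bad)}")

    def category(self, code: str) -> str:
        try:
            return self.mapping[str(code)]
        except KeyError:
            raise ValueError(f"unmapped cover class code: {code!r}") from None

    @classmethod
    def identity(cls) -> "CategoryMap":
        """Each category maps to itself — for layers already aggregated."""
        return cls({c: c for c in CATEGORIES})


@dataclass(frozen=True)
class EdgeRules:
    """Which category adjacencies count as forest edge.

    Forest edge is the boundary between a forest polygon and a cover type
    that forms a natural edge (a proxy for white-tailed-deer hunting
    habitat).  Urban, agriculture and saltwater wetland do not form edge;
    grassland, freshwater open water, shrubs and open freshwater wetland
    do.  The upland-forest / wetland-forest boundary itself also counts.
    """

    forest: frozenset[str] = frozenset({UPLAND_FOREST, WETLAND_FOREST})
    edge_forming: frozenset[str] = frozenset(
        {GRASSLAND, OPEN_WATER, UPLAND_SHRUB, WET_SHRUB, OPEN_FRESHWATER_WETLAND}
    )
    non_edge_forming: frozenset[str] = frozenset({URBAN, AGRICULTURE, SALTWATER_WETLAND})
    forest_forest_counts: bool = True

    def __post_init__(self) -> None:
        sets = [self.forest, self.edge_forming, self.non_edge_forming]
        union = frozenset().union(*sets)
        if union != frozenset(CATEGORIES):
            raise ValueError("edge rule sets must cover all 10 categories")
        if sum(len(s) for s in sets) != len(union):
            raise ValueError("edge rule sets must be disjoint")

    def is_edge_pair(self, cat_a: str, cat_b: str) -> bool:
        """True when a boundary between the two categories is forest edge."""
        if cat_a == cat_b:
            return False
        pair = {cat_a, cat_b}
        if pair == self.forest:
            return self.forest_forest_counts
        if (cat_a in self.forest and cat_b in self.edge_forming) or (
            cat_b in self.forest and cat_a in self.edge_forming
        ):
            return True
        return False
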