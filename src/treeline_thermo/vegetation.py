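"""Vegetation scenarios on a fixed 20-layer canopy grid.

Each treeline site pair (Italian Alps ``IT``, US Rocky Mountains ``US``,
Western Canadian taiga-tundra ``CA``) yields four scenarios:

* ``X-For`` — the existing subalpine/sub-Arctic forest (overstory trees plus
  understory), driven by below-treeline forcing;
* ``X-Un``  — counterfactual: that forest's understory alone, same forcing;
* ``X-Alp``/``X-Arc`` — the existing alpine meadow / Arctic tundra, driven
  by above-treeline forcing;
* ``X-Tr``  — counterfactual: the forest's vegetation transplanted above the
  treeline, driven by the above-treeline forcing.

Species are aggregated into functional groups (evergreen needleleaf trees,
suppressed deciduous trees, shrubs, grasses/sedges). Leaf area is
distributed uniformly within each group's vertical extent over the 20
above-ground layers; non-evergreen groups green up with a 30-day cosine
ramp once the ground is snow-free and senesce in autumn; any group whose
canopy top is at or below the snow surface is buried and contributes no
effective leaf area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "FunctionalGroup",
    "VegetationScenario",
    "CanopyGrid",
    "seasonal_lai",
    "leaf_area_density_profile",
    "make_counterfactual",
    "SITE_DEFINITIONS",
    "build_table1_scenarios",
    "load_scenario",
]

N_CANOPY_LAYERS = 20
N_SOIL_LAYERS = 12

TREE_GROUPS = {"evergreen_needleleaf_tree", "deciduous_tree_suppressed"}
GROUP_NAMES = TREE_GROUPS | {"shrub", "grass_or_sedge"}

# default phenology window (doy) for non-evergreen groups; green-up start is
# overridden at run time by the first snow-free day
DEFAULT_GREENUP_START = 120
GREENUP_RAMP_DAYS = 30
DEFAULT_SENESCENCE_START = 250
SENESCENCE_RAMP_DAYS = 30


@dataclass(frozen=True)
class FunctionalGroup:
    """One aggregated vegetation class and its physiology defaults.

    ``max_LAI`` is one-sided leaf area per ground area (m2/m2);
    ``photosynthetic_capacity`` and ``respiration_base`` are per unit leaf
    area (umol CO2 m-2 leaf s-1), the latter at the 10 C reference.
    """

    name: str
    max_LAI: float
    canopy_top: float
    canopy_bottom: float = 0.0
    evergreen: bool = False
    stem_area_index: float = 0.0
    leaf_reflectance: float = 0.1
    photosynthetic_capacity: float = 10.0
    respiration_base: float = 0.5

    def __post_init__(self) -> None:
        if self.name not in GROUP_NAMES:
            raise ValueError(f"unknown functional group name {self.name!r}")
        if not 0.0 <= self.canopy_bottom < self.canopy_top:
            raise ValueError("need 0 <= canopy_bottom < canopy_top")
        if self.max_LAI < 0:
            raise ValueError("max_LAI must be >= 0")

    @property
    def is_tree(self) -> bool:
        return self.name in TREE_GROUPS


@dataclass(frozen=True)
class VegetationScenario:
    """A labelled vegetation structure plus the ecosystem height h_e.

    ``h_e`` is the ecosystem height of the site *pair* (the maximum canopy
    height among the paired scenarios); it is the depth of the control
    volume used for the resultant temperature gradient.
    """

    label: str
    groups: tuple[FunctionalGroup, ...]
    h_e: float
    is_counterfactual: bool = False
    forcing_site: str = ""

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("scenario needs at least one functional group")
        top = max(g.canopy_top for g in self.groups)
        if self.h_e < top:
            raise ValueError(f"h_e={self.h_e} below tallest canopy top {top}")

    @property
    def canopy_height(self) -> float:
        return max(g.canopy_top for g in self.groups)

    @property
    def tree_groups(self) -> tuple[FunctionalGroup, ...]:
        return tuple(g for g in self.groups if g.is_tree)

    @property
    def overstory_groups(self) -> tuple[FunctionalGroup, ...]:
        """Overstory = evergreen needleleaf trees; a suppressed deciduous
        tree layer counts as understory."""
        return tuple(g for g in self.groups
                     if g.name == "evergreen_needleleaf_tree")


@dataclass
class CanopyGrid:
    """Fixed vertical grid: 20 above-ground layers spanning [0, h_e].

    ``edges`` has 21 entries; ``lad`` holds the current per-layer,
    per-group leaf area (m2/m2 per layer), shape (n_groups, 20).
    """

    h_e: float
    edges: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.h_e <= 0:
            raise ValueError("h_e must be positive")
        self.edges = np.linspace(0.0, self.h_e, N_CANOPY_LAYERS + 1)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def seasonal_lai(
    group: FunctionalGroup,
    day_of_year: int,
    snow_depth: float,
    greenup_start: int = DEFAULT_GREENUP_START,
) -> float:
    """Current effective LAI of one group (m2/m2).

    Evergreen groups hold ``max_LAI`` year-round; non-evergreen groups ramp
    up with a 30-day cosine from ``greenup_start`` (by default a fixed
    calendar day; the simulator passes the first snow-free day) and ramp
    down over 30 days from the senescence start. A group whose canopy top
    is at or below the snow surface is buried and returns 0.
    """
    if not 1 <= day_of_year <= 365:
        raise ValueError("day_of_year must be in [1, 365]")
    if snow_depth >= group.canopy_top:
        return 0.0
    if group.evergreen:
        return group.max_LAI
    return group.max_LAI * phenology_fraction(day_of_year, greenup_start)


def phenology_fraction(day_of_year: int, greenup_start: int,
                       senescence_start: int = DEFAULT_SENESCENCE_START) -> float:
    """Smooth 0..1 green-up/senescence factor for deciduous phenology."""
    d = day_of_year
    if d < greenup_start or d >= senescence_start + SENESCENCE_RAMP_DAYS:
        return 0.0
    if d < greenup_start + GREENUP_RAMP_DAYS:
        x = (d - greenup_start) / GREENUP_RAMP_DAYS
        return 0.5 * (1.0 - math.cos(math.pi * x))
    if d < senescence_start:
        return 1.0
    x = (d - senescence_start) / SENESCENCE_RAMP_DAYS
    return 0.5 * (1.0 + math.cos(math.pi * x))


def _overlap_weights(grid: CanopyGrid, bottom: float, top: float) -> np.ndarray:
    """Fraction of a group's vertical extent in each layer (sums to 1)."""
    lo = np.minimum(np.maximum(grid.edges[:-1], bottom), top)
    hi = np.minimum(np.maximum(grid.edges[1:], bottom), top)
    overlap = np.maximum(hi - lo, 0.0)
    total = overlap.sum()
    if total <= 0:
        raise ValueError(
            f"group extent [{bottom}, {top}] does not overlap the grid")
    return overlap / total


def leaf_area_density_profile(
    scenario: VegetationScenario,
    day_of_year: int,
    snow_depth: float,
    grid: CanopyGrid | None = None,
    greenup_start: int = DEFAULT_GREENUP_START,
) -> np.ndarray:
    """Per-group, per-layer leaf area (m2/m2), shape (n_groups, 20).

    Each group's current LAI is spread uniformly over the layers that
    intersect its [canopy_bottom, canopy_top] extent; the column sum equals
    the sum of group effective LAIs.
    """
    grid = grid or CanopyGrid(scenario.h_e)
    lad = np.zeros((len(scenario.groups), N_CANOPY_LAYERS))
    for i, g in enumerate(scenario.groups):
        lai = seasonal_lai(g, day_of_year, snow_depth, greenup_start)
        if lai > 0:
            lad[i] = lai * _overlap_weights(grid, g.canopy_bottom, g.canopy_top)
    return lad


def make_counterfactual(
    below_treeline: VegetationScenario,
    above_treeline: VegetationScenario,
) -> tuple[VegetationScenario, VegetationScenario]:
    """Build the two counterfactuals of a site pair.

    ``X-Tr`` carries the below-treeline (forest) vegetation but will be
    driven by the above-treeline forcing; ``X-Un`` is the forest understory
    alone (everything below the evergreen-needleleaf overstory, including
    a suppressed deciduous tree layer) under the below-treeline forcing.
    Both members of the pair share h_e, the maximum canopy height in the
    pair.
    """
    if not below_treeline.overstory_groups:
        raise ValueError("below-treeline scenario has no overstory tree group")
    if above_treeline.tree_groups:
        raise ValueError("above-treeline scenario already has trees")
    h_e = max(below_treeline.canopy_height, above_treeline.canopy_height)
    prefix = below_treeline.label.split("-")[0]
    x_tr = VegetationScenario(
        label=f"{prefix}-Tr",
        groups=below_treeline.groups,
        h_e=h_e,
        is_counterfactual=True,
        forcing_site=above_treeline.forcing_site,
    )
    understory = tuple(g for g in below_treeline.groups
                       if g.name != "evergreen_needleleaf_tree")
    if not understory:
        raise ValueError("forest scenario has no understory group")
    x_un = VegetationScenario(
        label=f"{prefix}-Un",
        groups=understory,
        h_e=h_e,
        is_counterfactual=True,
        forcing_site=below_treeline.forcing_site,
    )
    return x_tr, x_un


def _ent(max_lai: float, top: float, bottom: float) -> FunctionalGroup:
    return FunctionalGroup(
        name="evergreen_needleleaf_tree", max_LAI=max_lai, canopy_top=top,
        canopy_bottom=bottom, evergreen=True, stem_area_index=0.5,
        photosynthetic_capacity=10.0, respiration_base=0.35)


#: Site vegetation definitions for the three treeline pairs. Group LAI
#: defaults: trees 4.0 (temperate forests), 0.5 for the sparse sub-Arctic
#: forest-tundra site, shrubs 1.0, grasses/sedges 1.5, suppressed deciduous
#: understory trees 1.0. Heights are plausible stand heights per site.
SITE_DEFINITIONS: dict[str, dict] = {
    "Lav": {  # subalpine fir forest, suppressed beech understory (IT, below)
        "pair": "IT", "position": "below",
        "groups": [
            _ent(4.0, 25.0, 2.0),
            FunctionalGroup(name="deciduous_tree_suppressed", max_LAI=1.0,
                            canopy_top=2.0, canopy_bottom=0.2,
                            stem_area_index=0.3,
                            photosynthetic_capacity=9.0, respiration_base=0.35),
        ],
    },
    "MBo": {  # alpine meadow, perennial bunchgrass (IT, above)
        "pair": "IT", "position": "above",
        "groups": [
            FunctionalGroup(name="grass_or_sedge", max_LAI=1.5, canopy_top=0.3,
                            photosynthetic_capacity=12.0, respiration_base=0.3),
        ],
    },
    "NR1": {  # subalpine spruce-fir forest, sparse shrub understory (US, below)
        "pair": "US", "position": "below",
        "groups": [
            _ent(4.0, 12.0, 1.0),
            FunctionalGroup(name="shrub", max_LAI=1.0, canopy_top=0.5,
                            stem_area_index=0.3,
                            photosynthetic_capacity=10.0, respiration_base=0.35),
        ],
    },
    "T-Van": {  # alpine fellfield, curly sedge (US, above)
        "pair": "US", "position": "above",
        "groups": [
            FunctionalGroup(name="grass_or_sedge", max_LAI=1.5, canopy_top=0.2,
                            photosynthetic_capacity=12.0, respiration_base=0.3),
        ],
    },
    "HPC": {  # sparse black-spruce forest-tundra, shrubs (CA, below)
        "pair": "CA", "position": "below",
        "groups": [
            _ent(0.5, 5.0, 0.5),
            FunctionalGroup(name="shrub", max_LAI=1.0, canopy_top=0.5,
                            stem_area_index=0.3,
                            photosynthetic_capacity=10.0, respiration_base=0.35),
        ],
    },
    "TVC": {  # Arctic tundra, short shrubs/grasses (CA, above)
        "pair": "CA", "position": "above",
        "groups": [
            FunctionalGroup(name="shrub", max_LAI=1.0, canopy_top=0.4,
                            stem_area_index=0.3,
                            photosynthetic_capacity=10.0, respiration_base=0.35),
        ],
    },
}

_ABOVE_LABEL = {"IT": "Alp", "US": "Alp", "CA": "Arc"}


def build_table1_scenarios(pair: str | None = None) -> dict[str, VegetationScenario]:
    """Construct the 12 scenarios (4 per site pair) from the 6 site definitions.

    Returns a dict keyed by scenario label, e.g. ``US-For``, ``US-Un``,
    ``US-Alp``, ``US-Tr``. Restrict to one pair with ``pair`` in
    {"IT", "US", "CA"}.
    """
    pairs = [pair] if pair else ["IT", "US", "CA"]
    out: dict[str, VegetationScenario] = {}
    for p in pairs:
        below_site = next(s for s, d in SITE_DEFINITIONS.items()
                          if d["pair"] == p and d["position"] == "below")
        above_site = next(s for s, d in SITE_DEFINITIONS.items()
                          if d["pair"] == p and d["position"] == "above")
        bg = tuple(SITE_DEFINITIONS[below_site]["groups"])
        ag = tuple(SITE_DEFINITIONS[above_site]["groups"])
        h_e = max(g.canopy_top for g in bg + ag)
        x_for = VegetationScenario(label=f"{p}-For", groups=bg, h_e=h_e,
                                   forcing_site=below_site)
        x_existing = VegetationScenario(
            label=f"{p}-{_ABOVE_LABEL[p]}", groups=ag, h_e=h_e,
            forcing_site=above_site)
        x_tr, x_un = make_counterfactual(x_for, x_existing)
        for s in (x_for, x_un, x_existing, x_tr):
            out[s.label] = s
    return out


def load_scenario(source) -> VegetationScenario:
    """Load a scenario from a YAML block (path or string).

    Expected keys: label, h_e, is_counterfactual (optional), forcing_site
    (optional), groups: list of FunctionalGroup field mappings.
    """
    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = yaml.safe_load(source)
    groups = tuple(FunctionalGroup(**g) for g in data.pop("groups"))
    return VegetationScenario(groups=groups, **data)


def scenario_to_yaml(scenario: VegetationScenario) -> str:
    import dataclasses

    data = dataclasses.asdict(scenario)
    data["groups"] = [dataclasses.asdict(g) for g in scenario.groups]
    return yaml.safe_dump(data, sort_keys=False)
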