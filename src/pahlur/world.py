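"""Synthetic study region: terrain, land mosaic, roads, industry, sites.

The generator emulates the data landscape of a mid-sized industrial basin
monitored for air pollution: a rectangular study region with an urbanized
core (artificial surfaces, dense roads, clustered factories), surrounding
agricultural/natural land, a monitoring network of urban, rural and
background sites, a handful of meteorological stations, and a smooth
elevation field.  Everything is drawn from a single seeded RNG, so a
scenario regenerates bit-identically.

No dispersion or emission-inventory realism is attempted; the region only
has to exercise the covariate-extraction and regression machinery with the
spatial structure those stages assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import (
    LineString,
    MultiPoint,
    Point,
    Polygon,
    box,
)
from shapely.ops import voronoi_diagram

from .geoio import AsciiGrid, Feature
from .partition import PartitionParams
from .projection import LocalCRS
from .species import SEASONS, PAHSpecies, default_species

MAX_BUFFER_M = 5000.0


class SizingError(ValueError):
    """The scenario extent cannot accommodate the requested buffers."""


class NoPointSourceError(ValueError):
    """Distance-to-nearest-factory requested with an empty source layer."""


@dataclass
class TrueModel:
    """Ground-truth linear generating model for one (species, season) total.

    ``phase`` is the literal tag "total": concentrations are generated as
    totals and split into phases afterwards by the partition model.
    """

    species: str
    season: str
    intercept: float
    coefficients: dict[str, float]
    noise_sd: float
    detection_limit: float
    phase: str = "total"

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.detection_limit < 0:
            raise ValueError("detection_limit must be >= 0")


@dataclass
class SiteNetwork:
    sites: list[tuple[str, float, float, str]]  # (site_id, x, y, class)

    def ids(self) -> list[str]:
        return [s[0] for s in self.sites]

    def coords(self) -> np.ndarray:
        return np.array([(s[1], s[2]) for s in self.sites])

    def classes(self) -> list[str]:
        return [s[3] for s in self.sites]


@dataclass
class GISWorld:
    land_cover: list[Feature]
    land_use: list[Feature]
    roads: list[Feature]
    point_sources: list[Feature]
    met_stations: list[Feature]
    elevation: AsciiGrid
    boundary: Polygon
    crs: LocalCRS


def _default_true_models(
    species: list[PAHSpecies],
) -> dict[tuple[str, str], TrueModel]:
    """Template ground truth: every compound responds positively to the
    artificial-surface area and motorway length around a site and
    negatively to elevation, at magnitudes matched to the covariate scales
    (buffer areas of order 1e6-1e7 m^2, road lengths of order 1e3-1e4 m,
    elevation of order 1e3 m).  Base levels fall with ring count and rise
    in the heating season for heavy compounds."""
    base_by_rings = {3: 18.0, 4: 8.0, 5: 4.5, 6: 3.5}
    light_season = {"windy": 1.05, "non-heating": 1.0, "heating": 0.95}
    heavy_season = {"windy": 0.9, "non-heating": 0.8, "heating": 1.4}
    out: dict[tuple[str, str], TrueModel] = {}
    for sp in species:
        heavy = sp.ring_count >= 5
        seas_mult = heavy_season if heavy else light_season
        base = base_by_rings[sp.ring_count]
        for season in SEASONS:
            level = base * seas_mult[season]
            out[(sp.name, season)] = TrueModel(
                species=sp.name,
                season=season,
                intercept=level,
                coefficients={
                    "lc2000_80": 7.0e-7 * level / 15.0,
                    "r3000_51": 6.0e-5 * level / 15.0,
                    "dem": -0.008 * level / 15.0,
                },
                noise_sd=0.12 * level,
                detection_limit=0.05,
            )
    return out


@dataclass
class SyntheticScenario:
    """Everything needed to regenerate a study world bit-identically."""

    seed: int = 0
    extent: tuple[float, float, float, float] = (0.0, 0.0, 30_000.0, 24_000.0)
    species: list[PAHSpecies] = field(default_factory=default_species)
    true_models: dict[tuple[str, str], TrueModel] | None = None
    partition: PartitionParams = field(default_factory=PartitionParams)
    season_temperatures: dict[str, float] = field(
        default_factory=lambda: {"windy": 12.0, "non-heating": 20.0, "heating": 0.0}
    )
    # monitoring-network composition: urban / rural / background
    n_urban: int = 19
    n_rural: int = 4
    n_background: int = 2
    n_point_sources: int = 30
    n_met_stations: int = 9
    n_land_cover_seeds: int = 120
    n_land_use_seeds: int = 80
    elevation_cellsize: float = 200.0
    crs: LocalCRS = field(default_factory=LocalCRS)
    # phase-mean calibration targets: (species, season, phase) -> ng/m^3
    calibration_targets: dict[tuple[str, str, str], float] = field(
        default_factory=lambda: {("Ace", "windy", "gaseous"): 16.42}
    )

    def __post_init__(self):
        if self.true_models is None:
            self.true_models = _default_true_models(self.species)
        names = [s.name for s in self.species]
        if len(names) != len(set(names)):
            raise ValueError("species names must be unique")

    @property
    def boundary(self) -> Polygon:
        return box(*self.extent)

    def species_by_name(self) -> dict[str, PAHSpecies]:
        return {s.name: s for s in self.species}


def _check_extent(scenario: SyntheticScenario) -> None:
    xmin, ymin, xmax, ymax = scenario.extent
    area_km2 = (xmax - xmin) * (ymax - ymin) / 1e6
    if area_km2 < 100.0:
        raise SizingError(
            f"extent area {area_km2:.1f} km^2 cannot host "
            f"{MAX_BUFFER_M:.0f} m buffers (need >= 100 km^2)"
        )


def _urban_polygon(extent) -> Polygon:
    xmin, ymin, xmax, ymax = extent
    cx, cy = (xmin + xmax) / 2, (ymin + ymax) / 2
    hw, hh = (xmax - xmin) * 0.22, (ymax - ymin) * 0.22
    return box(cx - hw, cy - hh, cx + hw, cy + hh)


def _voronoi_mosaic(
    rng: np.random.Generator,
    boundary: Polygon,
    n_seeds: int,
    class_of_seed,
) -> list[Feature]:
    xmin, ymin, xmax, ymax = boundary.bounds
    pts = np.column_stack(
        [rng.uniform(xmin, xmax, n_seeds), rng.uniform(ymin, ymax, n_seeds)]
    )
    cells = voronoi_diagram(MultiPoint([Point(p) for p in pts]), envelope=boundary)
    feats = []
    for cell in cells.geoms:
        inside = [i for i, p in enumerate(pts) if cell.covers(Point(p))]
        if not inside:
            continue
        clipped = cell.intersection(boundary)
        if clipped.is_empty:
            continue
        feats.append(
            Feature(clipped, {"class": int(class_of_seed(pts[inside[0]]))})
        )
    return feats


def _random_polyline(rng, start, extent, n_vertices=3, step_km=(1.5, 4.0)):
    xmin, ymin, xmax, ymax = extent
    pts = [start]
    ang = rng.uniform(0, 2 * np.pi)
    for _ in range(n_vertices):
        ang += rng.normal(0, 0.5)
        step = rng.uniform(*step_km) * 1000.0
        nxt = (
            float(np.clip(pts[-1][0] + step * np.cos(ang), xmin, xmax)),
            float(np.clip(pts[-1][1] + step * np.sin(ang), ymin, ymax)),
        )
        pts.append(nxt)
    return LineString(pts)


def _elevation_grid(rng, scenario) -> AsciiGrid:
    xmin, ymin, xmax, ymax = scenario.extent
    cs = scenario.elevation_cellsize
    ncols = int(np.ceil((xmax - xmin) / cs))
    nrows = int(np.ceil((ymax - ymin) / cs))
    xs = xmin + (np.arange(ncols) + 0.5) * cs
    ys = ymin + (np.arange(nrows) + 0.5) * cs
    xx, yy = np.meshgrid(xs, ys)  # yy south->north
    # valley floor rising northward with a few smooth hills
    z = 780.0 + 0.012 * (yy - ymin)
    for _ in range(4):
        cx = rng.uniform(xmin, xmax)
        cy = rng.uniform(ymin, ymax)
        amp = rng.uniform(40.0, 160.0)
        sd = rng.uniform(2500.0, 6000.0)
        z += amp * np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sd**2)))
    values = z[::-1, :]  # rows north->south per ESRI ASCII layout
    return AsciiGrid(values, xmin, ymin, cs)


def _met_station_features(rng, scenario, elev: AsciiGrid) -> list[Feature]:
    xmin, ymin, xmax, ymax = scenario.extent
    k = int(np.ceil(np.sqrt(scenario.n_met_stations)))
    xs = np.linspace(xmin + 0.1 * (xmax - xmin), xmax - 0.1 * (xmax - xmin), k)
    ys = np.linspace(ymin + 0.1 * (ymax - ymin), ymax - 0.1 * (ymax - ymin), k)
    locs = [(x, y) for y in ys for x in xs][: scenario.n_met_stations]
    feats = []
    hum_base = {"windy": 40.0, "non-heating": 62.0, "heating": 45.0}
    rain_base = {"windy": 0.6, "non-heating": 2.4, "heating": 0.3}
    for i, (x, y) in enumerate(locs):
        jx = x + rng.uniform(-500, 500)
        jy = y + rng.uniform(-500, 500)
        jx = float(np.clip(jx, xmin, xmax))
        jy = float(np.clip(jy, ymin, ymax))
        z = elev.value_at(jx, jy)
        props: dict = {"station_id": f"M{i+1:02d}"}
        for season in SEASONS:
            t0 = scenario.season_temperatures[season]
            # lapse-rate cooling with altitude plus station noise
            props[f"tem_{season}"] = round(
                t0 - 0.0065 * (z - 800.0) + rng.normal(0, 0.4), 3
            )
            props[f"pre_{season}"] = round(
                1013.25 * np.exp(-z / 8434.0) + rng.normal(0, 0.8), 3
            )
            props[f"hum_{season}"] = round(
                float(np.clip(hum_base[season] + rng.normal(0, 4.0), 5, 98)), 3
            )
            props[f"wind_{season}"] = round(
                float(np.clip(2.2 + rng.normal(0, 0.4), 0.2, 8.0)), 3
            )
            props[f"rain_8_{season}"] = round(
                float(max(rain_base[season] + rng.normal(0, 0.15), 0.0)), 3
            )
            props[f"rain_20_{season}"] = round(
                float(max(0.7 * rain_base[season] + rng.normal(0, 0.1), 0.0)), 3
            )
        feats.append(Feature(Point(jx, jy), props))
    return feats


def generate_world(
    scenario: SyntheticScenario,
) -> tuple[GISWorld, SiteNetwork]:
    """Generate all GIS layers and the monitoring network.

    Urban sites cluster inside the designated urban polygon; background
    sites are placed at least 5000 m from every point source.  The same
    scenario (same seed) regenerates identical output.
    """
    _check_extent(scenario)
    rng = np.random.default_rng(scenario.seed)
    xmin, ymin, xmax, ymax = scenario.extent
    boundary = scenario.boundary
    urban = _urban_polygon(scenario.extent)
    ucx, ucy = urban.centroid.x, urban.centroid.y

    # factories: clustered around the urban core with a diffuse remainder
    sources = []
    for i in range(scenario.n_point_sources):
        if rng.uniform() < 0.7:
            x = float(np.clip(rng.normal(ucx, 4000.0), xmin, xmax))
            y = float(np.clip(rng.normal(ucy, 4000.0), ymin, ymax))
        else:
            x = float(rng.uniform(xmin, xmax))
            y = float(rng.uniform(ymin, ymax))
        sources.append(Feature(Point(x, y), {"source_id": f"F{i+1:02d}"}))
    src_xy = np.array([(f.geometry.x, f.geometry.y) for f in sources]).reshape(-1, 2)

    # monitoring network
    sites: list[tuple[str, float, float, str]] = []
    n = 0
    bxmin, bymin, bxmax, bymax = urban.bounds
    for _ in range(scenario.n_urban):
        n += 1
        sites.append(
            (f"S{n:02d}", float(rng.uniform(bxmin, bxmax)),
             float(rng.uniform(bymin, bymax)), "urban")
        )
    rural_done = 0
    attempts = 0
    while rural_done < scenario.n_rural:
        attempts += 1
        if attempts > 10_000:
            raise SizingError("could not place rural sites outside the urban core")
        x, y = rng.uniform(xmin, xmax), rng.uniform(ymin, ymax)
        if not urban.covers(Point(x, y)):
            n += 1
            sites.append((f"S{n:02d}", float(x), float(y), "rural"))
            rural_done += 1
    bg_done = 0
    attempts = 0
    while bg_done < scenario.n_background:
        attempts += 1
        if attempts > 10_000:
            raise SizingError(
                "could not place background sites >= 5000 m from all sources"
            )
        x, y = rng.uniform(xmin, xmax), rng.uniform(ymin, ymax)
        if len(src_xy) and np.hypot(*(src_xy - (x, y)).T).min() < MAX_BUFFER_M:
            continue
        if urban.covers(Point(x, y)):
            continue
        n += 1
        sites.append((f"S{n:02d}", float(x), float(y), "background"))
        bg_done += 1
    network = SiteNetwork(sites)

    # land mosaics
    lc_weights = {10: 0.30, 20: 0.18, 30: 0.18, 40: 0.05, 50: 0.03,
                  60: 0.07, 70: 0.02, 80: 0.05, 90: 0.08, 100: 0.04}
    lc_codes = np.array(list(lc_weights))
    lc_p = np.array(list(lc_weights.values()))
    lc_p = lc_p / lc_p.sum()
    lc_assign = {}

    def lc_class(pt):
        key = (round(pt[0], 3), round(pt[1], 3))
        if key not in lc_assign:
            if urban.covers(Point(pt)) and rng.uniform() < 0.75:
                lc_assign[key] = 80
            else:
                lc_assign[key] = int(rng.choice(lc_codes, p=lc_p))
        return lc_assign[key]

    land_cover = _voronoi_mosaic(
        rng, boundary, scenario.n_land_cover_seeds, lc_class
    )

    lu_weights = {1: 0.35, 2: 0.20, 3: 0.20, 4: 0.07, 6: 0.08, 5: 0.10}
    lu_codes = np.array(list(lu_weights))
    lu_p = np.array(list(lu_weights.values()))
    lu_p = lu_p / lu_p.sum()
    lu_assign = {}

    def lu_class(pt):
        key = (round(pt[0], 3), round(pt[1], 3))
        if key not in lu_assign:
            if urban.covers(Point(pt)) and rng.uniform() < 0.75:
                lu_assign[key] = 5
            else:
                lu_assign[key] = int(rng.choice(lu_codes, p=lu_p))
        return lu_assign[key]

    land_use = _voronoi_mosaic(rng, boundary, scenario.n_land_use_seeds, lu_class)

    # roads: density highest near the urban core; class 53 is the dense one
    roads: list[Feature] = []
    for cls, count, urban_frac in ((51, 8, 0.6), (52, 15, 0.7), (53, 40, 0.75)):
        for _ in range(count):
            if rng.uniform() < urban_frac:
                sx = float(np.clip(rng.normal(ucx, 5000.0), xmin, xmax))
                sy = float(np.clip(rng.normal(ucy, 5000.0), ymin, ymax))
            else:
                sx, sy = float(rng.uniform(xmin, xmax)), float(rng.uniform(ymin, ymax))
            line = _random_polyline(rng, (sx, sy), scenario.extent)
            roads.append(Feature(line, {"class": cls}))

    elevation = _elevation_grid(rng, scenario)
    met = _met_station_features(rng, scenario, elevation)

    world = GISWorld(
        land_cover=land_cover,
        land_use=land_use,
        roads=roads,
        point_sources=sources,
        met_stations=met,
        elevation=elevation,
        boundary=boundary,
        crs=scenario.crs,
    )
    return world, network
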