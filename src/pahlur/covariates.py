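"""GIS covariate extraction at point locations.

Every candidate variable of the registry is evaluated at arbitrary target
points (monitoring sites or prediction-grid centroids): areas of land
cover/use classes inside circular buffers, clipped road lengths, factory
counts and distances, elevation raster lookups, inverse-projected
geographic coordinates, and kriged seasonal meteorological fields.

Circular buffers are discretized as 256-segment polygons (shapely
``buffer(quad_segs=64)``); areas therefore carry a ~0.5 % polygonization
tolerance against the analytic pi r^2.  A point exactly ``radius`` away
from a site counts as inside (boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.ops import unary_union

from .geoio import AsciiGrid, Feature
from .kriging import OrdinaryKriging
from .predictors import DEFAULT_BUFFER_SIZES, MET_CODES, PredictorSpec, parse_code
from .species import SEASONS
from .world import GISWorld, NoPointSourceError

QUAD_SEGS = 64  # 256-segment discs


class GeometryError(ValueError):
    pass


def _as_point(site) -> Point:
    return site if isinstance(site, Point) else Point(site[0], site[1])


def _check_radius(radius: float, buffer_sizes) -> None:
    if float(radius) not in {float(r) for r in buffer_sizes}:
        raise ValueError(
            f"radius {radius} m is not in the configured buffer set {buffer_sizes}"
        )


def _class_geoms(layer: list[Feature], class_code) -> list:
    geoms = []
    for i, f in enumerate(layer):
        if not f.geometry.is_valid:
            raise GeometryError(f"invalid geometry in feature {i} ({f.properties})")
        if class_code is None or f.properties.get("class") == class_code:
            geoms.append(f.geometry)
    return geoms


def area_in_buffer(
    layer: list[Feature],
    site,
    radius: float,
    class_code: int,
    buffer_sizes=DEFAULT_BUFFER_SIZES,
) -> float:
    """Area (m^2) of polygons of ``class_code`` inside the disc of ``radius``."""
    _check_radius(radius, buffer_sizes)
    geoms = _class_geoms(layer, class_code)
    if not geoms:
        return 0.0
    disc = _as_point(site).buffer(radius, quad_segs=QUAD_SEGS)
    # union first: overlapping features must not double-count
    return float(disc.intersection(unary_union(geoms)).area)


def length_in_buffer(
    roads: list[Feature],
    site,
    radius: float,
    road_class: int,
    buffer_sizes=DEFAULT_BUFFER_SIZES,
) -> float:
    """Total clipped length (m) of lines of ``road_class`` inside the disc."""
    _check_radius(radius, buffer_sizes)
    geoms = _class_geoms(roads, road_class)
    if not geoms:
        return 0.0
    disc = _as_point(site).buffer(radius, quad_segs=QUAD_SEGS)
    return float(disc.intersection(unary_union(geoms)).length)


def count_within_radius(points: list[Feature], site, radius: float) -> int:
    """Points with Euclidean distance <= radius (boundary inclusive)."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    p = _as_point(site)
    return int(sum(1 for f in points if p.distance(f.geometry) <= radius))


def distance_to_nearest(points: list[Feature], site) -> float:
    if not points:
        raise NoPointSourceError(
            "distance to nearest factory undefined: the point-source layer is empty"
        )
    p = _as_point(site)
    return float(min(p.distance(f.geometry) for f in points))


def raster_at_site(raster: AsciiGrid, site) -> float:
    """Nearest-cell raster lookup (floor((coord - origin)/cellsize) convention)."""
    p = _as_point(site)
    return raster.value_at(p.x, p.y)


def interpolate_met(
    met_stations: list[Feature],
    targets,
    season: str,
    variable: str,
) -> np.ndarray:
    """Ordinary-kriging estimate of one seasonal met field at the targets.

    Station values are the per-season means stored on the station layer.
    A constant field short-circuits to the constant (the kriging system is
    degenerate there).
    """
    if variable not in MET_CODES:
        raise ValueError(f"unknown met variable {variable!r}")
    key = f"{variable}_{season}"
    coords, values = [], []
    for f in met_stations:
        if key not in f.properties:
            raise ValueError(f"station {f.properties} lacks field {key}")
        coords.append((f.geometry.x, f.geometry.y))
        values.append(float(f.properties[key]))
    coords = np.array(coords)
    values = np.array(values)
    if np.ptp(values) > 0 and len(values) < 3:
        raise ValueError("met interpolation needs >= 3 stations")
    tgt = np.array([(p.x, p.y) if isinstance(p, Point) else (p[0], p[1]) for p in targets])
    return OrdinaryKriging(coords, values).predict(tgt)


@dataclass
class CovariateTable:
    """Sites x predictors design matrix, rows indexed by (site_id, season)."""

    frame: pd.DataFrame  # MultiIndex (site_id, season), columns predictor codes

    def __post_init__(self):
        if self.frame.isna().any().any():
            bad = self.frame.columns[self.frame.isna().any()].tolist()
            raise ValueError(f"covariate table has missing cells in {bad}")

    def for_season(self, season: str) -> pd.DataFrame:
        return self.frame.xs(season, level="season")

    def to_long(self) -> pd.DataFrame:
        long = self.frame.stack().rename("value").reset_index()
        long.columns = ["site_id", "season", "code", "value"]
        return long

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "CovariateTable":
        wide = long.pivot_table(
            index=["site_id", "season"], columns="code", values="value",
            sort=False,
        )
        wide.columns.name = None
        return cls(wide)


class Extractor:
    """Caches per-class geometry unions and per-(target, radius) discs so a
    full registry can be evaluated at many targets efficiently."""

    def __init__(self, world: GISWorld, buffer_sizes=DEFAULT_BUFFER_SIZES):
        self.world = world
        self.buffer_sizes = tuple(buffer_sizes)
        self._unions: dict[tuple[str, int | None], object] = {}

    def _union(self, group: str, cls: int | None):
        key = (group, cls)
        if key not in self._unions:
            if group == "lc" or group == "w":
                layer, code = self.world.land_cover, (60 if group == "w" else cls)
            elif group == "lu":
                layer, code = self.world.land_use, cls
            elif group == "r":
                layer, code = self.world.roads, cls
            else:
                raise ValueError(group)
            geoms = _class_geoms(layer, code)
            self._unions[key] = unary_union(geoms) if geoms else None
        return self._unions[key]

    def buffered_value(self, group: str, cls: int | None, disc) -> float:
        union = self._union(group, cls)
        if union is None:
            return 0.0
        inter = disc.intersection(union)
        return float(inter.length if group == "r" else inter.area)


def build_covariate_table(
    world: GISWorld,
    targets: list[tuple[str, float, float]],
    registry: dict[str, PredictorSpec],
    buffer_sizes=DEFAULT_BUFFER_SIZES,
    seasons=SEASONS,
) -> CovariateTable:
    """Evaluate every registered predictor at every target for every season.

    Buffered and geographic variables are season-invariant and replicated
    across seasons; meteorological fields are kriged per season.  Errors
    are aggregated with the offending target and code named.
    """
    if not registry:
        raise ValueError("predictor registry is empty")
    ex = Extractor(world, buffer_sizes)
    ids = [t[0] for t in targets]
    pts = [Point(t[1], t[2]) for t in targets]
    lon, lat = world.crs.to_geographic(
        np.array([p.x for p in pts]), np.array([p.y for p in pts])
    )

    columns: dict[str, np.ndarray] = {}
    errors: list[str] = []
    discs: dict[tuple[int, float], object] = {}

    met_needed = [c for c in registry if c in MET_CODES]
    for code, spec in registry.items():
        if code in MET_CODES:
            continue
        group, radius, cls = parse_code(code)
        vals = np.empty(len(pts))
        for i, p in enumerate(pts):
            try:
                if group in ("lc", "lu", "r", "w"):
                    _check_radius(radius, buffer_sizes)
                    dkey = (i, radius)
                    if dkey not in discs:
                        discs[dkey] = p.buffer(radius, quad_segs=QUAD_SEGS)
                    vals[i] = ex.buffered_value(group, cls, discs[dkey])
                elif code == "point":
                    vals[i] = count_within_radius(world.point_sources, p, 5000.0)
                elif code == "dis":
                    vals[i] = distance_to_nearest(world.point_sources, p)
                elif code == "dem":
                    vals[i] = raster_at_site(world.elevation, p)
                elif code == "long":
                    vals[i] = lon[i]
                elif code == "lat":
                    vals[i] = lat[i]
                else:
                    raise ValueError(f"unhandled predictor code {code!r}")
            except Exception as exc:
                errors.append(f"{ids[i]}/{code}: {exc}")
                vals[i] = np.nan
        columns[code] = vals
    if errors:
        raise ValueError("covariate extraction failed:\n" + "\n".join(errors))
    static = pd.DataFrame(columns, index=pd.Index(ids, name="site_id"))

    rows = []
    for season in seasons:
        block = static.copy()
        for code in met_needed:
            block[code] = interpolate_met(world.met_stations, pts, season, code)
        block["season"] = season
        rows.append(block.set_index("season", append=True))
    frame = pd.concat(rows).reindex(
        pd.MultiIndex.from_product([ids, seasons], names=["site_id", "season"])
    )
    # column order follows the registry
    frame = frame[[c for c in registry]]
    return CovariateTable(frame)
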