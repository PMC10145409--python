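"""Candidate-predictor registry and the variable-code grammar.

Buffered variables follow the code grammar ``{group}{radius}_{class}``:
``lc2000_80`` is land-cover class 80 (artificial surface) within a 2000 m
circular buffer, ``r3000_51`` is motorway length within 3000 m,
``lu2500_5`` urban/rural land-use area within 2500 m, and ``w3500`` water
area within 3500 m (no class suffix).  Unbuffered variables carry plain
codes: ``point`` (factory count within 5 km), ``dis`` (distance to the
nearest factory), ``dem``, ``long``, ``lat`` and the meteorological fields
``rain_8, rain_20, pre, hum, tem, wind``.

Each predictor also carries its a-priori direction of effect, used by the
supervised selection procedure: vegetation and water variables are expected
to depress concentrations, road and industry variables to raise them, and
the rest are unconstrained.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import yaml

DEFAULT_BUFFER_SIZES = (500, 1000, 1500, 2000, 2500, 3000, 3500, 4000, 4500, 5000)

LAND_COVER_CLASSES = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100)
LAND_USE_CLASSES = (1, 2, 3, 4, 5, 6)
ROAD_CLASSES = (51, 52, 53)

# a-priori coefficient signs per group/class ("uncertain" imposes nothing)
_LC_SIGNS = {10: "uncertain", 20: "-", 30: "-", 40: "-", 50: "-", 60: "-",
             70: "-", 80: "uncertain", 90: "uncertain", 100: "uncertain"}
_LU_SIGNS = {1: "uncertain", 2: "-", 3: "-", 4: "-", 5: "-", 6: "uncertain"}
_ROAD_SIGNS = {51: "+", 52: "+", 53: "uncertain"}

MET_CODES = ("rain_8", "rain_20", "pre", "hum", "tem", "wind")

_BUFFERED_RE = re.compile(r"^(lc|lu|r)(\d+)_(\d+)$")
_WATER_RE = re.compile(r"^w(\d+)$")


@dataclass(frozen=True)
class PredictorSpec:
    """One candidate variable of the regression design."""

    code: str
    category: str  # land_cover | land_use | water | road | point | geo | met
    buffer_radius: float | None
    units: str
    expected_sign: str  # "+", "-" or "uncertain"

    def __post_init__(self) -> None:
        if self.expected_sign not in ("+", "-", "uncertain"):
            raise ValueError(f"{self.code}: bad expected_sign {self.expected_sign!r}")


def parse_code(code: str) -> tuple[str, float | None, int | None]:
    """Decompose a predictor code into (group, buffer_radius, class_code).

    Unbuffered codes return ``(code, None, None)``.
    """
    m = _BUFFERED_RE.match(code)
    if m:
        return m.group(1), float(m.group(2)), int(m.group(3))
    m = _WATER_RE.match(code)
    if m:
        return "w", float(m.group(1)), None
    return code, None, None


def make_spec(code: str) -> PredictorSpec:
    """Build the PredictorSpec for any grammatical code."""
    group, radius, cls = parse_code(code)
    if group == "lc":
        if cls not in LAND_COVER_CLASSES:
            raise ValueError(f"{code}: unknown land-cover class {cls}")
        return PredictorSpec(code, "land_cover", radius, "m^2", _LC_SIGNS[cls])
    if group == "lu":
        if cls not in LAND_USE_CLASSES:
            raise ValueError(f"{code}: unknown land-use class {cls}")
        return PredictorSpec(code, "land_use", radius, "m^2", _LU_SIGNS[cls])
    if group == "r":
        if cls not in ROAD_CLASSES:
            raise ValueError(f"{code}: unknown road class {cls}")
        return PredictorSpec(code, "road", radius, "m", _ROAD_SIGNS[cls])
    if group == "w":
        return PredictorSpec(code, "water", radius, "m^2", "-")
    if code == "point":
        return PredictorSpec(code, "point", None, "count", "+")
    if code == "dis":
        return PredictorSpec(code, "point", None, "m", "+")
    if code == "dem":
        return PredictorSpec(code, "geo", None, "m", "uncertain")
    if code in ("long", "lat"):
        return PredictorSpec(code, "geo", None, "deg", "uncertain")
    if code in ("rain_8", "rain_20"):
        return PredictorSpec(code, "met", None, "mm", "uncertain")
    if code == "pre":
        return PredictorSpec(code, "met", None, "hPa", "uncertain")
    if code == "hum":
        return PredictorSpec(code, "met", None, "%", "uncertain")
    if code in ("tem", "wind"):
        return PredictorSpec(code, "met", None, "", "uncertain")
    raise ValueError(f"unrecognised predictor code {code!r}")


def default_registry(
    buffer_sizes: tuple[int, ...] = DEFAULT_BUFFER_SIZES,
    include_met: bool = False,
) -> dict[str, PredictorSpec]:
    """Full candidate registry over the configured buffer set.

    Meteorological variables are computed by the extraction stage but only
    enter model selection when ``include_met`` is set; the final models of
    the study design contain no air-phase factors.
    """
    codes: list[str] = []
    for r in buffer_sizes:
        codes += [f"lc{r}_{c}" for c in LAND_COVER_CLASSES]
        codes += [f"lu{r}_{c}" for c in LAND_USE_CLASSES]
        codes += [f"w{r}"]
        codes += [f"r{r}_{c}" for c in ROAD_CLASSES]
    codes += ["point", "dis", "dem", "long", "lat"]
    if include_met:
        codes += list(MET_CODES)
    return {c: make_spec(c) for c in codes}


def compact_registry(buffer_sizes: tuple[int, ...] = (1000, 3000, 5000)) -> dict[str, PredictorSpec]:
    """A ~30-variable registry: one buffered code per group taxonomy row at
    a few radii, plus the unbuffered variables.  Sized like the study's own
    candidate list; used for recovery experiments where the full registry
    would be overkill."""
    codes: list[str] = []
    for r in buffer_sizes:
        codes += [f"lc{r}_20", f"lc{r}_30", f"lc{r}_60", f"lc{r}_80",
                  f"lu{r}_3", f"lu{r}_5", f"r{r}_51", f"r{r}_53"]
    codes += ["point", "dis", "dem", "long", "lat", "w3000"]
    return {c: make_spec(c) for c in codes}


def registry_to_yaml(registry: dict[str, PredictorSpec], path) -> None:
    rows = [
        {
            "code": s.code,
            "category": s.category,
            "buffer_radius": s.buffer_radius,
            "units": s.units,
            "expected_sign": s.expected_sign,
        }
        for s in registry.values()
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(rows, fh, sort_keys=False)


def registry_from_yaml(path) -> dict[str, PredictorSpec]:
    with open(path) as fh:
        rows = yaml.safe_load(fh)
    out = {}
    for row in rows:
        spec = PredictorSpec(
            row["code"], row["category"], row["buffer_radius"],
            row["units"], row["expected_sign"],
        )
        out[spec.code] = spec
    return out
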