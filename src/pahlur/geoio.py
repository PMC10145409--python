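"""Plain-text geospatial I/O: GeoJSON vector layers and ESRI ASCII rasters.

Vector layers are held as lists of ``Feature`` records (shapely geometry +
attribute dict) and serialized as GeoJSON FeatureCollections.  Rasters use
the ESRI ASCII grid format (``ncols/nrows/xllcorner/yllcorner/cellsize``
header followed by rows from north to south), which round-trips losslessly
as text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry


@dataclass
class Feature:
    geometry: BaseGeometry
    properties: dict = field(default_factory=dict)


def write_geojson(features: list[Feature], path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(f.geometry),
                "properties": f.properties,
            }
            for f in features
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh)


def read_geojson(path) -> list[Feature]:
    with open(path) as fh:
        fc = json.load(fh)
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    return [
        Feature(shape(f["geometry"]), f.get("properties") or {})
        for f in fc["features"]
    ]


class AsciiGrid:
    """ESRI ASCII raster: a 2-D value array on a regular south-west-anchored
    grid.  ``values[0, 0]`` is the north-west cell, matching the file layout.

    The cell containing a point (x, y) has column ``floor((x - xll) /
    cellsize)`` and row-from-south ``floor((y - yll) / cellsize)``; points on
    a cell boundary therefore belong to the cell to the north-east of the
    corner, a fixed convention.
    """

    def __init__(self, values: np.ndarray, xll: float, yll: float,
                 cellsize: float, nodata: float = -9999.0):
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        self.xll = float(xll)
        self.yll = float(yll)
        self.cellsize = float(cellsize)
        self.nodata = float(nodata)

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.xll,
            self.yll,
            self.xll + self.ncols * self.cellsize,
            self.yll + self.nrows * self.cellsize,
        )

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) into ``values`` of the cell containing (x, y)."""
        xmin, ymin, xmax, ymax = self.extent
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            raise ValueError(
                f"point ({x}, {y}) outside raster extent {self.extent}"
            )
        col = int(np.floor((x - self.xll) / self.cellsize))
        row_from_south = int(np.floor((y - self.yll) / self.cellsize))
        # points on the far edges fall into the last cell
        col = min(col, self.ncols - 1)
        row_from_south = min(row_from_south, self.nrows - 1)
        return self.nrows - 1 - row_from_south, col

    def value_at(self, x: float, y: float) -> float:
        r, c = self.cell_index(x, y)
        return float(self.values[r, c])

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.xll!r}\n")
            fh.write(f"yllcorner {self.yll!r}\n")
            fh.write(f"cellsize {self.cellsize!r}\n")
            fh.write(f"NODATA_value {self.nodata!r}\n")
            for row in self.values:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def read(cls, path) -> "AsciiGrid":
        header: dict[str, float] = {}
        rows: list[list[float]] = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                key = parts[0].lower()
                if key in ("ncols", "nrows", "xllcorner", "yllcorner",
                           "cellsize", "nodata_value") and len(parts) == 2:
                    header[key] = float(parts[1])
                else:
                    rows.append([float(v) for v in parts])
        values = np.array(rows, dtype=float)
        if values.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError(f"{path}: grid shape does not match header")
        return cls(
            values,
            header["xllcorner"],
            header["yllcorner"],
            header["cellsize"],
            header.get("nodata_value", -9999.0),
        )
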