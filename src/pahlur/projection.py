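"""Local projection between the metric working CRS and geographic lat/long.

All geometry lives in a single projected metric CRS (x east, y north, in
metres).  Geographic coordinates for the ``lat``/``long`` predictors are
obtained by inverting a local equirectangular projection about a reference
point: metre offsets are converted to degree offsets using the meridional
radius and the parallel radius at the reference latitude.  Over a study
region a few tens of kilometres across the distortion of this inverse is
far below the resolution at which latitude acts as a predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_M = 6_371_008.8


@dataclass(frozen=True)
class LocalCRS:
    """Equirectangular local CRS anchored at (ref_lon, ref_lat) = (x0, y0)."""

    ref_lon: float = 112.55  # degrees east
    ref_lat: float = 37.87   # degrees north
    x0: float = 0.0          # metres, projected coordinate of the reference
    y0: float = 0.0

    def to_geographic(self, x, y):
        """Projected metres -> (longitude, latitude) in degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lat = self.ref_lat + np.degrees((y - self.y0) / EARTH_RADIUS_M)
        lon = self.ref_lon + np.degrees(
            (x - self.x0) / (EARTH_RADIUS_M * np.cos(np.radians(self.ref_lat)))
        )
        return lon, lat

    def to_projected(self, lon, lat):
        """(longitude, latitude) degrees -> projected metres."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        y = self.y0 + np.radians(lat - self.ref_lat) * EARTH_RADIUS_M
        x = self.x0 + np.radians(lon - self.ref_lon) * (
            EARTH_RADIUS_M * np.cos(np.radians(self.ref_lat))
        )
        return x, y
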