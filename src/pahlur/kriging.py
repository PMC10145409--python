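"""Ordinary kriging on scattered 2-D data.

Used twice in the pipeline: to interpolate seasonal-mean meteorological
fields from station points, and to smooth grid-centroid model predictions
into an exposure surface.  The estimator is the classical ordinary-kriging
BLUP under an isotropic variogram: with zero nugget it is an exact
interpolator (it reproduces the data at the data points) and it preserves
constant fields.

Variogram models (h = lag distance):

    exponential : gamma(h) = nugget + psill * (1 - exp(-h / range))
    spherical   : gamma(h) = nugget + psill * (1.5 h/a - 0.5 (h/a)^3), h < a
    gaussian    : gamma(h) = nugget + psill * (1 - exp(-(h / range)^2))

Parameters are fitted by least squares to the binned empirical
semivariogram; if the fit fails or the data are degenerate, a documented
default is used (exponential, nugget 0, partial sill = sample variance,
range = one third of the extent diagonal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class Variogram:
    model: str  # exponential | spherical | gaussian
    nugget: float
    psill: float
    range_: float

    def __call__(self, h):
        h = np.asarray(h, dtype=float)
        a = max(self.range_, 1e-12)
        if self.model == "exponential":
            g = 1.0 - np.exp(-h / a)
        elif self.model == "gaussian":
            g = 1.0 - np.exp(-((h / a) ** 2))
        elif self.model == "spherical":
            hr = np.minimum(h / a, 1.0)
            g = 1.5 * hr - 0.5 * hr**3
        else:
            raise ValueError(f"unknown variogram model {self.model!r}")
        out = self.nugget + self.psill * g
        return np.where(h == 0.0, 0.0, out)


def empirical_variogram(
    coords: np.ndarray, values: np.ndarray, n_bins: int = 12
) -> tuple[np.ndarray, np.ndarray]:
    """Binned semivariances; returns (lag centers, semivariances)."""
    d = cdist(coords, coords)
    iu = np.triu_indices_from(d, k=1)
    lags = d[iu]
    sq = 0.5 * (values[:, None] - values[None, :]) ** 2
    gammas = sq[iu]
    edges = np.linspace(0.0, lags.max(), n_bins + 1)
    centers, semis = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (lags > lo) & (lags <= hi)
        if sel.any():
            centers.append(lags[sel].mean())
            semis.append(gammas[sel].mean())
    return np.array(centers), np.array(semis)


def default_variogram(coords: np.ndarray, values: np.ndarray) -> Variogram:
    span = coords.max(axis=0) - coords.min(axis=0)
    diag = float(np.hypot(*span)) or 1.0
    var = float(np.var(values))
    return Variogram("exponential", 0.0, var if var > 0 else 1.0, diag / 3.0)


def fit_variogram(
    coords: np.ndarray, values: np.ndarray, model: str = "exponential"
) -> Variogram:
    """Least-squares variogram fit with fallback to the documented default."""
    fallback = default_variogram(coords, values)
    try:
        lags, semis = empirical_variogram(coords, values)
        if len(lags) < 3 or semis.max() <= 0:
            return fallback

        def resid(theta):
            psill, rng = theta
            return Variogram(model, 0.0, psill, rng)(lags) - semis

        res = optimize.least_squares(
            resid,
            x0=[max(semis.max(), 1e-12), max(lags.max() / 3.0, 1e-6)],
            bounds=([1e-12, 1e-6], [np.inf, np.inf]),
        )
        if not res.success:
            raise RuntimeError(res.message)
        psill, rng = res.x
        return Variogram(model, 0.0, float(psill), float(rng))
    except Exception as exc:  # degenerate layouts, optimizer failure
        warnings.warn(
            f"variogram fit failed ({exc}); using default {fallback}",
            stacklevel=2,
        )
        return fallback


class OrdinaryKriging:
    """Exact ordinary-kriging interpolator.

    A constant field is detected up front and returned verbatim (the
    kriging system is singular there, not merely ill-conditioned).
    """

    def __init__(
        self,
        coords: np.ndarray,
        values: np.ndarray,
        variogram: Variogram | None = None,
    ):
        self.coords = np.asarray(coords, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (n, 2)")
        if len(self.values) != len(self.coords):
            raise ValueError("coords/values length mismatch")
        self._constant = float(np.ptp(self.values)) == 0.0
        if self._constant:
            self.variogram = variogram or Variogram("exponential", 0.0, 1.0, 1.0)
            self._lu = None
            return
        self.variogram = variogram or fit_variogram(self.coords, self.values)
        n = len(self.coords)
        a = np.empty((n + 1, n + 1))
        a[:n, :n] = self.variogram(cdist(self.coords, self.coords))
        a[n, :n] = 1.0
        a[:n, n] = 1.0
        a[n, n] = 0.0
        self._lu = linalg.lu_factor(a)

    def predict(self, targets: np.ndarray) -> np.ndarray:
        targets = np.atleast_2d(np.asarray(targets, dtype=float))
        if self._constant:
            return np.full(len(targets), self.values[0])
        n = len(self.coords)
        b = np.empty((n + 1, len(targets)))
        b[:n, :] = self.variogram(cdist(self.coords, targets))
        b[n, :] = 1.0
        w = linalg.lu_solve(self._lu, b)
        return w[:n, :].T @ self.values

    def weights(self, target: np.ndarray) -> np.ndarray:
        """Kriging weights (length n) for a single target, for inspection."""
        if self._constant:
            raise ValueError("constant field has no kriging weights")
        n = len(self.coords)
        b = np.empty(n + 1)
        b[:n] = self.variogram(
            cdist(self.coords, np.atleast_2d(target)).ravel()
        )
        b[n] = 1.0
        return linalg.lu_solve(self._lu, b)[:n]
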