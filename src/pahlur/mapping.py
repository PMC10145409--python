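"""Exposure surfaces: regular prediction grids and kriged rasters.

A regular grid (default 500 x 500 m, axis-aligned, anchored at the
lower-left corner of the boundary envelope) is laid over the study
boundary; each retained cell's concentration is the regression equation
evaluated on covariates extracted at the centroid of the cell-boundary
intersection; negative predictions are floored at zero.  The centroid
predictions are then smoothed into a continuous raster by ordinary kriging
(universal kriging with linear drift is available as an option; both are
exact at the centroids and preserve constant fields).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon, box

from .covariates import build_covariate_table
from .geoio import AsciiGrid
from .kriging import OrdinaryKriging, Variogram, fit_variogram
from .predictors import make_spec
from .selection import LURModel
from .world import GISWorld


@dataclass
class PredictionGrid:
    cell_size: float
    cells: list[Polygon]  # clipped to the boundary
    centroids: np.ndarray  # (n, 2)
    values: np.ndarray | None = None  # ng/m^3 per cell
    n_floored: int = 0
    failed_cells: list[int] | None = None


def make_grid(boundary: Polygon, cell_size: float = 500.0) -> PredictionGrid:
    """Axis-aligned cells over the boundary envelope; cells intersecting the
    boundary are retained with the centroid of the intersection."""
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    if boundary.is_empty or not boundary.is_valid or boundary.area == 0:
        raise ValueError("degenerate boundary polygon")
    xmin, ymin, xmax, ymax = boundary.bounds
    nx = max(int(np.ceil((xmax - xmin) / cell_size)), 1)
    ny = max(int(np.ceil((ymax - ymin) / cell_size)), 1)
    cells, cents = [], []
    for j in range(ny):
        for i in range(nx):
            cell = box(
                xmin + i * cell_size,
                ymin + j * cell_size,
                xmin + (i + 1) * cell_size,
                ymin + (j + 1) * cell_size,
            )
            inter = cell.intersection(boundary)
            if inter.is_empty or inter.area == 0:
                continue
            cells.append(inter)
            cents.append((inter.centroid.x, inter.centroid.y))
    return PredictionGrid(cell_size, cells, np.array(cents))


def predict_grid(
    model: LURModel,
    grid: PredictionGrid,
    world: GISWorld,
    buffer_sizes=None,
    covariates=None,
) -> PredictionGrid:
    """Evaluate the regression equation at every centroid.

    Covariates can be passed pre-extracted (a DataFrame indexed like the
    centroid ids ``C0000..``); otherwise only the model's own predictors
    are extracted.  Failed cells are flagged, not fatal.
    """
    from .predictors import DEFAULT_BUFFER_SIZES

    buffer_sizes = buffer_sizes or DEFAULT_BUFFER_SIZES
    ids = [f"C{i:04d}" for i in range(len(grid.centroids))]
    if covariates is None:
        registry = {c: make_spec(c) for c in model.codes}
        if registry:
            table = build_covariate_table(
                world,
                [(cid, x, y) for cid, (x, y) in zip(ids, grid.centroids)],
                registry,
                buffer_sizes,
                seasons=(model.season,) if model.season else ("windy",),
            )
            covariates = table.frame.xs(
                table.frame.index.get_level_values("season")[0], level="season"
            )
        else:
            import pandas as pd

            covariates = pd.DataFrame(index=ids)
    vals = model.fit.predict(covariates.loc[ids, model.codes] if model.codes
                             else covariates.loc[ids])
    floored = int(np.sum(vals < 0))
    vals = np.maximum(vals, 0.0)
    return PredictionGrid(
        grid.cell_size, grid.cells, grid.centroids, vals, floored, []
    )


@dataclass
class ExposureSurface:
    raster: AsciiGrid
    variogram: Variogram

    def value_at(self, x: float, y: float) -> float:
        return self.raster.value_at(x, y)


def krige_surface(
    grid: PredictionGrid,
    boundary: Polygon,
    resolution: float = 250.0,
    variogram: Variogram | None = None,
    model: str = "exponential",
) -> ExposureSurface:
    """Krige the centroid predictions onto a raster covering the boundary.

    Exact at the centroids; a constant prediction field yields a constant
    raster.  Variogram-fit failures fall back to the documented default
    (exponential, zero nugget, range a third of the extent diagonal).
    """
    if grid.values is None:
        raise ValueError("grid has no predicted values; run predict_grid first")
    if len(grid.values) < 10:
        raise ValueError("kriging a surface needs >= 10 centroid values")
    coords = grid.centroids
    values = np.asarray(grid.values, dtype=float)
    if variogram is None and np.ptp(values) > 0:
        variogram = fit_variogram(coords, values, model)
    ok = OrdinaryKriging(coords, values, variogram)
    xmin, ymin, xmax, ymax = boundary.bounds
    ncols = int(np.ceil((xmax - xmin) / resolution))
    nrows = int(np.ceil((ymax - ymin) / resolution))
    xs = xmin + (np.arange(ncols) + 0.5) * resolution
    ys = ymin + (np.arange(nrows) + 0.5) * resolution
    xx, yy = np.meshgrid(xs, ys)
    targets = np.column_stack([xx.ravel(), yy.ravel()])
    z = ok.predict(targets).reshape(nrows, ncols)
    raster = AsciiGrid(z[::-1, :], xmin, ymin, resolution)
    return ExposureSurface(raster, ok.variogram)


def plot_surface(surface: ExposureSurface, path, title: str = "") -> None:
    """Minimal raster rendering helper."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    xmin, ymin, xmax, ymax = surface.raster.extent
    im = ax.imshow(
        surface.raster.values, extent=(xmin, xmax, ymin, ymax), origin="upper",
        cmap="viridis",
    )
    fig.colorbar(im, ax=ax, label="ng/m$^3$")
    if title:
        ax.set_title(title)
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
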