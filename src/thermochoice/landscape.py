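"""Synthetic vegetation landscapes on a regular planar grid.

A landscape carries two co-registered rasters at (default) 10-m resolution:
percent canopy cover (vegetation above 3 m) and percent understory cover
(vegetation between 1 and 3 m).  Synthetic landscapes are built by
thresholding a smoothed Gaussian random field so that a chosen fraction of
cells falls in a high-canopy "forest" regime and the rest in a low-canopy
"field" regime, which yields contiguous patches separated by soft edges —
the structure that edge-affiliated predators such as ratsnakes respond to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "LandscapeConfig",
    "Landscape",
    "generate_landscape",
    "write_ascii_grid",
    "read_ascii_grid",
    "InvalidConfigError",
    "OutOfExtentError",
]

#: canopy percentages assigned to the two regimes before edge smoothing
FOREST_CANOPY = 85.0
FIELD_CANOPY = 5.0
#: midpoint separating the forest and field canopy regimes
REGIME_THRESHOLD = (FOREST_CANOPY + FIELD_CANOPY) / 2.0


class InvalidConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


class OutOfExtentError(ValueError):
    """Raised when a query point falls outside the raster extent."""


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of the synthetic landscape generator.

    correlation_length sets the patch grain (metres); forest_fraction the
    share of cells in the high-canopy regime.  Identical config + seed
    always reproduces the identical landscape.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 10.0
    correlation_length: float = 60.0
    forest_fraction: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidConfigError("raster dimensions must be >= 1")
        if self.cell_size <= 0:
            raise InvalidConfigError("cell_size must be positive")
        if not 0.0 <= self.forest_fraction <= 1.0:
            raise InvalidConfigError("forest_fraction must lie in [0, 1]")
        if self.correlation_length < 0:
            raise InvalidConfigError("correlation_length must be >= 0")


@dataclass
class Landscape:
    """Two co-registered percent-cover rasters plus their geotransform.

    ``canopy[row, col]`` covers the square with lower-left corner
    ``(origin_x + col*cell_size, origin_y + row*cell_size)``.
    """

    canopy: np.ndarray
    understory: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 10.0

    def __post_init__(self) -> None:
        self.canopy = np.asarray(self.canopy, dtype=float)
        self.understory = np.asarray(self.understory, dtype=float)
        if self.canopy.shape != self.understory.shape:
            raise ValueError("canopy and understory rasters must share shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.canopy.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint."""
        x0, y0 = self.origin
        nr, nc = self.shape
        return (x0, y0, x0 + nc * self.cell_size, y0 + nr * self.cell_size)

    def in_extent(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/column of the cell containing each point (must be in extent)."""
        inside = self.in_extent(x, y)
        if not np.all(inside):
            raise OutOfExtentError("point outside raster extent")
        x0, y0 = self.origin
        col = np.floor((np.asarray(x, float) - x0) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y, float) - y0) / self.cell_size).astype(int)
        return row, col

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """x and y coordinates of every cell center, as 2-D arrays."""
        x0, y0 = self.origin
        nr, nc = self.shape
        xs = x0 + (np.arange(nc) + 0.5) * self.cell_size
        ys = y0 + (np.arange(nr) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def canopy_at(self, x, y) -> np.ndarray:
        row, col = self.cell_index(x, y)
        return self.canopy[row, col]

    def understory_at(self, x, y) -> np.ndarray:
        row, col = self.cell_index(x, y)
        return self.understory[row, col]


def _correlated_field(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    """Smoothed white noise rescaled to unit variance (a cheap Gaussian field)."""
    z = rng.standard_normal(shape)
    if sigma_cells > 0:
        z = gaussian_filter(z, sigma=sigma_cells, mode="reflect")
        sd = z.std()
        if sd > 0:
            z = z / sd
    return z


def generate_landscape(config: LandscapeConfig) -> Landscape:
    """Generate a forest/field mosaic with soft edges.

    A correlated Gaussian field is thresholded at its empirical
    ``1 - forest_fraction`` quantile, so the share of forest-regime cells
    matches ``forest_fraction`` up to the smoothing applied afterwards to
    create edge gradients.  Understory is an independent correlated field
    rescaled to [0, 100].
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = (config.n_rows, config.n_cols)
    sigma_cells = config.correlation_length / config.cell_size

    base = _correlated_field(rng, shape, sigma_cells)
    if config.forest_fraction >= 1.0:
        forest = np.ones(shape, dtype=bool)
    elif config.forest_fraction <= 0.0:
        forest = np.zeros(shape, dtype=bool)
    else:
        cut = np.quantile(base, 1.0 - config.forest_fraction)
        forest = base >= cut

    canopy = np.where(forest, FOREST_CANOPY, FIELD_CANOPY)
    # mild within-class texture, then one-cell smoothing for edge gradients
    canopy = canopy + 4.0 * rng.standard_normal(shape)
    canopy = gaussian_filter(canopy, sigma=0.8, mode="reflect")
    canopy = np.clip(canopy, 0.0, 100.0)

    under = _correlated_field(rng, shape, sigma_cells)
    lo, hi = under.min(), under.max()
    if hi > lo:
        under = (under - lo) / (hi - lo) * 100.0
    else:  # degenerate 1-cell raster
        under = np.full(shape, 50.0)

    return Landscape(canopy=canopy, understory=under, origin=(0.0, 0.0),
                     cell_size=config.cell_size)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O — a plain-text raster interchange format readable by
# every GIS.  Rows are written north-to-south, hence the vertical flip.

def write_ascii_grid(path, values: np.ndarray, origin=(0.0, 0.0),
                     cell_size: float = 10.0, nodata: float = -9999.0) -> None:
    values = np.asarray(values, dtype=float)
    out = np.where(np.isfinite(values), values, nodata)
    header = (
        f"ncols {values.shape[1]}\n"
        f"nrows {values.shape[0]}\n"
        f"xllcorner {origin[0]:.6f}\n"
        f"yllcorner {origin[1]:.6f}\n"
        f"cellsize {cell_size:.6f}\n"
        f"NODATA_value {nodata:.1f}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out[::-1], fmt="%.6f")


def read_ascii_grid(path) -> tuple[np.ndarray, tuple[float, float], float]:
    """Return (values, origin, cell_size); NODATA cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    values = np.loadtxt(lines[n_header:])
    values = np.atleast_2d(values)[::-1].copy()
    nodata = header.get("nodata_value")
    if nodata is not None:
        values[values == nodata] = np.nan
    origin = (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0))
    return values, origin, header.get("cellsize", 1.0)
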