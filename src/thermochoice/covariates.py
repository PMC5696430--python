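"""Covariate extraction at telemetry locations.

Six covariates describe each location at a given time: buffer mean and SD
of canopy cover, buffer mean of understory cover, buffer mean temperature,
its square, and buffer SD of temperature.  Buffer statistics are taken over
all raster cells whose centers lie within a 15-m radius of the point
(≈7 cells on average on a 10-m grid), which absorbs GPS error.  Day of
year rides along as a continuous variable for seasonal interactions.

All statistics use the population (divide-by-n) SD convention; with only
~7 cells per buffer the n vs n−1 choice is material and must be fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import Landscape
from .temperature import TemperatureField, _time_components

__all__ = [
    "CovariateVector",
    "StandardizationParams",
    "buffer_stats",
    "covariates_at",
    "covariates_table",
    "standardize",
    "EmptyBufferError",
    "DegenerateCovariateError",
    "COVARIATE_COLUMNS",
]

DEFAULT_BUFFER_RADIUS = 15.0

#: columns standardized for modeling, in canonical order
COVARIATE_COLUMNS = (
    "canopy_mean",
    "canopy_sd",
    "understory_mean",
    "temp",
    "temp_sq",
    "temp_sd",
    "day_of_year",
)


class EmptyBufferError(ValueError):
    """No raster cell center falls inside the requested buffer."""


class DegenerateCovariateError(ValueError):
    """A covariate has zero spread and cannot be z-scored."""


@dataclass(frozen=True)
class CovariateVector:
    canopy_mean: float
    canopy_sd: float
    understory_mean: float
    temp: float
    temp_sq: float
    temp_sd: float
    day_of_year: float


def _buffer_window(landscape: Landscape, xs, ys, radius: float):
    """Rows/cols of candidate cells around each point plus an in-disk mask.

    Returns (rows, cols, mask), each (n_points, window_size); mask is True
    where the cell center lies within ``radius`` of the point and inside
    the raster.  Clipped indices are masked out, never wrapped.
    """
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    ys = np.atleast_1d(np.asarray(ys, dtype=float))
    row0, col0 = landscape.cell_index(xs, ys)
    row0 = np.atleast_1d(row0)
    col0 = np.atleast_1d(col0)
    c = landscape.cell_size
    x0, y0 = landscape.origin
    reach = int(np.ceil(radius / c))
    offs = np.arange(-reach, reach + 1)
    drow, dcol = np.meshgrid(offs, offs, indexing="ij")
    drow = drow.ravel()[None, :]
    dcol = dcol.ravel()[None, :]
    rows = row0[:, None] + drow
    cols = col0[:, None] + dcol
    nr, nc = landscape.shape
    inside = (rows >= 0) & (rows < nr) & (cols >= 0) & (cols < nc)
    cx = x0 + (cols + 0.5) * c
    cy = y0 + (rows + 0.5) * c
    dist2 = (cx - xs[:, None]) ** 2 + (cy - ys[:, None]) ** 2
    mask = inside & (dist2 <= radius * radius)
    np.clip(rows, 0, nr - 1, out=rows)
    np.clip(cols, 0, nc - 1, out=cols)
    return rows, cols, mask


def _masked_stats(values: np.ndarray, mask: np.ndarray):
    """Per-row mean and population SD of masked window values."""
    count = mask.sum(axis=1)
    if np.any(count == 0):
        raise EmptyBufferError("no cell center within buffer radius")
    v = np.where(mask, values, 0.0)
    mean = v.sum(axis=1) / count
    dev = np.where(mask, values - mean[:, None], 0.0)
    sd = np.sqrt((dev * dev).sum(axis=1) / count)
    return mean, sd


def buffer_stats(raster: np.ndarray, point, radius: float = DEFAULT_BUFFER_RADIUS,
                 *, origin=(0.0, 0.0), cell_size: float = 10.0):
    """Mean and population SD of raster cells whose centers lie within
    ``radius`` metres of ``point``.

    ``raster`` may be a bare 2-D array (with ``origin``/``cell_size``
    giving its geotransform) or a :class:`Landscape` layer accessed via the
    parent's geometry by the caller.
    """
    raster = np.asarray(raster, dtype=float)
    geom = Landscape(canopy=raster, understory=raster, origin=origin,
                     cell_size=cell_size)
    rows, cols, mask = _buffer_window(geom, point[0], point[1], radius)
    mean, sd = _masked_stats(raster[rows, cols], mask)
    return float(mean[0]), float(sd[0])


def covariates_table(xs, ys, timestamps, landscape: Landscape,
                     field: TemperatureField,
                     radius: float = DEFAULT_BUFFER_RADIUS) -> pd.DataFrame:
    """Vectorized covariate extraction for many (point, time) queries.

    Temperature statistics are taken over the same buffer cells as the
    vegetation statistics, each cell evaluated at the query's timestamp.
    """
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    ys = np.atleast_1d(np.asarray(ys, dtype=float))
    times = np.atleast_1d(np.asarray(timestamps, dtype="datetime64[ns]"))
    rows, cols, mask = _buffer_window(landscape, xs, ys, radius)

    canopy_mean, canopy_sd = _masked_stats(landscape.canopy[rows, cols], mask)
    under_mean, _ = _masked_stats(landscape.understory[rows, cols], mask)

    c = landscape.cell_size
    x0, y0 = landscape.origin
    cx = x0 + (cols + 0.5) * c
    cy = y0 + (rows + 0.5) * c
    # evaluate the field on every buffer cell at the row's own timestamp
    p = field.params
    doy, hour = _time_components(times)
    cell_canopy = landscape.canopy[rows, cols]
    from .temperature import diurnal_cycle, seasonal_cycle

    t_cells = (
        p.mean_temp
        + p.seasonal_amplitude * seasonal_cycle(doy)[:, None]
        + p.diurnal_amplitude
        * (1.0 - p.canopy_damping * cell_canopy / 100.0)
        * diurnal_cycle(hour)[:, None]
        + field.noise[rows, cols]
    )
    temp_mean, temp_sd = _masked_stats(t_cells, mask)

    return pd.DataFrame(
        {
            "canopy_mean": canopy_mean,
            "canopy_sd": canopy_sd,
            "understory_mean": under_mean,
            "temp": temp_mean,
            "temp_sq": temp_mean**2,
            "temp_sd": temp_sd,
            "day_of_year": doy,
        }
    )


def covariates_at(point, timestamp, landscape: Landscape,
                  field: TemperatureField,
                  radius: float = DEFAULT_BUFFER_RADIUS) -> CovariateVector:
    """Covariates of a single location at a single time."""
    df = covariates_table([point[0]], [point[1]], [timestamp], landscape,
                          field, radius)
    row = df.iloc[0]
    return CovariateVector(**{k: float(row[k]) for k in COVARIATE_COLUMNS})


@dataclass
class StandardizationParams:
    """Per-covariate mean and SD used for z-scoring, kept for prediction.

    ``temp_center`` is the pooled mean temperature used to build the
    quadratic term as a *centered* square, (T - temp_center)², before
    z-scoring.  Centering before squaring spans the same {1, T, T²} space
    but keeps the linear and quadratic columns from being collinear over a
    single growing season, where raw T and T² move almost in lockstep.
    """

    mean: dict[str, float]
    sd: dict[str, float]
    temp_center: float | None = None

    def quadratic_term(self, temp: np.ndarray) -> np.ndarray:
        center = self.temp_center if self.temp_center is not None else 0.0
        return (np.asarray(temp, float) - center) ** 2

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for name in self.mean:
            if name == "temp_sq" and "temp" in df.columns:
                v = self.quadratic_term(df["temp"].to_numpy(float))
            else:
                v = df[name].to_numpy(float)
            out[name] = (v - self.mean[name]) / self.sd[name]
        return pd.DataFrame(out, index=df.index)

    def invert(self, zdf: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for name in self.mean:
            out[name] = zdf[name].to_numpy(float) * self.sd[name] + self.mean[name]
        return pd.DataFrame(out, index=zdf.index)

    def to_dict(self) -> dict:
        return {"mean": dict(self.mean), "sd": dict(self.sd),
                "temp_center": self.temp_center}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationParams":
        return cls(mean=dict(d["mean"]), sd=dict(d["sd"]),
                   temp_center=d.get("temp_center"))


def _as_frame(rows) -> pd.DataFrame:
    if isinstance(rows, pd.DataFrame):
        return rows
    return pd.DataFrame([vars(r) if not isinstance(r, dict) else r for r in rows])


def standardize(rows, params: StandardizationParams | None = None):
    """Z-score covariate columns, pooling all rows (used and available).

    The quadratic temperature term is built as the centered square
    (T - pooled mean T)² and then standardized, so it is z-scored after
    squaring but stays decorrelated from the linear term.  Returns
    (standardized DataFrame, StandardizationParams); passing stored params
    reapplies them unchanged (idempotent given params).
    """
    df = _as_frame(rows).copy()
    cols = [c for c in COVARIATE_COLUMNS if c in df.columns or c == "temp_sq"]
    if "temp" not in df.columns:
        cols = [c for c in cols if c != "temp_sq"]
    if len(df) < 2 and params is None:
        raise ValueError("need at least 2 rows to estimate z-scores")
    if params is None:
        temp_center = (float(df["temp"].to_numpy(float).mean())
                       if "temp" in df.columns else None)
        stage = StandardizationParams(mean={}, sd={}, temp_center=temp_center)
        mean, sd = {}, {}
        for c in cols:
            if c == "temp_sq":
                v = stage.quadratic_term(df["temp"].to_numpy(float))
            else:
                v = df[c].to_numpy(float)
            m, s = float(v.mean()), float(v.std())  # population SD
            if s == 0.0:
                raise DegenerateCovariateError(f"covariate '{c}' has zero spread")
            mean[c], sd[c] = m, s
        params = StandardizationParams(mean=mean, sd=sd,
                                       temp_center=temp_center)
    return params.apply(df), params
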