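"""Space-time near-surface air temperature fields.

The field is a deterministic, queryable stand-in for a downscaled
microclimate model: a seasonal sinusoid plus a diurnal sinusoid whose
amplitude is damped under canopy (closed forest stays cooler by day), plus
a frozen spatially correlated anomaly.  Only the query interface
``T(point, datetime)`` matters downstream; any model exposing it could be
substituted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import Landscape, OutOfExtentError, _correlated_field

__all__ = ["TemperatureParams", "TemperatureField", "make_temperature_field"]

#: warmest day of year and warmest hour of day for the sinusoidal cycles
PEAK_DAY_OF_YEAR = 172.0
PEAK_HOUR = 15.0
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class TemperatureParams:
    """Amplitudes (°C) of the seasonal/diurnal cycles and spatial noise.

    ``canopy_damping`` is the fraction of the diurnal amplitude removed
    under 100% canopy cover: 0 means canopy has no thermal effect, 1 means
    a closed canopy flattens the diurnal cycle entirely.
    """

    mean_temp: float = 20.0
    seasonal_amplitude: float = 8.0
    diurnal_amplitude: float = 6.0
    canopy_damping: float = 0.5
    spatial_noise_sd: float = 1.0
    noise_correlation_length: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if self.seasonal_amplitude < 0 or self.diurnal_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if not 0.0 <= self.canopy_damping <= 1.0:
            raise ValueError("canopy_damping must lie in [0, 1]")
        if self.spatial_noise_sd < 0:
            raise ValueError("spatial_noise_sd must be >= 0")


def seasonal_cycle(day_of_year) -> np.ndarray:
    """Unit sinusoid peaking at day 172 (summer solstice)."""
    doy = np.asarray(day_of_year, dtype=float)
    return np.cos(2.0 * np.pi * (doy - PEAK_DAY_OF_YEAR) / DAYS_PER_YEAR)


def diurnal_cycle(hour) -> np.ndarray:
    """Unit sinusoid peaking at 15:00 local time."""
    h = np.asarray(hour, dtype=float)
    return np.cos(2.0 * np.pi * (h - PEAK_HOUR) / 24.0)


def _time_components(when) -> tuple[np.ndarray, np.ndarray]:
    """Fractional day-of-year and hour-of-day, preserving input shape."""
    arr = np.atleast_1d(np.asarray(when, dtype="datetime64[ns]"))
    idx = pd.DatetimeIndex(arr.ravel())
    frac_hour = (idx.hour + idx.minute / 60.0 + idx.second / 3600.0).to_numpy()
    doy = idx.dayofyear.to_numpy(dtype=float) + frac_hour / 24.0
    return doy.reshape(arr.shape), frac_hour.reshape(arr.shape)


class TemperatureField:
    """Deterministic air-temperature surface queryable at (x, y, datetime)."""

    def __init__(self, landscape: Landscape, params: TemperatureParams):
        params.validate()
        self.landscape = landscape
        self.params = params
        rng = np.random.default_rng(params.seed)
        sigma_cells = params.noise_correlation_length / landscape.cell_size
        self.noise = params.spatial_noise_sd * _correlated_field(
            rng, landscape.shape, sigma_cells
        )

    def at(self, x, y, when) -> np.ndarray:
        """Temperature (°C) at planar points and datetimes (broadcast)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if not np.all(self.landscape.in_extent(x, y)):
            raise OutOfExtentError("temperature query outside raster extent")
        row, col = self.landscape.cell_index(x, y)
        doy, hour = _time_components(when)
        p = self.params
        canopy = self.landscape.canopy[row, col]
        seasonal = p.seasonal_amplitude * seasonal_cycle(doy)
        damping = 1.0 - p.canopy_damping * canopy / 100.0
        diurnal = p.diurnal_amplitude * damping * diurnal_cycle(hour)
        out = p.mean_temp + seasonal + diurnal + self.noise[row, col]
        scalar = x.ndim == 0 and np.asarray(when, dtype="datetime64[ns]").ndim == 0
        out = np.atleast_1d(out)
        return float(out[0]) if scalar else out

    def grid_at(self, when) -> np.ndarray:
        """Temperature of every cell center at one datetime."""
        doy, hour = _time_components(when)
        p = self.params
        damping = 1.0 - p.canopy_damping * self.landscape.canopy / 100.0
        return (
            p.mean_temp
            + p.seasonal_amplitude * float(seasonal_cycle(doy)[0])
            + p.diurnal_amplitude * damping * float(diurnal_cycle(hour)[0])
            + self.noise
        )


def make_temperature_field(landscape: Landscape,
                           params: TemperatureParams) -> TemperatureField:
    """Build the queryable field; deterministic given ``params.seed``."""
    return TemperatureField(landscape, params)
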