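"""Discrete choice sets from telemetry.

Every telemetry fix becomes one choice set: the used location plus
``n_available`` alternatives sampled uniformly within a disk whose radius
reflects daily movement capacity (the mean across individuals of the
maximum straight-line displacement achievable in 24 h).  Locations used on
multiple occasions get fresh availability samples each time.  Covariates
for all alternatives are evaluated at the fix's own timestamp, so
temperature availability is specific to the moment of choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import DEFAULT_BUFFER_RADIUS, CovariateVector, covariates_table
from .landscape import Landscape
from .telemetry import _sample_disk
from .temperature import TemperatureField

__all__ = [
    "ChoiceSet",
    "availability_radius",
    "build_choice_sets",
    "iter_choice_sets",
    "InsufficientDataError",
]

logger = logging.getLogger(__name__)

DEFAULT_N_AVAILABLE = 5
DAY_HOURS = 24.0


class InsufficientDataError(ValueError):
    """Telemetry lacks the fixes needed for the requested statistic."""


@dataclass
class ChoiceSet:
    """One used location and its sampled alternatives.

    ``alternatives`` holds I = 1 + n_available (x, y) points with their
    covariate vectors; ``chosen_index`` marks the used one.
    """

    choice_set_id: int
    snake_id: str
    timestamp: pd.Timestamp
    points: np.ndarray  # (I, 2)
    covariates: list[CovariateVector]
    chosen_index: int


def availability_radius(telemetry: pd.DataFrame) -> float:
    """Mean over individuals of the maximum 24-h straight-line displacement.

    For each individual, all fix pairs no more than 24 h apart are scanned
    for the largest displacement.  When the tracking interval exceeds 24 h
    (so no such pair exists), that individual's maximum consecutive-step
    displacement is scaled by 24 h / (its mean step duration) — a linear
    pro-rating of movement to a daily window.
    """
    maxima = []
    for _, grp in telemetry.groupby("snake_id"):
        grp = grp.sort_values("datetime")
        if len(grp) < 2:
            continue
        ts = pd.to_datetime(grp["datetime"]).to_numpy()
        xy = grp[["x", "y"]].to_numpy(float)
        hours = (ts[:, None] - ts[None, :]) / np.timedelta64(1, "h")
        dist = np.hypot(xy[:, None, 0] - xy[None, :, 0],
                        xy[:, None, 1] - xy[None, :, 1])
        within = (hours > 0) & (hours <= DAY_HOURS)
        if within.any():
            maxima.append(dist[within].max())
        else:
            step_h = np.diff(ts) / np.timedelta64(1, "h")
            step_d = np.hypot(*np.diff(xy, axis=0).T)
            maxima.append(step_d.max() * DAY_HOURS / step_h.mean())
    if not maxima:
        raise InsufficientDataError("no individual with >= 2 fixes")
    return float(np.mean(maxima))


def build_choice_sets(telemetry: pd.DataFrame, landscape: Landscape,
                      field: TemperatureField, radius: float,
                      n_available: int = DEFAULT_N_AVAILABLE,
                      seed: int = 0,
                      buffer_radius: float = DEFAULT_BUFFER_RADIUS,
                      ) -> pd.DataFrame:
    """One choice set per telemetry record, in long format.

    Available points are uniform on the disk of ``radius`` metres around
    the used point (rejection-sampled from the bounding square; points
    falling off the raster are resampled, preserving the exact
    n_available : 1 ratio).  Returns one row per alternative with columns
    choice_set_id, alternative, used, snake_id, sex, datetime, x, y and the
    raw covariates.  Used points outside the raster are skipped with a
    logged count.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    rng = np.random.default_rng(seed)
    # canonical ordering makes construction independent of input row order
    telemetry = telemetry.sort_values(["snake_id", "datetime"],
                                      kind="mergesort").reset_index(drop=True)
    inside = landscape.in_extent(telemetry["x"].to_numpy(float),
                                 telemetry["y"].to_numpy(float))
    n_skipped = int((~inside).sum())
    if n_skipped:
        logger.warning("skipping %d used locations outside the raster extent",
                       n_skipped)

    I = n_available + 1
    frames = []
    set_id = 0
    for idx, rec in telemetry[inside].iterrows():
        ax, ay = _sample_disk(rng, float(rec["x"]), float(rec["y"]),
                              radius, n_available, landscape)
        xs = np.concatenate([[float(rec["x"])], ax])
        ys = np.concatenate([[float(rec["y"])], ay])
        frames.append(pd.DataFrame({
            "choice_set_id": set_id,
            "alternative": np.arange(I),
            "used": np.arange(I) == 0,
            "snake_id": rec["snake_id"],
            "sex": rec.get("sex", ""),
            "datetime": pd.Timestamp(rec["datetime"]),
            "x": xs,
            "y": ys,
        }))
        set_id += 1
    if not frames:
        raise InsufficientDataError("no usable telemetry records")
    long = pd.concat(frames, ignore_index=True)
    covs = covariates_table(
        long["x"].to_numpy(float), long["y"].to_numpy(float),
        long["datetime"].to_numpy(), landscape, field, buffer_radius,
    )
    return pd.concat([long, covs], axis=1)


def iter_choice_sets(frame: pd.DataFrame):
    """Yield :class:`ChoiceSet` objects from the long-format frame."""
    from .covariates import COVARIATE_COLUMNS

    for sid, grp in frame.groupby("choice_set_id", sort=True):
        grp = grp.sort_values("alternative")
        covs = [CovariateVector(**{c: float(r[c]) for c in COVARIATE_COLUMNS})
                for _, r in grp.iterrows()]
        yield ChoiceSet(
            choice_set_id=int(sid),
            snake_id=str(grp["snake_id"].iloc[0]),
            timestamp=pd.Timestamp(grp["datetime"].iloc[0]),
            points=grp[["x", "y"]].to_numpy(float),
            covariates=covs,
            chosen_index=int(np.flatnonzero(grp["used"].to_numpy())[0]),
        )
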