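"""Post-fit inference products: seasonal effect curves and use surfaces.

Effect curves show the relative probability that a location with covariate
value v is selected over an otherwise identical location held at the
observed covariate mean — a two-alternative softmax contrast, which pins
the curve to exactly 0.5 at the mean.  Seasonality enters through the
day-of-year interaction, so curves drawn for an early and a late date
(e.g. 31 May vs 31 August) separate only where that interaction is
nonzero.

Use surfaces map min–max-normalized exp(utility) over the landscape at a
given datetime, using the posterior means of the population coefficients;
cells whose covariate buffer extends off the raster are masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import (DEFAULT_BUFFER_RADIUS, StandardizationParams,
                         covariates_table)
from .landscape import Landscape
from .model import INTERACTION_SEP, PosteriorDraws
from .temperature import TemperatureField, _time_components

__all__ = ["EffectCurve", "UseSurface", "effect_curve", "use_surface"]


@dataclass
class EffectCurve:
    covariate: str
    date: pd.Timestamp
    values: np.ndarray       # raw covariate grid
    mean: np.ndarray         # posterior-mean relative selection probability
    lower95: np.ndarray
    upper95: np.ndarray
    reference_value: float   # observed covariate mean (curve = 0.5 there)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "covariate": self.covariate,
            "date": self.date,
            "value": self.values,
            "mean": self.mean,
            "lower95": self.lower95,
            "upper95": self.upper95,
        })


@dataclass
class UseSurface:
    values: np.ndarray       # (n_rows, n_cols) in [0, 1], NaN where masked
    when: pd.Timestamp
    model: str
    origin: tuple[float, float]
    cell_size: float


def _mu_draws(posterior: PosteriorDraws) -> np.ndarray:
    if posterior.groups is not None:
        # average the group-level means for a population-level curve
        return posterior.mu.mean(axis=1)
    return posterior.mu


def effect_curve(posterior: PosteriorDraws, params: StandardizationParams,
                 covariate: str, date, grid=None,
                 n_grid: int = 100) -> EffectCurve:
    """Relative selection probability across a covariate's range at a date.

    For each grid value v (in raw units), every posterior draw contributes
    psi = exp(u(v)) / (exp(u(v)) + exp(u(mean))) with u built from the
    draw's main effect and its day-of-year interaction evaluated at
    ``date``; the band is the 2.5–97.5 percentile across draws.
    """
    if covariate not in posterior.terms:
        raise ValueError(f"{covariate!r} is not a term of the fitted model")
    mu = _mu_draws(posterior)
    k_main = posterior.terms.index(covariate)
    inter = f"{covariate}{INTERACTION_SEP}day_of_year"
    k_inter = posterior.terms.index(inter) if inter in posterior.terms else None

    m = params.mean[covariate]
    s = params.sd[covariate]
    if grid is None:
        grid = np.linspace(m - 2.5 * s, m + 2.5 * s, n_grid)
    grid = np.asarray(grid, float)
    v_z = (grid - m) / s

    doy, _ = _time_components(pd.Timestamp(date).to_datetime64())
    doy_z = (float(doy[0]) - params.mean["day_of_year"]) / params.sd["day_of_year"]

    slope = mu[:, k_main].copy()
    if k_inter is not None:
        slope += mu[:, k_inter] * doy_z
    # u(v) - u(mean) = slope * v_z, so psi is a logistic in v_z per draw
    eta = slope[:, None] * v_z[None, :]
    psi = 1.0 / (1.0 + np.exp(-eta))
    lo, hi = np.percentile(psi, [2.5, 97.5], axis=0)
    return EffectCurve(
        covariate=covariate, date=pd.Timestamp(date), values=grid,
        mean=psi.mean(axis=0), lower95=lo, upper95=hi, reference_value=m,
    )


def use_surface(posterior: PosteriorDraws, landscape: Landscape,
                field: TemperatureField, when,
                params: StandardizationParams,
                buffer_radius: float = DEFAULT_BUFFER_RADIUS) -> UseSurface:
    """Relative probability of use over the landscape at one datetime.

    Every cell center gets the same covariates as a telemetry location
    (buffer statistics and time-specific temperature), standardized with
    the stored analysis parameters; utilities use the posterior means of
    the population coefficients, and exp(utility) is min–max normalized to
    [0, 1] per surface.  Cells whose buffer disk leaves the raster are
    masked (NaN).
    """
    when = pd.Timestamp(when)
    cx, cy = landscape.cell_centers()
    nr, nc = landscape.shape
    xs, ys = cx.ravel(), cy.ravel()

    xmin, ymin, xmax, ymax = landscape.extent
    ok = ((xs - buffer_radius >= xmin) & (xs + buffer_radius <= xmax)
          & (ys - buffer_radius >= ymin) & (ys + buffer_radius <= ymax))

    table = covariates_table(xs[ok], ys[ok],
                             np.full(int(ok.sum()), when.to_datetime64()),
                             landscape, field, buffer_radius)
    z = params.apply(table)

    # rebuild the design row-by-term from standardized columns
    from .model import ModelSpec

    spec = ModelSpec("surface", posterior.terms)
    X = spec.design_matrix(z)
    mu_hat = _mu_draws(posterior).mean(axis=0)
    u = X @ mu_hat

    flat = np.full(nr * nc, np.nan)
    lo, hi = u.min(), u.max()
    flat[ok] = (u - lo) / (hi - lo) if hi > lo else 0.5
    return UseSurface(values=flat.reshape(nr, nc), when=when,
                      model="+".join(posterior.terms),
                      origin=landscape.origin, cell_size=landscape.cell_size)
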