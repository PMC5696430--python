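"""Model comparison: WAIC ranking and Estrella's pseudo-R².

WAIC is computed from the pointwise log-likelihood of the retained
posterior draws, with one choice set as the pointwise unit (each set is
one multinomial outcome, the exchangeable contribution to the
likelihood):

    lppd   = sum_i log( mean_s exp(ll_is) )
    p_waic = sum_i var_s(ll_is)
    WAIC   = -2 (lppd - p_waic)        (lower = better support)

Estrella's R² rescales the likelihood-ratio index so that 0 means the
model predicts at random and 1 a perfect fit:

    R² = 1 - (L_fit / L_0)^(-(2/n) L_0)

with L_0 the log-likelihood of random choice within each set and L_fit
the log-likelihood at the posterior means of the individual coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .model import (MCMCConfig, ModelSpec, PosteriorDraws, PriorSpec,
                    assemble_choice_data, fit, log_likelihood,
                    pointwise_log_likelihood)

__all__ = ["ModelScore", "waic", "estrella_r2", "null_log_likelihood",
           "rank_models"]

logger = logging.getLogger(__name__)


@dataclass
class ModelScore:
    name: str
    waic: float
    lppd: float
    p_waic: float
    estrella_r2: float
    n_sets: int


def waic(pointwise_ll: np.ndarray) -> tuple[float, float, float]:
    """(waic, lppd, p_waic) from a (draws, n_sets) pointwise array."""
    ll = np.asarray(pointwise_ll, float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("WAIC needs >= 2 posterior draws")
    S = ll.shape[0]
    lppd = float((logsumexp(ll, axis=0) - np.log(S)).sum())
    p_waic = float(ll.var(axis=0, ddof=1).sum())
    return -2.0 * (lppd - p_waic), lppd, p_waic


def estrella_r2(loglik_fit: float, loglik_null: float, n: int) -> float:
    """Estrella's goodness-of-fit measure for discrete outcome models."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if loglik_fit > 0 or loglik_null >= 0:
        raise ValueError("log-likelihoods of discrete outcomes must be < 0")
    if loglik_fit < loglik_null:
        logger.warning("fitted log-likelihood below the null model's")
    return float(1.0 - (loglik_fit / loglik_null) ** (-(2.0 / n) * loglik_null))


def null_log_likelihood(set_sizes: np.ndarray) -> float:
    """Log-likelihood of random choice: sum of -ln(I) over choice sets."""
    return float(-np.log(np.asarray(set_sizes, float)).sum())


def rank_models(frame: pd.DataFrame, specs: list[ModelSpec],
                priors: PriorSpec = PriorSpec(),
                mcmc: MCMCConfig = MCMCConfig(),
                ) -> tuple[pd.DataFrame, dict[str, PosteriorDraws]]:
    """Fit every candidate model and rank by ascending WAIC.

    The null model is scored analytically (its likelihood is constant at
    -ln I per set, so p_waic = 0 and R² = 0 exactly).  A model whose fit
    fails is reported with NaN scores; the others continue.  Returns the
    ranking table plus the posterior of each fitted model.
    """
    if not specs:
        raise ValueError("specs must be nonempty")
    scores: list[ModelScore] = []
    posteriors: dict[str, PosteriorDraws] = {}
    for spec in specs:
        data, _ = assemble_choice_data(frame, spec)
        sizes = np.full(data.n_sets, data.n_alternatives)
        ll0 = null_log_likelihood(sizes)
        if spec.k == 0:
            lppd = ll0
            scores.append(ModelScore(spec.name, -2.0 * lppd, lppd, 0.0, 0.0,
                                     data.n_sets))
            continue
        try:
            posterior = fit(data, priors, mcmc)
            posteriors[spec.name] = posterior
            pw = pointwise_log_likelihood(data, posterior)
            w, lppd, p = waic(pw)
            ll_fit, _ = log_likelihood(data, posterior.beta_mean())
            r2 = estrella_r2(ll_fit, ll0, data.n_sets)
            scores.append(ModelScore(spec.name, w, lppd, p, r2, data.n_sets))
        except Exception:  # keep ranking the remaining models
            logger.exception("fit failed for model %s", spec.name)
            scores.append(ModelScore(spec.name, np.nan, np.nan, np.nan,
                                     np.nan, data.n_sets))
    table = pd.DataFrame([vars(s) for s in scores])
    return table.sort_values("waic", na_position="last").reset_index(drop=True), \
        posteriors
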