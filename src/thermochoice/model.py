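"""Hierarchical Bayesian discrete choice (mixed conditional logit).

Each individual j chooses among the I alternatives of a choice set with
probability

    psi_ij = exp(U_ij) / sum_i exp(U_ij),     U_ij = beta_j' x_ij,

where x_ij is the alternative's standardized covariate vector and beta_j
the individual's coefficient vector.  Individual coefficients are tied
together by a normal population distribution, beta_jk ~ N(mu_k, sigma_k^2),
which shares strength across individuals and absorbs the non-independence
of repeated fixes.  Priors are vague: mu_k ~ N(0, 100), sigma_k ~ U(0, 10).

Posteriors are sampled by a Metropolis-within-Gibbs scheme: adaptive
random-walk Metropolis for each beta_j (jointly over its K components),
the conjugate normal draw for each mu_k, and random-walk Metropolis on
(0, 10) for each sigma_k.  The default schedule runs three chains of
25,000 iterations, discards 10,000 as burn-in and thins by 15, retaining
3,000 draws in total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "CANDIDATE_MODELS",
    "candidate_model",
    "ChoiceData",
    "PriorSpec",
    "MCMCConfig",
    "PosteriorDraws",
    "assemble_choice_data",
    "utility",
    "choice_probs",
    "log_likelihood",
    "pointwise_log_likelihood",
    "fit",
    "fit_by_sex",
    "rhat",
    "rhat_table",
    "summarize",
]

MAIN_EFFECTS = ("canopy_mean", "canopy_sd", "understory_mean",
                "temp", "temp_sq", "temp_sd")
#: covariates allowed to interact with day of year (temperature preference
#: is assumed seasonally constant, so temp and temp_sq carry no interaction)
SEASONAL_EFFECTS = ("canopy_mean", "canopy_sd", "understory_mean", "temp_sd")
INTERACTION_SEP = ":"


@dataclass(frozen=True)
class ModelSpec:
    """A named set of covariate terms.

    A term is either a main-effect name or ``"<name>:day_of_year"`` for a
    seasonal interaction.  Interactions multiply the standardized main
    effect by standardized day of year (both z-scored before the product).
    Day of year never enters as a main effect: it is constant within a
    choice set and would cancel in the softmax.
    """

    name: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        seen = set()
        for t in self.terms:
            if t in seen:
                raise ValueError(f"duplicate term {t!r}")
            seen.add(t)
            base, _, inter = t.partition(INTERACTION_SEP)
            if base not in MAIN_EFFECTS:
                raise ValueError(f"unknown covariate {base!r}")
            if inter and (inter != "day_of_year" or base not in SEASONAL_EFFECTS):
                raise ValueError(f"unsupported interaction {t!r}")

    @property
    def k(self) -> int:
        return len(self.terms)

    def design_matrix(self, z: pd.DataFrame) -> np.ndarray:
        """(n_rows, K) design from a frame of standardized covariates."""
        cols = []
        for t in self.terms:
            base, _, inter = t.partition(INTERACTION_SEP)
            v = z[base].to_numpy(float)
            if inter:
                v = v * z["day_of_year"].to_numpy(float)
            cols.append(v)
        if not cols:
            return np.zeros((len(z), 0))
        return np.column_stack(cols)


def _with_season(effects) -> tuple[str, ...]:
    out = list(effects)
    out += [f"{e}{INTERACTION_SEP}day_of_year" for e in effects
            if e in SEASONAL_EFFECTS]
    return tuple(out)


HABITAT = ("canopy_mean", "canopy_sd", "understory_mean")
TEMPERATURE = ("temp", "temp_sq", "temp_sd")

#: the a priori candidate set, from the null model to the full
#: habitat + temperature + season model (10 terms)
CANDIDATE_MODELS: tuple[ModelSpec, ...] = (
    ModelSpec("null", ()),
    ModelSpec("habitat_only", HABITAT),
    ModelSpec("temperature_only", TEMPERATURE),
    ModelSpec("habitat_temperature", HABITAT + TEMPERATURE),
    ModelSpec("habitat_season", _with_season(HABITAT)),
    ModelSpec("temperature_season", _with_season(TEMPERATURE)),
    ModelSpec("habitat_temperature_season", _with_season(HABITAT + TEMPERATURE)),
)


def candidate_model(name: str) -> ModelSpec:
    for spec in CANDIDATE_MODELS:
        if spec.name == name:
            return spec
    raise KeyError(f"unknown candidate model {name!r}")


@dataclass
class ChoiceData:
    """Design arrays for fitting: X[(set, alternative, term)], the chosen
    alternative per set, and the individual owning each set."""

    X: np.ndarray            # (n_sets, I, K)
    chosen: np.ndarray       # (n_sets,)
    set_individual: np.ndarray  # (n_sets,) index into individuals
    individuals: list[str]
    sex: list[str]           # per individual
    spec: ModelSpec

    @property
    def n_sets(self) -> int:
        return self.X.shape[0]

    @property
    def n_alternatives(self) -> int:
        return self.X.shape[1]

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)


def assemble_choice_data(frame: pd.DataFrame, spec: ModelSpec,
                         params=None) -> tuple[ChoiceData, "StandardizationParams"]:
    """Standardize a long-format choice-set frame and build design arrays.

    Covariates are z-scored over the pooled used + available rows (or with
    supplied params, e.g. at prediction time).
    """
    from .covariates import standardize

    frame = frame.sort_values(["choice_set_id", "alternative"]).reset_index(drop=True)
    z, params = standardize(frame, params=params)
    design = spec.design_matrix(z)

    sizes = frame.groupby("choice_set_id", sort=True).size()
    if sizes.nunique() != 1:
        raise ValueError("all choice sets must have the same number of alternatives")
    I = int(sizes.iloc[0])
    n = len(sizes)
    X = design.reshape(n, I, spec.k)

    per_set = frame[frame["alternative"] == 0].sort_values("choice_set_id")
    individuals = sorted(per_set["snake_id"].astype(str).unique())
    ind_index = {s: i for i, s in enumerate(individuals)}
    set_individual = per_set["snake_id"].astype(str).map(ind_index).to_numpy()
    sex_map = per_set.groupby(per_set["snake_id"].astype(str))["sex"].first()
    sex = [str(sex_map[s]) for s in individuals]

    chosen = (
        frame.loc[frame["used"].astype(bool), ["choice_set_id", "alternative"]]
        .sort_values("choice_set_id")["alternative"].to_numpy()
    )
    if len(chosen) != n:
        raise ValueError("each choice set must have exactly one used alternative")
    data = ChoiceData(X=X, chosen=chosen, set_individual=set_individual,
                      individuals=individuals, sex=sex, spec=spec)
    return data, params


@dataclass(frozen=True)
class PriorSpec:
    """Vague priors: mu_k ~ N(0, 100), sigma_k ~ U(0, 10)."""

    mu_mean: float = 0.0
    mu_var: float = 100.0
    sigma_lower: float = 0.0
    sigma_upper: float = 10.0

    def validate(self) -> None:
        if self.mu_var <= 0:
            raise ValueError("mu_var must be > 0")
        if not self.sigma_upper > self.sigma_lower >= 0:
            raise ValueError("need sigma_upper > sigma_lower >= 0")


@dataclass(frozen=True)
class MCMCConfig:
    n_chains: int = 3
    n_iter: int = 25_000
    n_burn: int = 10_000
    thin: int = 15
    adapt_interval: int = 50
    target_accept: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.n_burn < self.n_iter:
            raise ValueError("need 0 <= n_burn < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def draws_per_chain(self) -> int:
        return (self.n_iter - self.n_burn) // self.thin

    @property
    def total_draws(self) -> int:
        return self.n_chains * self.draws_per_chain


@dataclass
class PosteriorDraws:
    """Retained MCMC draws.  For sex-grouped fits mu/sigma gain a group
    axis and ``groups`` names it."""

    mu: np.ndarray       # (S, K) or (S, G, K)
    sigma: np.ndarray    # same shape as mu
    beta: np.ndarray     # (S, J, K)
    chain: np.ndarray    # (S,)
    terms: tuple[str, ...]
    individuals: list[str]
    groups: list[str] | None = None

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0]

    def beta_mean(self) -> np.ndarray:
        return self.beta.mean(axis=0)


# ---------------------------------------------------------------------------
# likelihood

def utility(beta_j: np.ndarray, x_ij: np.ndarray) -> float:
    """U_ij = beta_j' x_ij."""
    beta_j = np.asarray(beta_j, float)
    x_ij = np.asarray(x_ij, float)
    if beta_j.shape != x_ij.shape:
        raise ValueError("beta and covariate vectors must have equal length")
    return float(beta_j @ x_ij) if beta_j.size else 0.0


def choice_probs(utilities) -> np.ndarray:
    """Stable softmax over one choice set's utilities."""
    u = np.asarray(utilities, dtype=float)
    e = np.exp(u - u.max())
    return e / e.sum()


def _set_loglik(X: np.ndarray, chosen: np.ndarray, beta_rows: np.ndarray):
    """Per-set log psi(chosen) for per-set coefficient rows (n, K)."""
    if X.shape[2] == 0:
        return np.full(X.shape[0], -np.log(X.shape[1]))
    u = np.einsum("nik,nk->ni", X, beta_rows)
    m = u.max(axis=1)
    lse = m + np.log(np.exp(u - m[:, None]).sum(axis=1))
    return u[np.arange(len(chosen)), chosen] - lse


def log_likelihood(data: ChoiceData, beta: np.ndarray):
    """Total log-likelihood and the per-choice-set pointwise vector.

    ``beta`` is the (J, K) matrix of individual coefficients.
    """
    beta = np.asarray(beta, float)
    if beta.shape != (data.n_individuals, data.spec.k):
        raise ValueError("beta must be (n_individuals, K)")
    pointwise = _set_loglik(data.X, data.chosen, beta[data.set_individual])
    return float(pointwise.sum()), pointwise


def pointwise_log_likelihood(data: ChoiceData,
                             posterior: PosteriorDraws) -> np.ndarray:
    """(S, n_sets) pointwise log-likelihood over retained draws (for WAIC)."""
    S = posterior.n_draws
    out = np.empty((S, data.n_sets))
    for s in range(S):
        out[s] = _set_loglik(data.X, data.chosen,
                             posterior.beta[s][data.set_individual])
    return out


# ---------------------------------------------------------------------------
# sampler

def _loglik_by_individual(data: ChoiceData, beta: np.ndarray) -> np.ndarray:
    ll = _set_loglik(data.X, data.chosen, beta[data.set_individual])
    return np.bincount(data.set_individual, weights=ll,
                       minlength=data.n_individuals)


def _run_chain(data: ChoiceData, priors: PriorSpec, mcmc: MCMCConfig,
               group_of: np.ndarray, n_groups: int,
               rng: np.random.Generator):
    """One chain of the Metropolis-within-Gibbs sampler.

    ``group_of`` maps individuals to population groups (all zeros for the
    ungrouped model); mu and sigma are (G, K) internally.
    """
    J, K = data.n_individuals, data.spec.k
    G = n_groups
    group_sizes = np.bincount(group_of, minlength=G).astype(float)

    for _ in range(20):  # over-dispersed, likelihood-finite initialization
        mu = rng.normal(0.0, 1.0, size=(G, K))
        sigma = rng.uniform(0.5, 2.0, size=(G, K))
        beta = mu[group_of] + sigma[group_of] * rng.standard_normal((J, K))
        ll_ind = _loglik_by_individual(data, beta)
        if np.all(np.isfinite(ll_ind)):
            break
    else:
        raise RuntimeError("could not find a finite-likelihood start")

    step_beta = np.full(J, 0.2)
    step_sigma = np.full((G, K), 0.2)
    acc_beta = np.zeros(J)
    acc_sigma = np.zeros((G, K))

    S = mcmc.draws_per_chain
    out_mu = np.empty((S, G, K))
    out_sigma = np.empty((S, G, K))
    out_beta = np.empty((S, J, K))
    s = 0

    for t in range(1, mcmc.n_iter + 1):
        # (a) individual coefficients: joint random-walk per individual
        prop = beta + step_beta[:, None] * rng.standard_normal((J, K))
        ll_prop = _loglik_by_individual(data, prop)
        mu_j = mu[group_of]
        sig_j = sigma[group_of]
        lp_cur = -0.5 * (((beta - mu_j) / sig_j) ** 2).sum(axis=1)
        lp_prop = -0.5 * (((prop - mu_j) / sig_j) ** 2).sum(axis=1)
        accept = np.log(rng.random(J)) < (ll_prop + lp_prop) - (ll_ind + lp_cur)
        beta[accept] = prop[accept]
        ll_ind[accept] = ll_prop[accept]
        acc_beta += accept

        # (b) population means: conjugate normal full conditional
        sums = np.zeros((G, K))
        np.add.at(sums, group_of, beta)
        prec = group_sizes[:, None] / sigma**2 + 1.0 / priors.mu_var
        mean = (sums / sigma**2 + priors.mu_mean / priors.mu_var) / prec
        mu = mean + rng.standard_normal((G, K)) / np.sqrt(prec)

        # (c) population SDs: random-walk Metropolis on (lower, upper)
        sprop = sigma + step_sigma * rng.standard_normal((G, K))
        ok = (sprop > priors.sigma_lower) & (sprop < priors.sigma_upper)
        sq = np.zeros((G, K))
        np.add.at(sq, group_of, (beta - mu[group_of]) ** 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll_cur_s = -group_sizes[:, None] * np.log(sigma) - 0.5 * sq / sigma**2
            ll_prop_s = np.where(
                ok, -group_sizes[:, None] * np.log(np.abs(sprop))
                - 0.5 * sq / sprop**2, -np.inf)
        acc = ok & (np.log(rng.random((G, K))) < ll_prop_s - ll_cur_s)
        sigma = np.where(acc, sprop, sigma)
        acc_sigma += acc

        # adapt proposal scales toward the target rate during burn-in only
        if t <= mcmc.n_burn and t % mcmc.adapt_interval == 0:
            rate_b = acc_beta / mcmc.adapt_interval
            step_beta *= np.exp(np.clip(rate_b - mcmc.target_accept, -0.5, 0.5))
            rate_s = acc_sigma / mcmc.adapt_interval
            step_sigma *= np.exp(np.clip(rate_s - mcmc.target_accept, -0.5, 0.5))
            acc_beta[:] = 0.0
            acc_sigma[:] = 0.0

        if t > mcmc.n_burn and (t - mcmc.n_burn) % mcmc.thin == 0:
            out_mu[s] = mu
            out_sigma[s] = sigma
            out_beta[s] = beta
            s += 1

    return out_mu[:s], out_sigma[:s], out_beta[:s]


def _fit_grouped(data: ChoiceData, priors: PriorSpec, mcmc: MCMCConfig,
                 group_of: np.ndarray, groups: list[str] | None) -> PosteriorDraws:
    priors.validate()
    mcmc.validate()
    G = len(groups) if groups else 1
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    mus, sigmas, betas, chains = [], [], [], []
    for c, ss in enumerate(seeds):
        m, sg, b = _run_chain(data, priors, mcmc, group_of, G,
                              np.random.default_rng(ss))
        mus.append(m)
        sigmas.append(sg)
        betas.append(b)
        chains.append(np.full(len(m), c))
    mu = np.concatenate(mus)
    sigma = np.concatenate(sigmas)
    if groups is None:
        mu = mu[:, 0, :]
        sigma = sigma[:, 0, :]
    return PosteriorDraws(
        mu=mu, sigma=sigma, beta=np.concatenate(betas),
        chain=np.concatenate(chains), terms=data.spec.terms,
        individuals=list(data.individuals), groups=groups,
    )


def fit(data: ChoiceData, priors: PriorSpec = PriorSpec(),
        mcmc: MCMCConfig = MCMCConfig()) -> PosteriorDraws:
    """Sample the posterior of the hierarchical discrete choice model.

    The null model (K = 0) has nothing to fit and returns empty draws.
    """
    if data.spec.k == 0:
        S = mcmc.n_chains * mcmc.draws_per_chain
        return PosteriorDraws(
            mu=np.zeros((S, 0)), sigma=np.zeros((S, 0)),
            beta=np.zeros((S, data.n_individuals, 0)),
            chain=np.repeat(np.arange(mcmc.n_chains), mcmc.draws_per_chain),
            terms=(), individuals=list(data.individuals))
    group_of = np.zeros(data.n_individuals, dtype=int)
    return _fit_grouped(data, priors, mcmc, group_of, None)


def fit_by_sex(data: ChoiceData, priors: PriorSpec = PriorSpec(),
               mcmc: MCMCConfig = MCMCConfig()) -> PosteriorDraws:
    """Refit with sex-specific population parameters.

    beta_jk ~ N(mu_k^sex(j), (sigma_k^sex(j))^2); the sampler is otherwise
    identical.  Draw arrays gain a group axis ordered as ``groups``.
    """
    if any(s not in ("M", "F") for s in data.sex):
        raise ValueError("every individual needs a sex label in {'M', 'F'}")
    groups = sorted(set(data.sex))
    gmap = {g: i for i, g in enumerate(groups)}
    group_of = np.array([gmap[s] for s in data.sex])
    return _fit_grouped(data, priors, mcmc, group_of, groups)


# ---------------------------------------------------------------------------
# diagnostics and summaries

def rhat(chains: np.ndarray) -> float:
    """Gelman–Rubin potential scale reduction for one parameter.

    ``chains`` is (n_chains, n_draws).  Values near 1 indicate the chains
    have mixed; > 1.1 is the conventional warning level.
    """
    chains = np.asarray(chains, float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("rhat needs >= 2 chains")
    m, n = chains.shape
    w = chains.var(axis=1, ddof=1).mean()
    b = n * chains.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else np.inf
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _param_frame(posterior: PosteriorDraws):
    """Iterate (label, draws (S,)) over population-level parameters."""
    if posterior.groups is None:
        for k, t in enumerate(posterior.terms):
            yield f"mu[{t}]", posterior.mu[:, k]
            yield f"sigma[{t}]", posterior.sigma[:, k]
    else:
        for g, gname in enumerate(posterior.groups):
            for k, t in enumerate(posterior.terms):
                yield f"mu[{t}|{gname}]", posterior.mu[:, g, k]
                yield f"sigma[{t}|{gname}]", posterior.sigma[:, g, k]


def rhat_table(posterior: PosteriorDraws, threshold: float = 1.1) -> pd.DataFrame:
    """R-hat for every population-level parameter, flagging > threshold."""
    rows = []
    chain_ids = np.unique(posterior.chain)
    for label, draws in _param_frame(posterior):
        per_chain = np.stack([draws[posterior.chain == c] for c in chain_ids])
        r = rhat(per_chain)
        rows.append({"parameter": label, "rhat": r, "flagged": r > threshold})
    return pd.DataFrame(rows)


def summarize(posterior: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean, SD and 95% credible interval per population mean —
    the coefficient-table view of a fitted model."""
    rows = []
    labels = (
        [(t, posterior.mu[:, k]) for k, t in enumerate(posterior.terms)]
        if posterior.groups is None else
        [(f"{t}|{g}", posterior.mu[:, gi, k])
         for gi, g in enumerate(posterior.groups)
         for k, t in enumerate(posterior.terms)]
    )
    for name, draws in labels:
        lo, hi = np.percentile(draws, [2.5, 97.5])
        rows.append({
            "term": name,
            "posterior_mean": draws.mean(),
            "posterior_sd": draws.std(ddof=1),
            "ci_2.5": lo,
            "ci_97.5": hi,
        })
    return pd.DataFrame(rows)
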