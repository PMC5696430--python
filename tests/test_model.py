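import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermochoice.model import (CANDIDATE_MODELS, ChoiceData, MCMCConfig,
                                ModelSpec, assemble_choice_data,
                                candidate_model, choice_probs, fit,
                                fit_by_sex, log_likelihood,
                                pointwise_log_likelihood, rhat, rhat_table,
                                summarize, utility)


# ---------------------------------------------------------------------------
# model specifications

def test_candidate_set_matches_hypothesis_list():
    names = [s.name for s in CANDIDATE_MODELS]
    assert names == ["null", "habitat_only", "temperature_only",
                     "habitat_temperature", "habitat_season",
                     "temperature_season", "habitat_temperature_season"]
    assert candidate_model("null").k == 0
    # the full model carries 10 coefficients: 6 main effects + 4 seasonal
    # interactions (temperature preference has no seasonal interaction)
    full = candidate_model("habitat_temperature_season")
    assert full.k == 10
    assert "temp:day_of_year" not in full.terms
    assert "temp_sq:day_of_year" not in full.terms
    assert "temp_sd:day_of_year" in full.terms


def test_spec_rejects_bad_terms():
    with pytest.raises(ValueError):
        ModelSpec("dup", ("temp", "temp"))
    with pytest.raises(ValueError):
        ModelSpec("bad", ("elevation",))
    with pytest.raises(ValueError):
        ModelSpec("bad", ("temp:day_of_year",))


# ---------------------------------------------------------------------------
# utilities and probabilities

@pytest.mark.parametrize("beta,x,expected", [
    (np.zeros(3), np.array([1.0, 2.0, 3.0]), 0.0),
    (np.array([1.0, 2.0]), np.array([3.0, -1.0]), 1.0),
    (np.zeros(0), np.zeros(0), 0.0),
])
def test_utility_is_inner_product(beta, x, expected):
    assert utility(beta, x) == expected


def test_utility_length_mismatch():
    with pytest.raises(ValueError):
        utility(np.zeros(2), np.zeros(3))


def test_choice_probs_uniform_and_closed_form():
    np.testing.assert_allclose(choice_probs(np.zeros(6)), np.full(6, 1 / 6))
    np.testing.assert_allclose(choice_probs([math.log(2), 0.0, 0.0]),
                               [0.5, 0.25, 0.25])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(-30, 30), min_size=2, max_size=8),
       st.floats(-100, 100))
def test_choice_probs_shift_invariant_and_normalized(us, c):
    u = np.asarray(us)
    p = choice_probs(u)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(p, choice_probs(u + c), atol=1e-12)


# ---------------------------------------------------------------------------
# likelihood

def _tiny_data(X, chosen, ind, J, terms=("canopy_mean",)):
    return ChoiceData(X=X, chosen=np.asarray(chosen),
                      set_individual=np.asarray(ind),
                      individuals=[f"S{j}" for j in range(J)],
                      sex=["M"] * J, spec=ModelSpec("t", terms))


def test_null_model_likelihood_is_uniform():
    n, I = 7, 6
    data = _tiny_data(np.zeros((n, I, 0)), np.zeros(n, int),
                      np.zeros(n, int), 1, terms=())
    total, pw = log_likelihood(data, np.zeros((1, 0)))
    assert total == pytest.approx(n * math.log(1 / I))
    np.testing.assert_allclose(pw, math.log(1 / I))


def test_likelihood_matches_brute_force_enumeration():
    """3 sets, I = 2, K = 1: direct softmax arithmetic per set."""
    X = np.array([[[0.3], [-0.2]], [[1.0], [0.4]], [[-0.5], [0.1]]])
    chosen = [0, 1, 1]
    ind = [0, 0, 1]
    data = _tiny_data(X, chosen, ind, 2)
    beta = np.array([[0.7], [-1.3]])
    total, pw = log_likelihood(data, beta)
    expected = []
    for s in range(3):
        b = beta[ind[s], 0]
        u = X[s, :, 0] * b
        psi = np.exp(u) / np.exp(u).sum()
        expected.append(math.log(psi[chosen[s]]))
    np.testing.assert_allclose(pw, expected, atol=1e-12)
    assert total == pytest.approx(sum(expected), abs=1e-12)


def test_likelihood_invariant_to_within_set_covariate_shift():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((5, 4, 2))
    data = _tiny_data(X, rng.integers(0, 4, 5), np.zeros(5, int), 1,
                      terms=("canopy_mean", "temp"))
    beta = rng.standard_normal((1, 2))
    t0, _ = log_likelihood(data, beta)
    shifted = _tiny_data(X + rng.standard_normal((5, 1, 2)),
                         data.chosen, data.set_individual, 1,
                         terms=("canopy_mean", "temp"))
    t1, _ = log_likelihood(shifted, beta)
    assert t1 == pytest.approx(t0, abs=1e-9)


# ---------------------------------------------------------------------------
# sampler

def test_retained_draw_bookkeeping_small_schedule(synthetic_choice_data):
    data, _ = synthetic_choice_data(3, 10, [0.2], [0.1], seed=1)
    mcmc = MCMCConfig(n_chains=2, n_iter=900, n_burn=300, thin=7, seed=2)
    post = fit(data, mcmc=mcmc)
    assert mcmc.draws_per_chain == (900 - 300) // 7
    assert post.n_draws == 2 * mcmc.draws_per_chain
    assert np.array_equal(np.unique(post.chain), [0, 1])
    assert post.sigma.min() > 0.0 and post.sigma.max() < 10.0


def test_fit_is_deterministic_given_seed(synthetic_choice_data):
    data, _ = synthetic_choice_data(3, 10, [0.2], [0.1], seed=1)
    mcmc = MCMCConfig(n_chains=2, n_iter=600, n_burn=200, thin=5, seed=3)
    a = fit(data, mcmc=mcmc)
    b = fit(data, mcmc=mcmc)
    assert np.array_equal(a.mu, b.mu)
    assert np.array_equal(a.beta, b.beta)


def test_constant_likelihood_recovers_prior(synthetic_choice_data):
    """All alternatives identical -> the data say nothing and the
    population mean's posterior is its N(0, 100) prior."""
    rng = np.random.default_rng(0)
    n, I, J = 10, 3, 4
    X = np.repeat(rng.standard_normal((n, 1, 1)), I, axis=1)
    data = ChoiceData(X=X, chosen=np.zeros(n, int),
                      set_individual=rng.integers(0, J, n),
                      individuals=[f"S{j}" for j in range(J)], sex=["M"] * J,
                      spec=ModelSpec("t", ("canopy_mean",)))
    post = fit(data, mcmc=MCMCConfig(n_chains=3, n_iter=20_000, n_burn=5_000,
                                     thin=5, seed=7))
    assert abs(post.mu.mean()) < 2.0
    assert 8.5 < post.mu.std() < 11.5


def test_posterior_mean_matches_grid_oracle():
    """K = 1, J = 1, I = 2: the sampler's posterior for beta agrees with a
    2-D grid integration over (beta, sigma) with mu marginalized
    analytically (beta | sigma ~ N(0, 100 + sigma^2))."""
    from scipy.stats import norm

    rng = np.random.default_rng(3)
    n = 40
    X = np.zeros((n, 2, 1))
    X[:, 1, 0] = rng.standard_normal(n)
    u = X[:, :, 0] * 0.8
    p = np.exp(u - u.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    chosen = np.array([rng.choice(2, p=pi) for pi in p])
    data = ChoiceData(X=X, chosen=chosen, set_individual=np.zeros(n, int),
                      individuals=["S0"], sex=["M"],
                      spec=ModelSpec("t", ("canopy_mean",)))
    post = fit(data, mcmc=MCMCConfig(n_chains=3, n_iter=8000, n_burn=2000,
                                     thin=3, seed=9))

    bg = np.linspace(-3, 4, 701)
    sg = np.linspace(0.01, 10, 300)
    ll = np.array([(X[np.arange(n), chosen, 0] * b
                    - np.logaddexp(0.0, X[:, 1, 0] * b)).sum() for b in bg])
    prior = norm.logpdf(bg[:, None], 0.0, np.sqrt(100.0 + sg[None, :] ** 2))
    lp = ll[:, None] + prior
    w = np.exp(lp - lp.max())
    pb = w.sum(axis=1)
    pb /= pb.sum()
    grid_mean = float((bg * pb).sum())
    assert post.beta.mean() == pytest.approx(grid_mean, abs=0.05)


def test_sex_grouped_fit_single_sex_matches_shape(synthetic_choice_data):
    data, _ = synthetic_choice_data(4, 12, [0.3, -0.2], [0.1, 0.1], seed=5)
    mcmc = MCMCConfig(n_chains=2, n_iter=800, n_burn=300, thin=5, seed=6)
    post = fit_by_sex(data, mcmc=mcmc)
    assert post.groups == ["F", "M"]
    assert post.mu.shape == (post.n_draws, 2, 2)
    # all-male data reduces to the ungrouped model's shape
    data.sex = ["M"] * data.n_individuals
    post_m = fit_by_sex(data, mcmc=mcmc)
    assert post_m.groups == ["M"]
    assert post_m.mu.shape == (post_m.n_draws, 1, 2)


def test_fit_by_sex_requires_labels(synthetic_choice_data):
    data, _ = synthetic_choice_data(3, 5, [0.1], [0.1], seed=8)
    data.sex = ["M", "", "F"]
    with pytest.raises(ValueError):
        fit_by_sex(data)


def test_null_model_fit_returns_empty_draws(synthetic_choice_data):
    data, _ = synthetic_choice_data(2, 5, [0.1], [0.0], seed=9)
    data.spec = ModelSpec("null", ())
    data.X = np.zeros((data.n_sets, data.n_alternatives, 0))
    mcmc = MCMCConfig(n_chains=3, n_iter=1000, n_burn=400, thin=3, seed=1)
    post = fit(data, mcmc=mcmc)
    assert post.mu.shape == (3 * mcmc.draws_per_chain, 0)


# ---------------------------------------------------------------------------
# convergence diagnostics and summaries

def test_rhat_identical_chains_is_one():
    rng = np.random.default_rng(0)
    draws = rng.standard_normal(500)
    assert rhat(np.stack([draws, draws])) == pytest.approx(1.0, abs=2e-3)


def test_rhat_same_distribution_near_one_and_matches_arviz():
    rng = np.random.default_rng(1)
    chains = rng.standard_normal((3, 1000))
    r = rhat(chains)
    assert r < 1.05
    arviz = pytest.importorskip("arviz")
    r_av = float(arviz.rhat(chains.reshape(3, 1000)))
    # arviz uses rank-normalized split-Rhat; both must sit near 1
    assert abs(r - r_av) < 0.05


def test_rhat_disjoint_chains_flagged():
    rng = np.random.default_rng(2)
    a = rng.normal(0, 0.1, 400)
    b = rng.normal(10, 0.1, 400)
    assert rhat(np.stack([a, b])) > 10


def test_rhat_table_flags_and_summary_layout(synthetic_choice_data):
    data, _ = synthetic_choice_data(3, 10, [0.2, -0.2], [0.1, 0.1], seed=4)
    post = fit(data, mcmc=MCMCConfig(n_chains=2, n_iter=800, n_burn=300,
                                     thin=5, seed=5))
    diag = rhat_table(post)
    assert set(diag.columns) == {"parameter", "rhat", "flagged"}
    assert len(diag) == 2 * data.spec.k
    summary = summarize(post)
    assert list(summary.columns) == ["term", "posterior_mean", "posterior_sd",
                                     "ci_2.5", "ci_97.5"]
    assert (summary["ci_2.5"] <= summary["posterior_mean"]).all()
    assert (summary["posterior_mean"] <= summary["ci_97.5"]).all()


def test_bias_shrinks_with_more_choice_sets(synthetic_choice_data):
    """With sigma = 0, the population-mean error falls as sets accumulate
    (averaged over replicate datasets)."""
    errs = {}
    for sets in (8, 128):
        e = []
        for seed in range(4):
            data, _ = synthetic_choice_data(4, sets, [0.5], [0.0],
                                            seed=300 + seed)
            post = fit(data, mcmc=MCMCConfig(n_chains=2, n_iter=1500,
                                             n_burn=500, thin=5, seed=seed))
            e.append(abs(post.mu.mean(axis=0)[0] - 0.5))
        errs[sets] = np.mean(e)
    assert errs[128] < errs[8]


def test_assemble_choice_data_from_frame(choice_frame):
    spec = candidate_model("habitat_temperature_season")
    data, params = assemble_choice_data(choice_frame, spec)
    assert data.X.shape == (choice_frame["choice_set_id"].nunique(), 6, 10)
    assert np.isfinite(data.X).all()
    assert (data.chosen == 0).all()  # used alternative listed first
    assert len(data.individuals) == 6
    # pointwise log-likelihood hooks up to the posterior draw shapes
    post = fit(data, mcmc=MCMCConfig(n_chains=2, n_iter=300, n_burn=100,
                                     thin=10, seed=1))
    pw = pointwise_log_likelihood(data, post)
    assert pw.shape == (post.n_draws, data.n_sets)
    assert np.all(pw <= 0.0)
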