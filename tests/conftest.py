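import numpy as np
import pytest

import thermochoice as tc
from thermochoice.model import ChoiceData, ModelSpec
from thermochoice.telemetry import TelemetrySimConfig, TrueSelectionParams

#: Table-3-style generating values for the full 10-term model, in the
#: canonical term order of candidate_model("habitat_temperature_season")
FULL_MODEL_MU = np.array(
    [-0.21, 0.09, -0.20, -0.10, -0.10, 0.21, 0.11, -0.22, 0.04, 0.24])


@pytest.fixture(scope="session")
def landscape():
    return tc.generate_landscape(
        tc.LandscapeConfig(n_rows=60, n_cols=60, cell_size=10,
                           correlation_length=60, forest_fraction=0.6, seed=42))


@pytest.fixture(scope="session")
def field(landscape):
    return tc.make_temperature_field(landscape, tc.TemperatureParams(seed=43))


@pytest.fixture(scope="session")
def small_sim(landscape, field):
    """A small full-pipeline simulation shared across tests."""
    spec = tc.candidate_model("habitat_temperature_season")
    truth = TrueSelectionParams(mu=FULL_MODEL_MU, sigma=np.full(10, 0.2),
                                model_spec=spec)
    cfg = TelemetrySimConfig(n_individuals=6, fixes_per_individual=15,
                             availability_radius=250, candidates_per_step=15,
                             seed=44)
    return tc.simulate_telemetry(landscape, field, truth, cfg)


@pytest.fixture(scope="session")
def choice_frame(small_sim, landscape, field):
    return tc.build_choice_sets(small_sim.records, landscape, field,
                                radius=250, n_available=5, seed=45)


def make_synthetic_choice_data(J, sets_per, mu, sigma, seed, I=6):
    """Choice data with i.i.d. standard-normal designs and logit choices —
    a minimal generative model for sampler tests, bypassing the landscape."""
    mu = np.atleast_1d(np.asarray(mu, float))
    sigma = np.atleast_1d(np.asarray(sigma, float))
    K = len(mu)
    rng = np.random.default_rng(seed)
    n = J * sets_per
    X = rng.standard_normal((n, I, K))
    ind = np.repeat(np.arange(J), sets_per)
    beta = mu + sigma * rng.standard_normal((J, K))
    u = np.einsum("nik,nk->ni", X, beta[ind])
    p = np.exp(u - u.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    chosen = np.array([rng.choice(I, p=pi) for pi in p])
    names = ("canopy_mean", "canopy_sd", "understory_mean", "temp",
             "temp_sq", "temp_sd")[:K]
    data = ChoiceData(
        X=X, chosen=chosen, set_individual=ind,
        individuals=[f"S{j:02d}" for j in range(J)],
        sex=["M" if j % 2 == 0 else "F" for j in range(J)],
        spec=ModelSpec("synthetic", tuple(names)))
    return data, beta


@pytest.fixture()
def synthetic_choice_data():
    return make_synthetic_choice_data
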