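import numpy as np
import pytest

from gannetpop.modelspec import ModelSpec
from gannetpop.params import DemographicParams


@pytest.fixture(scope="session")
def best_model_params() -> DemographicParams:
    """Posterior-median coefficients of the best-fitting published model."""
    return DemographicParams(
        alpha0=0.969,
        alpha_lin={"nsAT": 1.546, "prec": 0.139},
        alpha_quad={"nsAT": 0.848},
        beta0=-6.619,
        beta_lin={"SST": 0.881},
        K=np.array([10_000.0]),
    )


@pytest.fixture(scope="session")
def best_model_spec() -> ModelSpec:
    return ModelSpec(
        id="m3.3^251",
        fecundity_terms=(("nsAT", 1), ("nsAT", 2), ("prec", 1)),
        recruitment_terms=(("SST", 1),),
    )


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by inference/forecast tests."""
    from gannetpop.synthetic import generate_study

    return generate_study(seed=42, n_colonies=4, fit_years=(1987, 2016))


@pytest.fixture(scope="session")
def small_fit(small_study):
    """A quick MCMC fit of the generating structure on the small study."""
    from gannetpop import inference as inf

    data = inf.prepare_data(small_study.census, small_study.fecundity,
                            small_study.climate, small_study.colonies,
                            small_study.years, small_study.params_true.K,
                            hpai_statuses=[small_study.hpai_status[c]
                                           for c in small_study.colonies])
    settings = inf.MCMCSettings(chains=2, iters=1500, burnin=700, thin=4, seed=7)
    return inf.run_mcmc(data, small_study.spec_true, small_study.params_true,
                        settings)
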