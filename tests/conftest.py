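import numpy as np
import pytest

from gmmdiag import LongitudinalDataset, nlsy_like_params, simulate_gmm
from gmmdiag.params import ClassParams, MixtureParams

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def truth_params() -> MixtureParams:
    return nlsy_like_params()


@pytest.fixture(scope="session")
def small_data(truth_params):
    """60-subject unbalanced panel from the default generator."""
    return simulate_gmm(truth_params, n_subjects=60, seed=3,
                        missing_pattern="nlsy").dataset


@pytest.fixture(scope="session")
def tiny_balanced_data(truth_params):
    """20-subject complete panel: cheap inputs for exactness checks."""
    return simulate_gmm(truth_params, n_subjects=20, seed=5).dataset


@pytest.fixture()
def one_class_params() -> MixtureParams:
    return MixtureParams(
        pi=np.array([1.0]),
        classes=(ClassParams(beta0=2.0, beta1=1.0, beta2=-0.1,
                             sd_int=0.5, sd_slope=0.2, corr=0.3),),
        sigma_resid=0.5)


def random_class_params(rng) -> ClassParams:
    return ClassParams(
        beta0=rng.normal(2, 1), beta1=rng.normal(1, 0.5),
        beta2=rng.normal(0, 0.2), sd_int=rng.uniform(0.1, 1.0),
        sd_slope=rng.uniform(0.05, 0.5), corr=rng.uniform(-0.9, 0.9))


def random_mixture(rng, K=3) -> MixtureParams:
    pi = rng.dirichlet(np.full(K, 5.0))
    return MixtureParams(pi=pi,
                         classes=tuple(random_class_params(rng)
                                       for _ in range(K)),
                         sigma_resid=rng.uniform(0.2, 0.8))
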