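import numpy as np
import pytest

from digisim.params import ModelParams, SystemState, baseline_params
from digisim.cytometry import NoiseModel


@pytest.fixture(scope="session")
def baseline() -> ModelParams:
    return baseline_params()


@pytest.fixture(scope="session")
def unpaired(baseline) -> ModelParams:
    """Baseline with the pairing reaction switched off (closed-form regime)."""
    return baseline.replace(k_pair=0.0)


@pytest.fixture(scope="session")
def sweep_doses() -> np.ndarray:
    """Dose grid used for coarse sweep checks: 0 plus log-spaced points."""
    return np.concatenate([[0.0], np.logspace(-1, 3, 41)])


@pytest.fixture(scope="session")
def noise_quiet() -> NoiseModel:
    """Noise model with all randomness off and a point-mass autofluorescence."""
    return NoiseModel(sigma_ext=0.0, autofluor_sigma=0.0)


def random_params(rng: np.random.Generator, k_pair: float = 0.0) -> ModelParams:
    """Random positive parameter draw over realistic log-ranges."""
    lu = lambda lo, hi: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return ModelParams(
        alpha_R=lu(0.5, 50.0), beta_R=lu(0.01, 2.0), K_TF=lu(5.0, 500.0),
        n_act=float(rng.uniform(1.0, 4.0)), alpha_S=lu(0.5, 50.0),
        K_R=lu(5.0, 5000.0), n_rep=float(rng.uniform(1.0, 4.0)),
        k_pair=k_pair, delta_mR=lu(0.05, 1.0), delta_mS=lu(0.05, 1.0),
        delta_R=lu(0.005, 0.1), delta_G=lu(0.005, 0.1),
        lambda_R=lu(0.2, 10.0), lambda_G=lu(0.2, 10.0), mu=0.0,
    )


def random_state(rng: np.random.Generator, tf_a: float = 0.0) -> SystemState:
    v = rng.uniform(0.0, 50.0, size=4)
    return SystemState(tf_a=tf_a, mR=v[0], mS=v[1], R=v[2], G=v[3])
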