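import numpy as np
import pytest

from cvxspca import (
    DataMatrix,
    ProblemSpec,
    SolverConfig,
    auto_hyperparams,
    gen_gaussian_matrix,
)


def build_problem(
    data: DataMatrix,
    gamma_frac: float,
    w_seed: int = 7,
    margin: float = 0.05,
    c_m: float = 50.0,
    theta_eta: float = 0.2,
    T: int = 30,
    seed: int = 0,
    **config_kwargs,
):
    """Assemble (problem, config) with auto hyperparameters.

    gamma is expressed as a fraction of ||w||_inf; the conservative
    (c_m=50, theta_eta=0.2) defaults here put the theoretical contraction
    factor below one so stochastic solves are tightly comparable to the
    deterministic oracles.
    """
    lam, eta, m, lip = auto_hyperparams(
        data, margin=margin, c_m=c_m, theta_eta=theta_eta, seed=seed
    )
    w = np.random.default_rng(w_seed).standard_normal(data.d)
    gamma = gamma_frac * float(np.max(np.abs(w)))
    problem = ProblemSpec(lam=lam, w=w, gamma=gamma)
    config = SolverConfig(eta=eta, m=m, T=T, seed=seed, **config_kwargs)
    return problem, config


@pytest.fixture(scope="session")
def small_gaussian() -> DataMatrix:
    """The standard small fixture: 200 samples, 20 features, i.i.d. N(0,1)."""
    return gen_gaussian_matrix(200, 20, seed=42)


@pytest.fixture(scope="session")
def tiny_gaussian() -> DataMatrix:
    return gen_gaussian_matrix(30, 8, seed=5)
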