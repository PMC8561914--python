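"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.distance import cdist


def gaussian_kernel_reference(X, sigma):
    """Direct evaluation of exp(−‖x_i−x_j‖²/(2σ²)), independent of the package."""
    sq = cdist(X, X, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * sigma**2))


def svr_dual_qp_oracle(K, y, C, epsilon):
    """Brute-force solution of the ε-SVR dual by a dense NLP solver.

    Solves the 2N-variable QP with SLSQP run to tight tolerance.  Used
    only as an independent check; shares no code with the SMO path.
    Returns (α⁺, α⁻, objective).
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    N = len(y)

    def obj(a):
        d = a[:N] - a[N:]
        return float(-y @ d + epsilon * a.sum() + 0.5 * d @ (K @ d))

    def grad(a):
        g = K @ (a[:N] - a[N:])
        return np.concatenate([-y + epsilon + g, y + epsilon - g])

    cons = [
        {
            "type": "eq",
            "fun": lambda a: float(a[:N].sum() - a[N:].sum()),
            "jac": lambda a: np.concatenate([np.ones(N), -np.ones(N)]),
        }
    ]
    res = minimize(
        obj,
        np.zeros(2 * N),
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, C)] * (2 * N),
        constraints=cons,
        options={"maxiter": 5000, "ftol": 1e-14},
    )
    assert res.success, f"oracle QP failed: {res.message}"
    return res.x[:N], res.x[N:], float(res.fun)


def random_svr_instance(rng, n, d=3, C=10.0, epsilon=0.1):
    """A random dense SVR instance with a Gaussian kernel (PD for distinct points)."""
    X = rng.normal(size=(n, d))
    y = np.sin(X[:, 0]) + 0.5 * X[:, 1] ** 2 + 0.1 * rng.normal(size=n)
    sigma = float(np.sqrt(d))
    K = gaussian_kernel_reference(X, sigma)
    return K, y, C, epsilon


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort with one informative set (session cache)."""
    from prognosit.synthetic import SyntheticSpec, generate

    spec = SyntheticSpec(
        n_samples=60, n_genes=120, n_sets=6, informative_sets=(0,),
        noise_sd=0.3, seed=7,
    )
    expr, collection, volumes = generate(spec)
    return spec, expr, collection, volumes
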