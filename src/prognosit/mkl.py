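"""The PrognosiT training loop: alternating SVR solves and kernel-weight updates.

The model learns a convex combination K_η = Σ_m η_m K_m of per-gene-set
kernels jointly with the SVR dual coefficients.  The outer problem over η
is constrained to the unit simplex (an ℓ1 constraint, hence sparse
weights); it is attacked by alternating optimization:

1. solve the ε-SVR dual on the combined kernel at the current η,
2. update each weight multiplicatively,

       η_m ← η_m √(αᵀ K_m α) / Σ_o η_o √(αᵀ K_o α),

   with α = α⁺ − α⁻ from step 1,

which is the group-Lasso MKL update carried over from binary
classification to regression.  All weights start at 1/P.  The alternation
monotonically decreases the dual objective (verified empirically here;
the nested problem is nonconvex, so only a local optimum is guaranteed).
Gene sets whose final weight exceeds a small threshold (0.01 by default)
form the selected model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from prognosit.kernels import KernelStack, combine
from prognosit.svr import SVRConfig, SVRSolution, predict, solve_dual

logger = logging.getLogger(__name__)

#: weights below this are snapped to exactly 0 (absorbing state of the
#: multiplicative update); prevents underflow drift
ETA_FLOOR = 1e-12


@dataclass(frozen=True)
class MKLConfig:
    """Settings of the alternating MKL optimization."""

    svr: SVRConfig
    max_iter: int = 200
    eta_tol: float = 1e-6
    selection_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0 <= self.selection_threshold < 1:
            raise ValueError("selection threshold must lie in [0, 1)")


def init_eta(P: int) -> np.ndarray:
    """Uniform simplex initialization: η_m = 1/P."""
    if P < 1:
        raise ValueError("need at least one kernel")
    return np.full(P, 1.0 / P)


class DegenerateAlphaError(RuntimeError):
    """All dual coefficients are zero: the η-update denominator vanishes."""


def update_eta(eta: np.ndarray, alpha: np.ndarray, stack: KernelStack | list[np.ndarray]) -> np.ndarray:
    """One multiplicative kernel-weight update on the unit simplex.

    Round-off can make αᵀK_mα marginally negative on a PSD kernel; it is
    clamped to 0 before the square root.  Exact zeros of η are absorbing.
    """
    matrices = stack.matrices if isinstance(stack, KernelStack) else stack
    eta = np.asarray(eta, dtype=float)
    if len(eta) != len(matrices):
        raise ValueError("eta length must match the number of kernels")
    norms = np.array([np.sqrt(max(float(alpha @ (Km @ alpha)), 0.0)) for Km in matrices])
    weighted = eta * norms
    denom = weighted.sum()
    if denom <= 0.0:
        raise DegenerateAlphaError(
            "all dual coefficients are zero (tube covers every response); "
            "kernel weights cannot be updated"
        )
    new = weighted / denom
    new[new < ETA_FLOOR] = 0.0
    return new / new.sum()


@dataclass
class MKLModel:
    """Fitted PrognosiT model: kernel weights + embedded SVR solution.

    ``objective_trace`` holds the MKL objective per iteration: the
    optimal value of the regularized SVR primal at each η, obtained by
    strong duality as the negative of the minimized dual value.  This is
    the quantity the alternation decreases monotonically (the min-form
    dual value itself increases by the same amount).
    """

    stack: KernelStack = field(repr=False)
    eta: np.ndarray
    solution: SVRSolution
    objective_trace: list[float]
    config: MKLConfig
    converged: bool
    n_iter: int
    degenerate: bool = False
    eta_trace: list[np.ndarray] = field(default_factory=list, repr=False)

    @property
    def set_names(self) -> list[str]:
        return self.stack.names

    def predict(self, X_new_std: np.ndarray) -> np.ndarray:
        """Predict responses for new (already standardized) samples."""
        cross = self.stack.cross_matrices(X_new_std)
        K_cross = combine(cross, self.eta)
        return predict(self.solution, K_cross)

    @property
    def selected_sets(self) -> list[str]:
        names, _ = select(self, self.config.selection_threshold)
        return names

    @property
    def used_gene_count(self) -> int:
        _, count = select(self, self.config.selection_threshold)
        return count

    def to_dict(self) -> dict:
        return {
            "eta": dict(zip(self.stack.names, self.eta.tolist())),
            "sigmas": dict(zip(self.stack.names, self.stack.sigmas)),
            "solution": self.solution.to_dict(),
            "selection_threshold": self.config.selection_threshold,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))


def fit(stack: KernelStack, y: np.ndarray, config: MKLConfig) -> MKLModel:
    """Alternate SVR dual solves and η-updates until convergence.

    Runs at most ``config.max_iter`` iterations (the alternation typically
    settles within tens), stopping early once the ℓ1 change of η drops
    below ``config.eta_tol``.  If the tube is so wide that every dual
    coefficient is zero, the current η is kept and the constant-intercept
    model is returned with a warning.  The reported solution is re-solved
    once at the final η so coefficients and weights are mutually optimal.
    """
    y = np.asarray(y, dtype=float)
    eta = init_eta(stack.P)
    eta_trace: list[np.ndarray] = [eta.copy()]
    trace: list[float] = []
    converged = False
    degenerate = False
    sol: SVRSolution | None = None
    warm = None
    it = 0
    for it in range(1, config.max_iter + 1):
        K = combine(stack, eta)
        sol = solve_dual(K, y, config.svr, warm=warm)
        warm = (sol.alpha_plus, sol.alpha_minus)
        trace.append(-sol.objective)  # primal optimum by strong duality
        try:
            new_eta = update_eta(eta, sol.alpha, stack)
        except DegenerateAlphaError:
            logger.warning(
                "all dual coefficients zero at iteration %d; returning the "
                "constant model at the current kernel weights", it
            )
            degenerate = True
            converged = True
            break
        eta_trace.append(new_eta.copy())
        if np.abs(new_eta - eta).sum() < config.eta_tol:
            eta = new_eta
            converged = True
            break
        eta = new_eta
    # final re-solve so the reported coefficients match the final weights
    K = combine(stack, eta)
    sol = solve_dual(K, y, config.svr, warm=warm)
    trace.append(-sol.objective)
    return MKLModel(
        stack=stack,
        eta=eta,
        solution=sol,
        objective_trace=trace,
        config=config,
        converged=converged,
        n_iter=it,
        degenerate=degenerate,
        eta_trace=eta_trace,
    )


def select(model: MKLModel, threshold: float | None = None) -> tuple[list[str], int]:
    """Sets with η above the threshold, plus the count of genes they use.

    The gene count is the size of the union of matched expression features
    over the selected sets (shared genes counted once).
    """
    if threshold is None:
        threshold = model.config.selection_threshold
    names = [n for n, w in zip(model.stack.names, model.eta) if w > threshold]
    used = set()
    for n in names:
        used.update(model.stack.indices[n])
    return names, len(used)
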