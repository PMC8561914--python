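"""ε-insensitive support vector regression solved in the dual.

The dual QP, in the 2N variables (α⁺, α⁻), is

    min  −Σ y_i (α⁺_i − α⁻_i) + ε Σ (α⁺_i + α⁻_i)
         + ½ ΣΣ (α⁺_i − α⁻_i)(α⁺_j − α⁻_j) K_ij
    s.t. Σ (α⁺_i − α⁻_i) = 0,   0 ≤ α⁺_i, α⁻_i ≤ C,

for a symmetric PSD kernel K.  It is solved here by sequential minimal
optimization (SMO): repeatedly pick the maximally KKT-violating pair of
variables under the single equality constraint and solve the two-variable
subproblem in closed form, with second-order working-set selection.  This
is the same decomposition scheme libsvm uses for this QP; it needs no
external QP solver and its accuracy is controlled by the tolerance on the
maximal KKT violation.

The intercept b is recovered from the KKT conditions: every free support
vector (0 < α < C) pins b exactly; their values are averaged.  With no
free support vector, b is the midpoint of the interval the inequality
conditions leave feasible.

Predictions are ŷ_t = Σ_i (α⁺_i − α⁻_i) K(x_t, x_i) + b.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class SVRConfig:
    """Hyperparameters of the ε-insensitive SVR.

    ``C`` is the box bound on the dual coefficients; ``epsilon`` the tube
    half-width.  Upstream protocol code sets ``epsilon`` as a tuned
    multiplier times the standard deviation of the current training
    responses.  ``tol`` bounds the maximal KKT violation at termination;
    ``jitter`` is a ridge added to the kernel diagonal for numerical
    stability with semidefinite kernels.
    """

    C: float
    epsilon: float
    tol: float = 1e-8
    jitter: float = 1e-10
    max_iter: int = 10_000_000

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")


@dataclass
class SVRSolution:
    """Dual solution: coefficients, intercept and objective value."""

    alpha_plus: np.ndarray
    alpha_minus: np.ndarray
    b: float
    objective: float
    n_iter: int = 0
    config: SVRConfig | None = None

    @property
    def alpha(self) -> np.ndarray:
        """Combined coefficients α_i = α⁺_i − α⁻_i."""
        return self.alpha_plus - self.alpha_minus

    def to_dict(self) -> dict:
        return {
            "alpha_plus": self.alpha_plus.tolist(),
            "alpha_minus": self.alpha_minus.tolist(),
            "b": self.b,
            "objective": self.objective,
            "C": self.config.C if self.config else None,
            "epsilon": self.config.epsilon if self.config else None,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))


class SolverError(RuntimeError):
    """SMO failed to reach the requested KKT tolerance."""


def _smo(
    K: np.ndarray,
    y: np.ndarray,
    cfg: SVRConfig,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Core SMO loop.  Returns (α⁺, α⁻, iterations).

    Internally works on a = [α⁺; α⁻] with signs s = [+1; −1] so the
    equality constraint reads sᵀa = 0 and the Hessian is s sᵀ ∘ [[K,K],[K,K]].
    A warm start (α⁺, α⁻) is feasible for any kernel since the constraints
    do not involve K — used by the MKL loop across η-updates.
    """
    N = len(y)
    Kj = K + cfg.jitter * np.eye(N)
    s = np.concatenate([np.ones(N), -np.ones(N)])
    # linear term: p_k = ε − s_k y_{i(k)}
    p = cfg.epsilon - s * np.concatenate([y, y])
    if warm is not None:
        a = np.concatenate([np.clip(warm[0], 0, cfg.C), np.clip(warm[1], 0, cfg.C)])
        alpha0 = a[:N] - a[N:]
        if abs(alpha0.sum()) > 1e-9:   # SMO preserves sᵀa; must start feasible
            a = np.zeros(2 * N)
            G = p.copy()
        else:
            G = p + s * (Kj @ alpha0)[np.concatenate([np.arange(N), np.arange(N)])]
    else:
        a = np.zeros(2 * N)
        G = p.copy()  # gradient = p + Q a, and a = 0 initially
    C = cfg.C
    idx = np.concatenate([np.arange(N), np.arange(N)])  # sample index of each var

    TAU = 1e-12
    for it in range(cfg.max_iter):
        # I_up: can increase along +s direction; I_low: can decrease
        up = np.where(s > 0, a < C, a > 0)
        low = np.where(s > 0, a > 0, a < C)
        nsg = -s * G
        m_val = np.max(nsg[up]) if up.any() else -np.inf
        M_val = np.min(nsg[low]) if low.any() else np.inf
        if m_val - M_val < cfg.tol:
            return a[:N], a[N:], it
        u_candidates = np.where(up)[0]
        u = u_candidates[np.argmax(nsg[u_candidates])]
        iu = idx[u]
        # second-order selection of v among I_low with violation against u
        v_candidates = np.where(low & (nsg < m_val - TAU))[0]
        if len(v_candidates) == 0:
            v_candidates = np.where(low)[0]
            v_candidates = v_candidates[v_candidates != u]
            if len(v_candidates) == 0:
                return a[:N], a[N:], it
        b_uv = m_val + s[v_candidates] * G[v_candidates]  # > 0 violations
        quad = (
            Kj[iu, iu]
            + Kj[idx[v_candidates], idx[v_candidates]]
            - 2.0 * s[u] * s[v_candidates] * Kj[iu, idx[v_candidates]]
        )
        quad = np.maximum(quad, TAU)
        v = v_candidates[np.argmax(b_uv**2 / quad)]
        iv = idx[v]

        q = Kj[iu, iu] + Kj[iv, iv] - 2.0 * s[u] * s[v] * Kj[iu, iv]
        q = max(q, TAU)
        delta = (-s[u] * G[u] + s[v] * G[v]) / q  # unconstrained step, > 0
        # clip to the box: a_u moves by +s_u*delta restriction, a_v by −s_v*delta
        max_u = (C - a[u]) if s[u] > 0 else a[u]
        max_v = a[v] if s[v] > 0 else (C - a[v])
        t_step = min(delta, max_u, max_v)
        if t_step <= 0:
            return a[:N], a[N:], it
        a[u] += s[u] * t_step
        a[v] -= s[v] * t_step
        # ΔG_k = t · s_k (K_{i(k),iu} − K_{i(k),iv})
        G += t_step * s * (Kj[:, iu][idx] - Kj[:, iv][idx])
    raise SolverError(
        f"SMO did not converge within {cfg.max_iter} iterations "
        f"(KKT violation still above tol={cfg.tol})"
    )


def solve_dual(
    K: np.ndarray,
    y: np.ndarray,
    cfg: SVRConfig,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> SVRSolution:
    """Solve the ε-SVR dual QP on kernel ``K`` for responses ``y``."""
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be a square matrix")
    if len(y) != K.shape[0]:
        raise ValueError("len(y) must equal the kernel dimension")
    if np.any(~np.isfinite(K)) or np.any(~np.isfinite(y)):
        raise ValueError("K and y must be finite (no NaN/inf)")
    ap, am, n_iter = _smo(K, y, cfg, warm=warm)
    # clean round-off: clip to the box, enforce complementarity
    ap = np.clip(ap, 0.0, cfg.C)
    am = np.clip(am, 0.0, cfg.C)
    both = np.minimum(ap, am)
    ap -= both
    am -= both
    sol = SVRSolution(alpha_plus=ap, alpha_minus=am, b=0.0, n_iter=n_iter, objective=0.0, config=cfg)
    sol.b = intercept(sol, K, y, cfg)
    sol.objective = dual_objective(sol, K, y, cfg)
    return sol


def intercept(sol: SVRSolution, K: np.ndarray, y: np.ndarray, cfg: SVRConfig) -> float:
    """KKT-based intercept: average over free SVs, else interval midpoint."""
    alpha = sol.alpha
    Ka = K @ alpha
    eps, C = cfg.epsilon, cfg.C
    free_tol = max(1e-8, cfg.tol)
    free_plus = (sol.alpha_plus > free_tol) & (sol.alpha_plus < C - free_tol)
    free_minus = (sol.alpha_minus > free_tol) & (sol.alpha_minus < C - free_tol)
    vals = np.concatenate([
        y[free_plus] - eps - Ka[free_plus],
        y[free_minus] + eps - Ka[free_minus],
    ])
    if len(vals):
        return float(vals.mean())
    # no free SV: intersect the KKT inequality bounds on b
    lowers, uppers = [], []
    at_zero_p = sol.alpha_plus <= free_tol
    at_C_p = sol.alpha_plus >= C - free_tol
    at_zero_m = sol.alpha_minus <= free_tol
    at_C_m = sol.alpha_minus >= C - free_tol
    lowers.append((y - eps - Ka)[at_zero_p])   # residual ≤ ε
    uppers.append((y - eps - Ka)[at_C_p])      # residual ≥ ε
    uppers.append((y + eps - Ka)[at_zero_m])
    lowers.append((y + eps - Ka)[at_C_m])
    lo = max((v.max() for v in lowers if len(v)), default=-np.inf)
    hi = min((v.min() for v in uppers if len(v)), default=np.inf)
    if np.isinf(lo) and np.isinf(hi):
        return float(np.mean(y))
    if np.isinf(lo):
        return float(hi)
    if np.isinf(hi):
        return float(lo)
    return float(0.5 * (lo + hi))


def predict(sol: SVRSolution, K_cross: np.ndarray) -> np.ndarray:
    """ŷ_t = Σ_i α_i K_cross[t, i] + b for an M×N cross-kernel."""
    K_cross = np.atleast_2d(np.asarray(K_cross, dtype=float))
    if K_cross.shape[1] != len(sol.alpha_plus):
        raise ValueError(
            f"cross-kernel has {K_cross.shape[1]} columns but the model "
            f"was trained on {len(sol.alpha_plus)} samples"
        )
    return K_cross @ sol.alpha + sol.b


def dual_objective(sol: SVRSolution, K: np.ndarray, y: np.ndarray, cfg: SVRConfig) -> float:
    """Evaluate the dual objective at the solution's coefficients."""
    alpha = sol.alpha
    return float(
        -y @ alpha
        + cfg.epsilon * (sol.alpha_plus + sol.alpha_minus).sum()
        + 0.5 * alpha @ (np.asarray(K, dtype=float) @ alpha)
    )


def epsilon_from_multiplier(multiplier: float, y_train: np.ndarray) -> float:
    """Tube half-width ε = multiplier × std of the current training responses."""
    if multiplier < 0:
        raise ValueError("tube multiplier must be non-negative")
    y_train = np.asarray(y_train, dtype=float)
    return float(multiplier * np.std(y_train, ddof=1))
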