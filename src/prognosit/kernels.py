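"""Per-gene-set Gaussian kernels and their convex combination.

Each gene set defines a sub-matrix of the (standardized) expression matrix;
on that sub-matrix a Gaussian kernel

    k(x_i, x_j) = exp(−‖x_i − x_j‖² / (2σ²))

is built with the width heuristic σ = mean pairwise Euclidean distance
between training samples, computed per gene set.  Widths are estimated on
training data only and reused for test-vs-train cross-kernels.  No further
normalization is applied beyond the Gaussian's intrinsic unit diagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

from prognosit.geneset_io import FeaturePartition

logger = logging.getLogger(__name__)


def estimate_width(X_sub: np.ndarray) -> float:
    """Mean pairwise Euclidean distance over unordered training pairs.

    Raises ``ValueError`` when all samples coincide (σ = 0): callers
    should substitute a fallback width explicitly (see
    :func:`build_stack`).
    """
    X_sub = np.atleast_2d(np.asarray(X_sub, dtype=float))
    if X_sub.shape[0] < 2:
        raise ValueError("width heuristic needs at least 2 samples")
    sigma = float(pdist(X_sub, metric="euclidean").mean())
    if sigma == 0.0:
        raise ValueError(
            "all samples identical on this feature subset (sigma = 0); "
            "use a fallback width"
        )
    return sigma


def gaussian_kernel(X_a: np.ndarray, X_b: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian kernel matrix between the rows of ``X_a`` and ``X_b``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    X_a = np.atleast_2d(np.asarray(X_a, dtype=float))
    X_b = np.atleast_2d(np.asarray(X_b, dtype=float))
    if X_a.shape[1] != X_b.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {X_a.shape[1]} vs {X_b.shape[1]}"
        )
    sq = cdist(X_a, X_b, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * sigma**2))


@dataclass
class KernelStack:
    """P training kernels (one per gene set) plus what prediction needs.

    ``matrices[m]`` is the N×N training kernel of set ``names[m]`` built
    with width ``sigmas[m]`` on the columns ``indices[m]`` of the stored
    standardized training matrix.
    """

    names: list[str]
    matrices: list[np.ndarray]
    sigmas: list[float]
    indices: dict[str, list[int]] = field(repr=False)
    X_train: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.matrices) == len(self.sigmas)):
            raise ValueError("names, matrices and sigmas must align")
        if len(self.names) < 1:
            raise ValueError("a kernel stack needs at least one kernel")

    @property
    def P(self) -> int:
        return len(self.names)

    @property
    def n_train(self) -> int:
        return self.X_train.shape[0]

    def cross_matrices(self, X_new: np.ndarray) -> list[np.ndarray]:
        """M×N cross-kernels between new samples (rows) and training samples."""
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        out = []
        for name, sigma in zip(self.names, self.sigmas):
            ix = self.indices[name]
            out.append(gaussian_kernel(X_new[:, ix], self.X_train[:, ix], sigma))
        return out


def build_stack(
    X_train_std: np.ndarray,
    partition: FeaturePartition,
    zero_width_fallback: float = 1.0,
) -> KernelStack:
    """One Gaussian kernel per non-empty gene set, each with its own width.

    Sets matching zero expression features are dropped with a warning.
    Degenerate sub-matrices whose pairwise distances are all zero get the
    fallback width (their kernel is then the all-ones matrix, harmless in
    a convex combination).
    """
    X = np.asarray(X_train_std, dtype=float)
    part = partition.nonempty
    dropped = set(partition.set_names) - set(part.set_names)
    if dropped:
        logger.warning("dropping %d gene set(s) with no matched features: %s",
                       len(dropped), sorted(dropped))
    if not part.set_names:
        raise ValueError("no gene set matches any expression feature")
    names, mats, sigmas = [], [], []
    for name in part.set_names:
        sub = X[:, part.indices[name]]
        try:
            sigma = estimate_width(sub)
        except ValueError:
            logger.warning("sigma = 0 for set %r; using fallback width %.3g",
                           name, zero_width_fallback)
            sigma = zero_width_fallback
        names.append(name)
        sigmas.append(sigma)
        mats.append(gaussian_kernel(sub, sub, sigma))
    return KernelStack(
        names=names,
        matrices=mats,
        sigmas=sigmas,
        indices={n: list(part.indices[n]) for n in names},
        X_train=X,
    )


def combine(matrices: list[np.ndarray] | KernelStack, eta: np.ndarray) -> np.ndarray:
    """Weighted sum Σ_m η_m K_m for simplex weights η."""
    if isinstance(matrices, KernelStack):
        matrices = matrices.matrices
    eta = np.asarray(eta, dtype=float)
    if len(eta) != len(matrices):
        raise ValueError(
            f"{len(matrices)} kernels but {len(eta)} weights"
        )
    if np.any(eta < -1e-12):
        raise ValueError("kernel weights must be non-negative")
    if abs(eta.sum() - 1.0) > 1e-8:
        raise ValueError("kernel weights must sum to 1")
    K = np.zeros_like(matrices[0])
    for w, Km in zip(eta, matrices):
        if w != 0.0:
            K += w * Km
    return K
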