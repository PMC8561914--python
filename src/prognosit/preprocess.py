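"""Response transform, feature standardization and train/test splitting.

The response (tumour volume) is cube-root transformed — a volume is the
product of three linear dimensions, so its cube root lives back on a
linear scale.  Expression features are z-scored with statistics learned on
the training split only; test samples are transformed with those same
training statistics.  Responses are deliberately NOT standardized: the SVR
tube half-width is instead expressed as a multiplier of the training
responses' standard deviation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


def cube_root(volumes: np.ndarray | float) -> np.ndarray | float:
    """Elementwise cube root of strictly positive volumes.

    Raises ``ValueError`` on non-positive input: such samples should have
    been filtered out when volumes were computed.
    """
    v = np.asarray(volumes, dtype=float)
    if np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise ValueError("cube_root requires strictly positive finite volumes")
    out = np.cbrt(v)
    return float(out) if out.ndim == 0 else out


@dataclass
class Standardizer:
    """Per-feature z-scoring with statistics frozen on a training set.

    Standard deviation uses the sample (N−1) denominator.  Zero-variance
    training features are mapped to zero everywhere (their std is treated
    as 1): they carry no information and must not produce NaNs.
    """

    mean_: np.ndarray | None = None
    std_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a nonempty 2-D array")
        self.mean_ = X.mean(axis=0)
        std = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        std = np.where(std > 0, std, 1.0)
        self.std_ = std
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None or self.std_ is None:
            raise RuntimeError("Standardizer must be fitted before transform")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) / self.std_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    # -- persistence -------------------------------------------------
    def to_dict(self) -> dict:
        if self.mean_ is None or self.std_ is None:
            raise RuntimeError("cannot serialize an unfitted Standardizer")
        return {"mean": self.mean_.tolist(), "std": self.std_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        s = cls()
        s.mean_ = np.asarray(d["mean"], dtype=float)
        s.std_ = np.asarray(d["std"], dtype=float)
        return s

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "Standardizer":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class SplitPlan:
    """A reproducible 80/20 train/test partition of sample indices."""

    seed: int
    train: np.ndarray
    test: np.ndarray

    @property
    def n(self) -> int:
        return len(self.train) + len(self.test)


def make_split(n_samples: int, seed: int, train_fraction: float = 0.8) -> SplitPlan:
    """Uniformly random train/test partition with |train| = round(f·N).

    Deterministic under ``seed``.  Requires N ≥ 5 so both parts are
    nonempty at the default 80/20 split.
    """
    if n_samples < 5:
        raise ValueError("need at least 5 samples to form an 80/20 split")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    n_train = int(round(train_fraction * n_samples))
    n_train = min(max(n_train, 1), n_samples - 1)
    return SplitPlan(seed=seed, train=np.sort(perm[:n_train]), test=np.sort(perm[n_train:]))
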