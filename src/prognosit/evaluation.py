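"""Evaluation protocol: NRMSE, grid-search CV, replications, Wilcoxon analysis.

The experimental protocol mirrors the tumour-volume study design: per
replication, an 80/20 train/test split; features z-scored with training
statistics; hyperparameters (regularization C and tube-width multiplier)
chosen by 4-fold cross-validation on the training part, with kernel
widths and standardizers re-fit inside each fold; the winning pair refit
on the full training set and scored on the held-out test set by NRMSE,

    NRMSE = sqrt( Σ(y−ŷ)² / Σ(y−ȳ)² ),

so 1 marks the mean predictor and values below 1 indicate learning.
Across replications, pathway selection frequencies (how often a set's
kernel weight exceeded the threshold) and used-gene counts are
aggregated.  A paired Wilcoxon signed-rank test compares tumour vs
normal expression per gene for the genes the model retains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from prognosit.geneset_io import FeaturePartition
from prognosit.kernels import build_stack
from prognosit.mkl import MKLConfig, MKLModel
from prognosit.mkl import fit as mkl_fit
from prognosit.preprocess import Standardizer, make_split
from prognosit.svr import SVRConfig, epsilon_from_multiplier

logger = logging.getLogger(__name__)


def nrmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root of (prediction SS / total SS); requires non-constant ``y``."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("y and y_hat must be equal-length 1-D arrays (n >= 2)")
    denom = float(((y - y.mean()) ** 2).sum())
    if denom == 0.0:
        raise ValueError("NRMSE undefined for constant observed responses")
    return float(np.sqrt(((y - y_hat) ** 2).sum() / denom))


@dataclass(frozen=True)
class HyperGrid:
    """The hyperparameter grid searched by cross-validation.

    Defaults are the study grid: C over seven decades 10⁻³…10⁺³ and the
    tube-width multiplier over {0, 0.25, …, 2}, with 4 folds.
    """

    C_values: tuple[float, ...] = tuple(10.0**k for k in range(-3, 4))
    multipliers: tuple[float, ...] = tuple(0.25 * k for k in range(9))
    n_folds: int = 4

    def __post_init__(self) -> None:
        if not self.C_values or not self.multipliers:
            raise ValueError("grids must be nonempty")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass
class GridSearchResult:
    """Best (C, multiplier) plus the full fold-by-config NRMSE table."""

    best_C: float
    best_multiplier: float
    table: pd.DataFrame  # columns: C, multiplier, fold, nrmse

    @property
    def mean_table(self) -> pd.DataFrame:
        return (
            self.table.groupby(["C", "multiplier"], as_index=False)["nrmse"].mean()
        )


def _fit_on(
    X_train_raw: np.ndarray,
    y_train: np.ndarray,
    partition: FeaturePartition,
    C: float,
    multiplier: float,
    mkl_config: MKLConfig | None = None,
) -> tuple[MKLModel, Standardizer]:
    """Standardize, build kernels, and fit at one hyperparameter pair.

    The tube half-width is ``multiplier`` × std of the *current* training
    responses, so it is recomputed per fold and per replication.
    """
    std = Standardizer().fit(X_train_raw)
    stack = build_stack(std.transform(X_train_raw), partition)
    eps = epsilon_from_multiplier(multiplier, y_train)
    base = mkl_config.svr if mkl_config is not None else SVRConfig(C=1.0, epsilon=0.0)
    svr_cfg = SVRConfig(C=C, epsilon=eps, tol=base.tol, jitter=base.jitter, max_iter=base.max_iter)
    cfg = MKLConfig(
        svr=svr_cfg,
        max_iter=mkl_config.max_iter if mkl_config else 200,
        eta_tol=mkl_config.eta_tol if mkl_config else 1e-6,
        selection_threshold=mkl_config.selection_threshold if mkl_config else 0.01,
    )
    return mkl_fit(stack, y_train, cfg), std


def all_features_partition(n_features: int) -> FeaturePartition:
    """Single-set partition over every column: the plain-SVR baseline."""
    return FeaturePartition(["ALL_FEATURES"], {"ALL_FEATURES": list(range(n_features))})


def grid_search(
    X_train: np.ndarray,
    y_train: np.ndarray,
    partition: FeaturePartition,
    grid: HyperGrid = HyperGrid(),
    seed: int = 0,
    mkl_config: MKLConfig | None = None,
) -> GridSearchResult:
    """Pick (C, tube multiplier) by K-fold CV on the training set only.

    Folds are random but reproducible under ``seed``.  Kernel widths and
    the standardizer are re-fit inside each fold on that fold's training
    part.  Ties are broken toward the smallest C, then the smallest
    multiplier (the most regularized model).
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    kf = KFold(n_splits=grid.n_folds, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, va) in enumerate(kf.split(X_train)):
        X_tr, X_va = X_train[tr], X_train[va]
        y_tr, y_va = y_train[tr], y_train[va]
        # kernels depend only on the fold, not on (C, multiplier): build once
        std = Standardizer().fit(X_tr)
        stack = build_stack(std.transform(X_tr), partition)
        X_va_std = std.transform(X_va)
        for C in grid.C_values:
            for mult in grid.multipliers:
                eps = epsilon_from_multiplier(mult, y_tr)
                base = mkl_config.svr if mkl_config else SVRConfig(C=1.0, epsilon=0.0)
                cfg = MKLConfig(
                    svr=SVRConfig(C=C, epsilon=eps, tol=base.tol,
                                  jitter=base.jitter, max_iter=base.max_iter),
                    max_iter=mkl_config.max_iter if mkl_config else 200,
                    eta_tol=mkl_config.eta_tol if mkl_config else 1e-6,
                    selection_threshold=(
                        mkl_config.selection_threshold if mkl_config else 0.01
                    ),
                )
                model = mkl_fit(stack, y_tr, cfg)
                err = nrmse(y_va, model.predict(X_va_std))
                rows.append({"C": C, "multiplier": mult, "fold": fold, "nrmse": err})
    table = pd.DataFrame(rows)
    means = table.groupby(["C", "multiplier"])["nrmse"].mean()
    best_C, best_mult = _select_best(means)
    return GridSearchResult(best_C=best_C, best_multiplier=best_mult, table=table)


def _select_best(means: pd.Series) -> tuple[float, float]:
    """Minimizer of mean CV NRMSE over (C, multiplier) pairs.

    Ties are broken toward the smallest C, then the smallest multiplier
    (the most regularized model).
    """
    best_C, best_mult = None, None
    best = np.inf
    for C, mult in sorted(means.index):
        m = means.loc[(C, mult)]
        if m < best:
            best, best_C, best_mult = m, C, mult
    return best_C, best_mult


@dataclass
class ReplicationResult:
    """Outcome of one train/test replication."""

    replication: int
    seed: int
    C: float
    multiplier: float
    test_nrmse: float
    selected_sets: list[str]
    used_gene_count: int
    eta: dict[str, float] = field(default_factory=dict)
    error: str | None = None


def run_replications(
    X: np.ndarray,
    y: np.ndarray,
    partition: FeaturePartition,
    grid: HyperGrid = HyperGrid(),
    n_reps: int = 100,
    base_seed: int = 0,
    mkl_config: MKLConfig | None = None,
) -> list[ReplicationResult]:
    """The full replication protocol on (already cube-rooted) responses.

    Per replication r (seed = base_seed + r): 80/20 split, grid-search CV
    on the training part, refit on the full training set at the winning
    pair, and score on the test set.  A failing replication is recorded
    with its error message and the run continues.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    results: list[ReplicationResult] = []
    for r in range(n_reps):
        seed = base_seed + r
        try:
            plan = make_split(len(y), seed)
            X_tr, y_tr = X[plan.train], y[plan.train]
            gs = grid_search(X_tr, y_tr, partition, grid, seed=seed, mkl_config=mkl_config)
            model, std = _fit_on(X_tr, y_tr, partition, gs.best_C, gs.best_multiplier, mkl_config)
            y_hat = model.predict(std.transform(X[plan.test]))
            names, gene_count = model.selected_sets, model.used_gene_count
            results.append(
                ReplicationResult(
                    replication=r,
                    seed=seed,
                    C=gs.best_C,
                    multiplier=gs.best_multiplier,
                    test_nrmse=nrmse(y[plan.test], y_hat),
                    selected_sets=names,
                    used_gene_count=gene_count,
                    eta=dict(zip(model.set_names, model.eta.tolist())),
                )
            )
        except Exception as exc:  # record and continue: one bad split must not kill 100
            logger.exception("replication %d failed", r)
            results.append(
                ReplicationResult(
                    replication=r, seed=seed, C=np.nan, multiplier=np.nan,
                    test_nrmse=np.nan, selected_sets=[], used_gene_count=0,
                    error=f"{type(exc).__name__}: {exc}",
                )
            )
    return results


def selection_frequencies(results: list[ReplicationResult]) -> pd.DataFrame:
    """Per-set selection counts over replications, plus the mean per-rep count.

    Returns a DataFrame with columns ``set`` and ``frequency`` (number of
    replications in which the set's kernel weight exceeded the
    threshold); the mean number of selected sets per replication is
    stored in ``df.attrs["mean_selected"]``.
    """
    ok = [r for r in results if r.error is None]
    all_sets: list[str] = []
    for r in ok:
        for n in r.eta:
            if n not in all_sets:
                all_sets.append(n)
    counts = {n: 0 for n in all_sets}
    for r in ok:
        for n in r.selected_sets:
            counts[n] = counts.get(n, 0) + 1
    df = pd.DataFrame({"set": list(counts), "frequency": list(counts.values())})
    df.attrs["mean_selected"] = (
        float(np.mean([len(r.selected_sets) for r in ok])) if ok else float("nan")
    )
    return df


def paired_wilcoxon(
    tumour: pd.DataFrame,
    normal: pd.DataFrame,
    alpha: float = 0.05,
    exact_max_n: int = 25,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Two-sided Wilcoxon signed-rank test per gene on paired samples.

    Both frames are samples × genes with identical indices and columns
    (row i of each is the same patient).  Zero differences are dropped
    (Wilcoxon's original treatment); the exact null distribution is used
    for up to ``exact_max_n`` non-zero pairs, the normal approximation
    with continuity correction above.  Direction is the sign of the
    median paired difference.  ``bh_correct`` adds a
    Benjamini–Hochberg-adjusted column; the significance flag stays on
    the raw p-values either way.
    """
    if list(tumour.columns) != list(normal.columns):
        raise ValueError("tumour and normal matrices must share the same genes")
    if list(tumour.index) != list(normal.index):
        mism = sorted(set(tumour.index).symmetric_difference(normal.index))
        raise ValueError(f"sample pairing mismatch: {mism[:10]}")
    if len(tumour) < 4:
        raise ValueError("need at least 4 sample pairs for the signed-rank test")
    rows = []
    for gene in tumour.columns:
        d = tumour[gene].to_numpy(dtype=float) - normal[gene].to_numpy(dtype=float)
        nz = d[d != 0.0]
        med = float(np.median(d))
        if len(nz) == 0:
            rows.append({"gene": gene, "median_diff": med, "direction": "neutral",
                         "p_value": 1.0, "all_zero": True})
            continue
        method = "exact" if len(nz) <= exact_max_n else "approx"
        try:
            res = stats.wilcoxon(nz, alternative="two-sided", method=method,
                                 correction=(method == "approx"))
        except ValueError:
            res = stats.wilcoxon(nz, alternative="two-sided", method="approx",
                                 correction=True)
        direction = "up" if med > 0 else ("down" if med < 0 else "neutral")
        rows.append({"gene": gene, "median_diff": med, "direction": direction,
                     "p_value": float(res.pvalue), "all_zero": False})
    df = pd.DataFrame(rows)
    df["significant"] = df["p_value"] < alpha
    if bh_correct:
        df["p_adjusted"] = stats.false_discovery_control(df["p_value"], method="bh")
    return df


def paired_ttest(nrmse_a: np.ndarray, nrmse_b: np.ndarray) -> float:
    """Two-tailed paired t-test p-value across per-replication scores.

    Reporting utility for comparing two algorithms run on the same
    replication splits.
    """
    res = stats.ttest_rel(np.asarray(nrmse_a, float), np.asarray(nrmse_b, float))
    return float(res.pvalue)
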