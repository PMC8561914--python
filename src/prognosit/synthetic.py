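"""Synthetic cohorts with gene-set structure and a set-driven response.

The generator emulates the shape of a bulk expression study: a samples ×
genes matrix partitioned into gene sets, where a small number of sets
drive a nonlinear response that plays the role of tumour volume.

Expression model.  Genes within a set share an exchangeable correlation
(default 0.5) through a per-set latent factor; different sets are
independent; genes outside every set are i.i.d. standard normal.  This
mimics the strong within-pathway co-expression of real transcriptomes
while keeping set identity crisp.

Response model.  Each informative set contributes a Gaussian radial bump
exp(−‖x_S − c‖²/(2h²)) of its sub-profile around a random center — a
smooth nonlinear signal that a Gaussian kernel can represent, so success
of the kernel method reflects the method rather than a lucky functional
form.  The summed signal is standardized, noise added, shifted positive,
and cubed into "volumes" so that the pipeline's cube-root transform
recovers a well-scaled regression target.

A paired tumour/normal mode plants a per-gene mean shift on a chosen
gene subset for testing the differential-expression analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from prognosit.geneset_io import GeneSet, GeneSetCollection


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of a synthetic cohort.

    Defaults define the standard recovery benchmark: 150 samples, 600
    genes in 20 disjoint sets of 30, sets 0 and 1 informative, noise at
    half the (unit) signal standard deviation.
    """

    n_samples: int = 150
    n_genes: int = 600
    n_sets: int = 20
    set_size: int | None = None            # None -> n_genes // n_sets
    overlap_fraction: float = 0.0          # share of a set borrowed from its neighbour
    informative_sets: tuple[int, ...] = (0, 1)
    noise_sd: float = 0.5
    within_corr: float = 0.5
    volume_shift: float = 3.0              # positive offset before cubing
    seed: int = 0
    # paired tumour/normal mode
    n_pairs: int = 30
    paired_shift: tuple[float, ...] | None = None   # per-gene mean shift, length n_genes
    paired_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        size = self.resolved_set_size
        if size < 1 or size > self.n_genes:
            raise ValueError("set size must lie in [1, n_genes]")
        if self.n_sets * size > self.n_genes + self.n_sets * int(self.overlap_fraction * size):
            raise ValueError("gene sets do not fit into n_genes")
        if any(m < 0 or m >= self.n_sets for m in self.informative_sets):
            raise ValueError("informative set indices out of range")
        if self.noise_sd < 0 or not 0 <= self.overlap_fraction < 1:
            raise ValueError("noise_sd must be >= 0 and overlap_fraction in [0,1)")
        if not 0 <= self.within_corr < 1:
            raise ValueError("within_corr must lie in [0, 1)")
        if self.paired_shift is not None and len(self.paired_shift) != self.n_genes:
            raise ValueError("paired_shift must have one entry per gene")

    @property
    def resolved_set_size(self) -> int:
        return self.set_size if self.set_size is not None else self.n_genes // self.n_sets

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    def collection(self) -> GeneSetCollection:
        """The gene-set collection implied by the spec (GMT-compatible)."""
        names = self.gene_names()
        size = self.resolved_set_size
        n_overlap = int(self.overlap_fraction * size)
        sets = []
        for m in range(self.n_sets):
            own = list(range(m * size, (m + 1) * size))
            genes = [names[i] for i in own]
            if n_overlap and m > 0:
                prev = list(range((m - 1) * size, m * size))
                genes = [names[i] for i in prev[-n_overlap:]] + genes[: size - n_overlap]
            sets.append(
                GeneSet(name=f"SET{m + 1:02d}", description="synthetic", genes=tuple(genes))
            )
        return GeneSetCollection(tuple(sets))


def _draw_expression(spec: SyntheticSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    """Correlated-within-set Gaussian expression draw (n × n_genes)."""
    X = rng.standard_normal((n, spec.n_genes))
    rho = spec.within_corr
    if rho > 0:
        size = spec.resolved_set_size
        for m in range(spec.n_sets):
            cols = np.arange(m * size, (m + 1) * size)
            factor = rng.standard_normal((n, 1))
            X[:, cols] = np.sqrt(rho) * factor + np.sqrt(1 - rho) * X[:, cols]
    return X


def generate(spec: SyntheticSpec) -> tuple[pd.DataFrame, GeneSetCollection, pd.Series]:
    """Draw one cohort: expression matrix, gene sets, positive volumes."""
    rng = np.random.default_rng(spec.seed)
    collection = spec.collection()
    names = spec.gene_names()
    X = _draw_expression(spec, rng, spec.n_samples)
    expr = pd.DataFrame(
        X,
        index=[f"S{i + 1:04d}" for i in range(spec.n_samples)],
        columns=names,
    )
    col_of = {g: j for j, g in enumerate(names)}
    signal = np.zeros(spec.n_samples)
    for m in spec.informative_sets:
        gs = collection.sets[m]
        cols = [col_of[g] for g in gs.genes]
        sub = X[:, cols]
        # center drawn like a plausible sample of the same set
        rho = spec.within_corr
        center = np.sqrt(rho) * rng.standard_normal() + np.sqrt(1 - rho) * rng.standard_normal(len(cols))
        d2 = ((sub - center) ** 2).sum(axis=1)
        h = np.sqrt(d2.mean())
        signal += np.exp(-d2 / (2 * h**2))
    if spec.informative_sets and signal.std() > 0:
        signal = (signal - signal.mean()) / signal.std()
    target = signal + spec.noise_sd * rng.standard_normal(spec.n_samples)
    shifted = np.maximum(spec.volume_shift + target, 0.05)
    volumes = pd.Series(shifted**3, index=expr.index, name="volume")
    return expr, collection, volumes


def generate_paired(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired tumour/normal matrices with a planted per-gene shift.

    Normal tissue is a baseline draw from the expression model; tumour is
    the same baseline plus the per-gene shift plus independent noise, so
    the planted genes are the truly "regulated" ones and their direction
    equals the shift's sign.
    """
    if spec.paired_shift is None:
        raise ValueError("paired mode requires a paired_shift vector")
    rng = np.random.default_rng(spec.seed)
    names = spec.gene_names()
    index = [f"P{i + 1:04d}" for i in range(spec.n_pairs)]
    base = _draw_expression(spec, rng, spec.n_pairs)
    shift = np.asarray(spec.paired_shift, dtype=float)
    noise = spec.paired_noise_sd * rng.standard_normal(base.shape)
    normal = pd.DataFrame(base, index=index, columns=names)
    tumour = pd.DataFrame(base + shift + noise, index=index, columns=names)
    return tumour, normal
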