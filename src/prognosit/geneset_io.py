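"""Gene-set (GMT) and clinical-table input handling.

Gene-set collections such as MSigDB Hallmark or the Pathway Interaction
Database are distributed as GMT: one set per line, tab-separated, with the
set name, a description (possibly empty or a URL) and then the member gene
symbols.  Sets are mapped onto the columns of an expression matrix by exact,
case-sensitive symbol match; each matched set defines the feature sub-matrix
that one kernel is built on.

Tumour volumes are computed from the three linear dimensions recorded in
clinical annotation tables (length × width × depth); rows with a missing
dimension or a non-positive product are marked invalid and excluded from
modelling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


class GMTParseError(ValueError):
    """Raised when a GMT file violates the format (line number included)."""


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered list of unique gene symbols."""

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be nonempty")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered collection of gene sets with unique names."""

    sets: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("collection must contain at least one gene set")
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene set names: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass
class FeaturePartition:
    """Mapping of each gene set onto expression-matrix column indices.

    Overlap between sets is permitted; a gene appearing in two sets
    contributes its column to both sub-matrices.  Sets that match no
    column are retained here (flagged via ``empty_sets``) but must be
    dropped before kernel construction.
    """

    set_names: list[str]
    indices: dict[str, list[int]]
    matched_counts: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.matched_counts = {n: len(ix) for n, ix in self.indices.items()}

    @property
    def empty_sets(self) -> list[str]:
        return [n for n in self.set_names if self.matched_counts[n] == 0]

    @property
    def nonempty(self) -> "FeaturePartition":
        names = [n for n in self.set_names if self.matched_counts[n] > 0]
        return FeaturePartition(names, {n: self.indices[n] for n in names})

    def union_indices(self, names: Iterable[str] | None = None) -> list[int]:
        """Sorted union of matched column indices over the given sets."""
        if names is None:
            names = self.set_names
        out: set[int] = set()
        for n in names:
            out.update(self.indices[n])
        return sorted(out)

    @property
    def union_size(self) -> int:
        return len(self.union_indices())


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Each line must have at least three tab-separated fields: name,
    description, and one or more gene symbols.  Trailing empty fields
    (common in exports padded to equal width) are ignored.  Duplicate
    genes within a line are dropped with a warning, keeping first
    occurrence order.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            while fields and fields[-1] == "":
                fields.pop()
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated fields "
                    f"(name, description, genes), got {len(fields)}"
                )
            name, description, *genes = fields
            seen: dict[str, None] = {}
            dropped = 0
            for g in genes:
                if g in seen:
                    dropped += 1
                else:
                    seen[g] = None
            if dropped:
                logger.warning(
                    "%s:%d: set %r contains %d duplicate gene(s); deduplicated",
                    path.name,
                    lineno,
                    name,
                    dropped,
                )
            sets.append(GeneSet(name=name, description=description, genes=tuple(seen)))
    return GeneSetCollection(tuple(sets))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection back to GMT (inverse of :func:`read_gmt`)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def map_to_features(
    collection: GeneSetCollection, gene_ids: Sequence[str]
) -> FeaturePartition:
    """Map each gene set onto the column indices of an expression matrix.

    ``gene_ids`` are the matrix's column labels.  Matching is exact and
    case-sensitive.  Sets matching zero columns are flagged (they cannot
    form a kernel); overlapping sets share columns.
    """
    col_of = {g: i for i, g in enumerate(gene_ids)}
    if len(col_of) != len(gene_ids):
        raise ValueError("expression matrix has duplicate gene identifiers")
    indices: dict[str, list[int]] = {}
    for s in collection:
        indices[s.name] = [col_of[g] for g in s.genes if g in col_of]
        if not indices[s.name]:
            logger.warning(
                "gene set %r matches no expression feature; it will be "
                "dropped before kernel construction",
                s.name,
            )
    return FeaturePartition(collection.names, indices)


@dataclass(frozen=True)
class ClinicalVolume:
    """Per-sample tumour volume derived from three linear dimensions."""

    sample_id: str
    length: float
    width: float
    depth: float
    volume: float
    valid: bool


def compute_volumes(
    table: pd.DataFrame,
    length_col: str = "neoplasm_length",
    width_col: str = "neoplasm_width",
    depth_col: str = "neoplasm_depth",
) -> list[ClinicalVolume]:
    """Compute tumour volume = length · width · depth per clinical row.

    Rows with any missing dimension, or whose product is non-positive or
    non-finite, are marked invalid; downstream modelling uses only valid
    rows.  Invalidity is a data state, not an error.
    """
    out: list[ClinicalVolume] = []
    for sample_id, row in table.iterrows():
        dims = [row.get(c) for c in (length_col, width_col, depth_col)]
        vals: list[float] = []
        ok = True
        for d in dims:
            try:
                v = float(d)
            except (TypeError, ValueError):
                ok = False
                v = math.nan
            if math.isnan(v):
                ok = False
            vals.append(v)
        volume = vals[0] * vals[1] * vals[2] if ok else math.nan
        valid = ok and math.isfinite(volume) and volume > 0
        out.append(
            ClinicalVolume(
                sample_id=str(sample_id),
                length=vals[0],
                width=vals[1],
                depth=vals[2],
                volume=volume,
                valid=valid,
            )
        )
    return out


def volumes_to_series(volumes: Iterable[ClinicalVolume]) -> pd.Series:
    """Valid volumes as a Series indexed by sample id (invalid rows dropped)."""
    valid = [v for v in volumes if v.valid]
    return pd.Series(
        [v.volume for v in valid],
        index=[v.sample_id for v in valid],
        name="volume",
        dtype=float,
    )
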