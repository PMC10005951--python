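"""Structural connectome containers and graph metrics.

A structural connectome is a symmetric, non-negative region-by-region
matrix of streamline weights with a zero diagonal.  Group-level matrices
are element-wise means of per-subject matrices; hubs are regions in the
upper tail of degree centrality.  Zero connections are retained and
weights are not log-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, InvalidArgumentError, ShapeError

__all__ = [
    "ConnectivityMatrix",
    "CentralityMap",
    "group_connectome",
    "degree_centrality",
    "identify_hubs",
]

_SYM_TOL = 1e-9


@dataclass
class ConnectivityMatrix:
    """Symmetric non-negative region x region streamline-weight matrix."""

    weights: np.ndarray
    labels: tuple
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.labels = tuple(str(x) for x in self.labels)
        n = len(self.labels)
        if self.weights.shape != (n, n):
            raise ShapeError(
                f"weights must be square ({n}, {n}); got {self.weights.shape}"
            )
        if not np.all(np.isfinite(self.weights)):
            raise InvalidArgumentError("weights must be finite")
        if np.max(np.abs(self.weights - self.weights.T), initial=0.0) > _SYM_TOL:
            raise InvalidArgumentError("weights must be symmetric within 1e-9")
        if np.any(np.diagonal(self.weights) != 0.0):
            raise InvalidArgumentError("diagonal must be exactly zero")
        if np.any(self.weights < 0):
            raise InvalidArgumentError("weights must be non-negative")

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=list(self.labels), columns=list(self.labels))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, metadata: dict | None = None) -> "ConnectivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise AlignmentError("connectome TSV row and column labels differ")
        return cls(df.to_numpy(float), tuple(df.index.astype(str)), metadata or {})


@dataclass(frozen=True)
class CentralityMap:
    """Per-region degree centrality (weighted strength or binary degree)."""

    values: np.ndarray
    labels: tuple
    mode: str

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if self.values.shape != (len(self.labels),):
            raise ShapeError("one centrality value per region required")
        if np.any(self.values < 0):
            raise InvalidArgumentError("centrality values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"parcel_id": list(self.labels), "centrality": self.values})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def group_connectome(subject_matrices) -> ConnectivityMatrix:
    """Element-wise mean of per-subject connectomes (mean streamlines)."""
    matrices = list(subject_matrices)
    if not matrices:
        raise InvalidArgumentError("need at least one subject matrix")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise AlignmentError("subject matrices have mismatched region labels")
    mean = np.mean([m.weights for m in matrices], axis=0)
    # enforce exact symmetry/zero diagonal against accumulated rounding
    mean = 0.5 * (mean + mean.T)
    np.fill_diagonal(mean, 0.0)
    return ConnectivityMatrix(mean, labels, {"n_subjects": len(matrices)})


def degree_centrality(
    matrix: ConnectivityMatrix, mode: str = "weighted", binary_threshold: float = 0.0
) -> CentralityMap:
    """Degree centrality per region.

    ``weighted`` returns row sums of streamline weights (node strength);
    ``binary`` counts edges with weight strictly above ``binary_threshold``.
    """
    if mode == "weighted":
        values = matrix.weights.sum(axis=1)
    elif mode == "binary":
        values = (matrix.weights > binary_threshold).sum(axis=1).astype(float)
    else:
        raise InvalidArgumentError(f"unknown centrality mode: {mode!r}")
    return CentralityMap(values, matrix.labels, mode)


def identify_hubs(centrality: CentralityMap, top_fraction: float = 0.2) -> list:
    """Regions in the top ``top_fraction`` of centrality (ties at the cutoff included)."""
    if len(centrality.labels) == 0:
        raise InvalidArgumentError("empty centrality map")
    if not 0 < top_fraction <= 1:
        raise InvalidArgumentError("top_fraction must be in (0, 1]")
    cutoff = np.quantile(centrality.values, 1.0 - top_fraction)
    return [lab for lab, v in zip(centrality.labels, centrality.values) if v >= cutoff]
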