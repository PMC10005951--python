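"""Connectome predictive modeling (CPM).

Cross-validated prediction of a continuous target (here: polygenic risk)
from connectome edges, in four steps: per-fold feature selection (edges
whose training-set correlation with the target passes a p threshold,
split by sign), feature summarization (sum of selected edge weights per
network), linear model building (OLS of the target on the network
scores), and permutation-based prediction significance.

The model object follows the fit/results convention: build a
:class:`ConnectomePredictiveModel` from subject matrices and a target,
call :meth:`fit` to obtain a :class:`CPMResult` with out-of-fold
predictions, and call :meth:`permutation_significance` for the
permutation p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, LeaveOneOut

from .exceptions import (
    AlignmentError,
    DegenerateTargetError,
    InvalidArgumentError,
    ShapeError,
)
from .network import ConnectivityMatrix

__all__ = [
    "EdgeVector",
    "CPMConfig",
    "CPMResult",
    "vectorize_edges",
    "devectorize_edges",
    "edge_matrix",
    "select_edges",
    "summarize_features",
    "ConnectomePredictiveModel",
    "cpm_crossval",
    "permutation_significance",
    "top_predictors",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EdgeVector:
    """Strict upper triangle of a connectome in row-major order."""

    values: np.ndarray
    pairs: np.ndarray          # (E, 2) region indices, i < j
    labels: tuple              # region labels

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, float))
        object.__setattr__(self, "pairs", np.asarray(self.pairs, int))
        if self.values.shape[0] != self.pairs.shape[0]:
            raise ShapeError("values and pairs must have equal length")

    @property
    def pair_labels(self) -> list:
        return [(self.labels[i], self.labels[j]) for i, j in self.pairs]


def vectorize_edges(matrix: ConnectivityMatrix) -> EdgeVector:
    """Strict upper-triangle edge vector of a symmetric connectome."""
    n = matrix.n_regions
    iu = np.triu_indices(n, k=1)
    return EdgeVector(matrix.weights[iu], np.column_stack(iu), matrix.labels)


def devectorize_edges(edges: EdgeVector) -> ConnectivityMatrix:
    """Inverse of :func:`vectorize_edges` (exact round trip)."""
    n = len(edges.labels)
    w = np.zeros((n, n))
    w[edges.pairs[:, 0], edges.pairs[:, 1]] = edges.values
    w += w.T
    return ConnectivityMatrix(w, edges.labels)


def edge_matrix(subject_matrices) -> tuple:
    """Stack subject connectomes into a (subjects, edges) array.

    Returns ``(X, pairs, labels)`` with edge columns in the
    :func:`vectorize_edges` order.
    """
    matrices = list(subject_matrices)
    if not matrices:
        raise InvalidArgumentError("need at least one subject matrix")
    labels = matrices[0].labels
    n = matrices[0].n_regions
    iu = np.triu_indices(n, k=1)
    rows = []
    for m in matrices:
        if m.labels != labels:
            raise AlignmentError("subject matrices have mismatched region labels")
        rows.append(m.weights[iu])
    return np.asarray(rows), np.column_stack(iu), labels


@dataclass(frozen=True)
class CPMConfig:
    """Selection threshold, network mode, CV scheme and permutation count."""

    selection_p: float = 0.01
    network_mode: str = "combined"   # positive | negative | combined
    cv_scheme: str = "kfold"         # kfold | loo
    k: int = 10
    n_permutations: int = 1000
    consistency_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.selection_p < 1.0:
            raise InvalidArgumentError("selection_p must be in (0, 1)")
        if self.k < 2:
            raise InvalidArgumentError("k must be >= 2")
        if self.network_mode not in ("positive", "negative", "combined"):
            raise InvalidArgumentError(f"unknown network_mode {self.network_mode!r}")
        if self.cv_scheme not in ("kfold", "loo"):
            raise InvalidArgumentError(f"unknown cv_scheme {self.cv_scheme!r}")


def _edge_correlations(train_edges: np.ndarray, train_target: np.ndarray):
    """Pearson r and two-sided p of each edge column with the target.

    Constant edge columns get r = nan, p = 1 (never selected).
    """
    n = len(train_target)
    y = train_target - train_target.mean()
    ynorm = np.linalg.norm(y)
    x = train_edges - train_edges.mean(axis=0)
    xnorm = np.linalg.norm(x, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (x.T @ y) / (xnorm * ynorm)
        r = np.where(xnorm > 0, r, np.nan)
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 0.0))
    p = np.where(np.isnan(r), 1.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    return r, p


def select_edges(train_edges: np.ndarray, train_target: np.ndarray, selection_p: float = 0.01):
    """Sign-split edge selection by correlation with the training target.

    Returns ``(positive_mask, negative_mask)`` over edge columns:
    positive = {r > 0, p < selection_p}, negative = {r < 0, p < selection_p}.
    """
    train_edges = np.asarray(train_edges, float)
    train_target = np.asarray(train_target, float)
    if train_edges.shape[0] != train_target.shape[0]:
        raise ShapeError("edge rows must match target length")
    if train_edges.shape[0] < 10:
        raise InvalidArgumentError("need at least 10 training subjects")
    if train_target.std() == 0:
        raise DegenerateTargetError("training target is constant")
    r, p = _edge_correlations(train_edges, train_target)
    sig = p < selection_p
    return (sig & (r > 0)), (sig & (r < 0))


def summarize_features(edges: np.ndarray, masks) -> np.ndarray:
    """Network scores: sum of edge values inside each mask.

    ``edges`` is (E,) or (subjects, E); ``masks`` is the
    (positive, negative) pair from :func:`select_edges`.  Returns the
    scores stacked on the last axis (positive first).  An empty mask
    yields a zero score (the empty-model case; callers fall back to the
    training-mean prediction).
    """
    edges = np.asarray(edges, float)
    pos, neg = masks
    if edges.shape[-1] != len(pos) or len(pos) != len(neg):
        raise ShapeError("mask length must equal the number of edge columns")
    if not pos.any() and not neg.any():
        logger.warning("both selection masks are empty: empty-model fold")
    scores = np.stack([edges[..., pos].sum(axis=-1), edges[..., neg].sum(axis=-1)], axis=-1)
    return scores


@dataclass
class CPMResult:
    """Out-of-fold predictions and per-fold selection bookkeeping."""

    predicted: np.ndarray          # out-of-fold prediction per subject
    target: np.ndarray
    r_true_pred: float
    p_parametric: float            # parametric p for r_true_pred (t distribution)
    fold_pos_masks: np.ndarray     # (folds, E) bool
    fold_neg_masks: np.ndarray
    fold_train_r: np.ndarray       # (folds, E) training-set edge correlations
    fold_test_indices: list
    empty_folds: list
    pairs: np.ndarray
    labels: tuple
    config: CPMConfig
    p_perm: float | None = None
    null_r: np.ndarray | None = None

    @property
    def n_folds(self) -> int:
        return self.fold_pos_masks.shape[0]

    def top_predictors(self, consistency_fraction: float | None = None) -> pd.DataFrame:
        return top_predictors(self, consistency_fraction)

    def summary(self) -> str:
        lines = [
            f"CPM ({self.config.network_mode} network, {self.config.cv_scheme}"
            f"{'' if self.config.cv_scheme == 'loo' else f', k={self.config.k}'})",
            f"subjects: {len(self.target)}   edges: {self.fold_pos_masks.shape[1]}",
            f"r(true, predicted) = {self.r_true_pred:+.3f}   parametric p = {self.p_parametric:.3g}",
        ]
        if self.p_perm is not None:
            lines.append(
                f"permutation p = {self.p_perm:.4g} ({len(self.null_r)} permutations)"
            )
        sel = (self.fold_pos_masks | self.fold_neg_masks).sum(axis=1)
        lines.append(f"edges selected per fold: median {int(np.median(sel))}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        top = self.top_predictors()
        return {
            "r_true_pred": float(self.r_true_pred),
            "p_parametric": float(self.p_parametric),
            "p_perm": None if self.p_perm is None else float(self.p_perm),
            "n_subjects": int(len(self.target)),
            "n_folds": int(self.n_folds),
            "empty_folds": list(self.empty_folds),
            "fold_pos_edges": [np.flatnonzero(m).tolist() for m in self.fold_pos_masks],
            "fold_neg_edges": [np.flatnonzero(m).tolist() for m in self.fold_neg_masks],
            "top_predictors": top.to_dict(orient="records"),
        }


def _pearson_with_p(a: np.ndarray, b: np.ndarray):
    if a.std() == 0 or b.std() == 0:
        return 0.0, 1.0
    r = float(np.corrcoef(a, b)[0, 1])
    n = len(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / max(1.0 - r**2, 1e-300))
    return r, float(2.0 * stats.t.sf(abs(t), n - 2))


class ConnectomePredictiveModel:
    """CPM model object.

    Parameters
    ----------
    edges : numpy.ndarray, (subjects, E)
        Edge data in :func:`vectorize_edges` column order.
    target : array-like
        Continuous per-subject target (e.g. PRS).
    config : CPMConfig
    pairs, labels
        Edge index table and region labels (for predictor reporting).
    """

    def __init__(self, edges, target, config: CPMConfig | None = None, pairs=None, labels=None):
        self.edges = np.asarray(edges, float)
        self.target = np.asarray(target, float)
        if self.edges.shape[0] != self.target.shape[0]:
            raise AlignmentError("edge rows and target length differ")
        if self.edges.shape[0] < 30:
            raise InvalidArgumentError("CPM requires at least 30 subjects")
        if self.target.std() == 0:
            raise DegenerateTargetError("target is constant")
        self.config = config or CPMConfig()
        n_regions = int(round((1 + np.sqrt(1 + 8 * self.edges.shape[1])) / 2))
        if pairs is None:
            pairs = np.column_stack(np.triu_indices(n_regions, k=1))
        self.pairs = np.asarray(pairs, int)
        self.labels = tuple(labels) if labels is not None else tuple(
            f"r{i + 1}" for i in range(n_regions)
        )

    @classmethod
    def from_matrices(cls, subject_matrices, target, config: CPMConfig | None = None):
        X, pairs, labels = edge_matrix(subject_matrices)
        return cls(X, target, config, pairs, labels)

    def _folds(self):
        n = len(self.target)
        if self.config.cv_scheme == "loo":
            splitter = LeaveOneOut()
        else:
            splitter = KFold(n_splits=self.config.k, shuffle=True,
                             random_state=int(self.config.seed) % (2**32))
        return list(splitter.split(np.arange(n)))

    def _fit_target(self, target: np.ndarray, folds, collect: bool) -> tuple:
        """One full cross-validated pass for an arbitrary target vector."""
        cfg = self.config
        n, E = self.edges.shape
        predicted = np.empty(n)
        pos_masks, neg_masks, train_rs, test_sets, empty = [], [], [], [], []
        for fold_idx, (train, test) in enumerate(folds):
            if np.intersect1d(train, test).size:
                raise RuntimeError("leakage: a test subject appears in its training fold")
            Xtr, ytr = self.edges[train], target[train]
            pos, neg = select_edges(Xtr, ytr, cfg.selection_p)
            if cfg.network_mode == "positive":
                neg = np.zeros_like(neg)
            elif cfg.network_mode == "negative":
                pos = np.zeros_like(pos)

            use = [m for m in (pos, neg) if m.any()]
            if not use:
                predicted[test] = ytr.mean()
                empty.append(fold_idx)
            else:
                str_tr = np.column_stack([Xtr[:, m].sum(axis=1) for m in use])
                str_te = np.column_stack([self.edges[test][:, m].sum(axis=1) for m in use])
                A = np.column_stack([np.ones(len(train)), str_tr])
                coef, _, _, _ = np.linalg.lstsq(A, ytr, rcond=None)
                predicted[test] = np.column_stack([np.ones(len(test)), str_te]) @ coef
            if collect:
                pos_masks.append(pos)
                neg_masks.append(neg)
                r, _ = _edge_correlations(Xtr, ytr)
                train_rs.append(r)
                test_sets.append(test)
        return predicted, pos_masks, neg_masks, train_rs, test_sets, empty

    def fit(self) -> CPMResult:
        folds = self._folds()
        predicted, pos, neg, train_r, tests, empty = self._fit_target(
            self.target, folds, collect=True
        )
        r, p_par = _pearson_with_p(self.target, predicted)
        return CPMResult(
            predicted=predicted,
            target=self.target.copy(),
            r_true_pred=r,
            p_parametric=p_par,
            fold_pos_masks=np.asarray(pos),
            fold_neg_masks=np.asarray(neg),
            fold_train_r=np.asarray(train_r),
            fold_test_indices=tests,
            empty_folds=empty,
            pairs=self.pairs,
            labels=self.labels,
            config=self.config,
        )

    def permutation_significance(self, result: CPMResult | None = None,
                                 n_permutations: int | None = None) -> CPMResult:
        """Permute the target, rerun the full CV pipeline, and attach
        ``p_perm = (1 + #{null r >= observed}) / (1 + n_permutations)``."""
        if result is None:
            result = self.fit()
        n_perm = n_permutations or self.config.n_permutations
        rng = np.random.default_rng(np.random.SeedSequence([int(self.config.seed), 1]))
        folds = self._folds()
        null_r = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(self.target)
            pred, *_ = self._fit_target(perm, folds, collect=False)
            null_r[i], _ = _pearson_with_p(perm, pred)
        result.null_r = null_r
        result.p_perm = (1.0 + float(np.sum(null_r >= result.r_true_pred))) / (1.0 + n_perm)
        return result


def cpm_crossval(subject_matrices, target, config: CPMConfig | None = None) -> CPMResult:
    """Functional entry point: cross-validated CPM from subject matrices."""
    return ConnectomePredictiveModel.from_matrices(subject_matrices, target, config).fit()


def permutation_significance(subject_matrices, target, config: CPMConfig | None = None,
                             observed_result: CPMResult | None = None) -> CPMResult:
    """Functional entry point for the permutation test."""
    model = ConnectomePredictiveModel.from_matrices(subject_matrices, target, config)
    return model.permutation_significance(observed_result)


def top_predictors(result: CPMResult, consistency_fraction: float | None = None) -> pd.DataFrame:
    """Edges selected (either sign) in >= consistency_fraction of folds.

    Returns a DataFrame ``region_a, region_b, n_folds, mean_abs_r`` sorted
    by the mean absolute training correlation, descending.
    """
    frac = result.config.consistency_fraction if consistency_fraction is None else consistency_fraction
    if not 0.0 <= frac <= 1.0:
        raise InvalidArgumentError("consistency_fraction must be in [0, 1]")
    selected = result.fold_pos_masks | result.fold_neg_masks
    counts = selected.sum(axis=0)
    need = max(frac * result.n_folds, 1e-12)  # fraction 0 -> any selection counts
    keep = np.flatnonzero((counts >= need) & (counts > 0))
    with np.errstate(invalid="ignore"):
        mean_abs = np.nanmean(np.abs(result.fold_train_r[:, keep]), axis=0) if len(keep) else np.array([])
    rows = [
        {
            "region_a": result.labels[result.pairs[e, 0]],
            "region_b": result.labels[result.pairs[e, 1]],
            "n_folds": int(counts[e]),
            "mean_abs_r": float(m),
        }
        for e, m in zip(keep, mean_abs)
    ]
    df = pd.DataFrame(rows, columns=["region_a", "region_b", "n_folds", "mean_abs_r"])
    return df.sort_values("mean_abs_r", ascending=False, ignore_index=True) if len(df) else df
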