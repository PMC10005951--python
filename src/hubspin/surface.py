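"""Parcellated spherical cortical surface model.

Cortical parcels are represented by labeled centroids on the unit sphere,
one set per hemisphere, with the right hemisphere the mirror image of the
left (the first coordinate is negated).  This is the substrate for the
spin permutation test: a map defined on the parcels can be rotated on the
sphere and resampled back onto the parcels.

Spatially autocorrelated per-parcel fields are drawn from a Gaussian
process with a squared-exponential kernel in geodesic (arc-length)
distance, emulating the smoothness that surface-based smoothing imposes
on real cortical thickness maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError, ShapeError

__all__ = [
    "SphereParcellation",
    "build_parcellation",
    "geodesic_distance",
    "geodesic_distance_matrix",
    "smooth_field",
]

_UNIT_TOL = 1e-9
_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0


@dataclass(frozen=True)
class SphereParcellation:
    """Labeled parcel centroids on the unit sphere.

    Parameters
    ----------
    parcel_id : tuple of str
        Unique parcel labels, left hemisphere first.
    hemisphere : numpy.ndarray of str
        ``"left"`` or ``"right"`` per parcel.  Left-hemisphere centroids
        have negative first coordinate, right-hemisphere positive.
    centroids : numpy.ndarray, shape (n, 3)
        Unit-norm centroid per parcel.
    """

    parcel_id: tuple
    hemisphere: np.ndarray
    centroids: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "parcel_id", tuple(str(p) for p in self.parcel_id))
        object.__setattr__(self, "hemisphere", np.asarray(self.hemisphere, dtype=object))
        object.__setattr__(self, "centroids", np.asarray(self.centroids, dtype=float))
        n = len(self.parcel_id)
        if len(set(self.parcel_id)) != n:
            raise InvalidArgumentError("parcel_ids must be unique")
        if self.centroids.shape != (n, 3):
            raise ShapeError(f"centroids must be ({n}, 3), got {self.centroids.shape}")
        if self.hemisphere.shape != (n,):
            raise ShapeError("hemisphere labels must be one per parcel")
        bad = set(self.hemisphere) - {"left", "right"}
        if bad:
            raise InvalidArgumentError(f"unknown hemisphere labels: {sorted(bad)}")
        norms = np.linalg.norm(self.centroids, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise InvalidArgumentError("all centroids must have unit norm (tol 1e-9)")
        for hemi in ("left", "right"):
            if np.sum(self.hemisphere == hemi) < 2:
                raise InvalidArgumentError(f"need at least 2 parcels in {hemi} hemisphere")
        x = self.centroids[:, 0]
        left = self.hemisphere == "left"
        if np.any(x[left] >= 0) or np.any(x[~left] <= 0):
            raise InvalidArgumentError(
                "mirror convention violated: left parcels need x < 0, right x > 0"
            )

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_id)

    @property
    def left_mask(self) -> np.ndarray:
        return self.hemisphere == "left"

    @property
    def right_mask(self) -> np.ndarray:
        return self.hemisphere == "right"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parcel_id": list(self.parcel_id),
                "hemisphere": list(self.hemisphere),
                "x": self.centroids[:, 0],
                "y": self.centroids[:, 1],
                "z": self.centroids[:, 2],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SphereParcellation":
        df = pd.read_csv(path)
        required = {"parcel_id", "hemisphere", "x", "y", "z"}
        missing = required - set(df.columns)
        if missing:
            raise InvalidArgumentError(f"parcellation CSV missing columns: {sorted(missing)}")
        return cls(
            parcel_id=tuple(df["parcel_id"].astype(str)),
            hemisphere=df["hemisphere"].to_numpy(),
            centroids=df[["x", "y", "z"]].to_numpy(float),
        )


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Low-discrepancy lattice of n points on the open hemisphere x < 0."""
    i = np.arange(n)
    u = (i + 0.5) / n                      # cos of angle from the -x axis, in (0, 1)
    phi = 2.0 * np.pi * i / _GOLDEN
    s = np.sqrt(1.0 - u**2)
    return np.column_stack([-u, s * np.cos(phi), s * np.sin(phi)])


def build_parcellation(n_per_hemisphere: int) -> SphereParcellation:
    """Construct a bilateral parcellation of 2*n_per_hemisphere parcels.

    Left-hemisphere centroids are placed by a deterministic Fibonacci
    lattice on the hemisphere x < 0; the right hemisphere is its exact
    mirror image.  Ordering is all left parcels, then all right parcels.
    """
    if not isinstance(n_per_hemisphere, (int, np.integer)) or isinstance(n_per_hemisphere, bool):
        raise InvalidArgumentError("n_per_hemisphere must be an integer")
    if n_per_hemisphere < 2:
        raise InvalidArgumentError("n_per_hemisphere must be >= 2")
    left = _fibonacci_hemisphere(int(n_per_hemisphere))
    right = left * np.array([-1.0, 1.0, 1.0])
    # Renormalize defensively against accumulated rounding.
    left /= np.linalg.norm(left, axis=1, keepdims=True)
    right /= np.linalg.norm(right, axis=1, keepdims=True)
    width = len(str(n_per_hemisphere))
    ids = [f"L{i + 1:0{width}d}" for i in range(n_per_hemisphere)] + [
        f"R{i + 1:0{width}d}" for i in range(n_per_hemisphere)
    ]
    hemis = np.array(["left"] * n_per_hemisphere + ["right"] * n_per_hemisphere, dtype=object)
    return SphereParcellation(tuple(ids), hemis, np.vstack([left, right]))


def _check_unit(v: np.ndarray, name: str, tol: float = 1e-6) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != 3:
        raise ShapeError(f"{name} must be a 3-vector")
    if np.any(np.abs(np.linalg.norm(v, axis=-1) - 1.0) > tol):
        raise InvalidArgumentError(f"{name} must have unit norm (tol {tol})")
    return v


def geodesic_distance(a, b) -> float:
    """Arc-length (angular) distance between two unit vectors, in [0, pi]."""
    a = _check_unit(a, "a")
    b = _check_unit(b, "b")
    return float(np.arccos(np.clip(np.dot(a, b), -1.0, 1.0)))


def geodesic_distance_matrix(points: np.ndarray) -> np.ndarray:
    """Pairwise geodesic distances between rows of unit-norm ``points``."""
    points = _check_unit(points, "points")
    return np.arccos(np.clip(points @ points.T, -1.0, 1.0))


def smooth_field(
    parcellation: SphereParcellation,
    lengthscale: float,
    variance: float = 1.0,
    seed=None,
    size: int | None = None,
) -> np.ndarray:
    """Draw zero-mean Gaussian random field(s) over the parcels.

    The covariance between parcels a and b is
    ``variance * exp(-d(a, b)**2 / (2 * lengthscale**2))`` with d the
    geodesic distance; a small jitter is added to the diagonal for
    numerical positive definiteness.

    Parameters
    ----------
    lengthscale : float
        Kernel lengthscale in radians (> 0).
    variance : float
        Marginal field variance (> 0).
    seed : int, numpy.random.Generator or None
        Seed for the draw.
    size : int, optional
        If given, return ``size`` independent draws, shape (size, n);
        otherwise a single (n,) draw.

    Returns
    -------
    numpy.ndarray
    """
    if lengthscale <= 0:
        raise InvalidArgumentError("lengthscale must be positive")
    if variance <= 0:
        raise InvalidArgumentError("variance must be positive")
    rng = np.random.default_rng(seed)
    chol = _field_cholesky(parcellation, lengthscale, variance)
    n = parcellation.n_parcels
    if size is None:
        return chol @ rng.standard_normal(n)
    return rng.standard_normal((int(size), n)) @ chol.T


def _field_cholesky(
    parcellation: SphereParcellation, lengthscale: float, variance: float
) -> np.ndarray:
    d = geodesic_distance_matrix(parcellation.centroids)
    cov = variance * np.exp(-(d**2) / (2.0 * lengthscale**2))
    jitter = 1e-8 * variance
    for _ in range(8):
        try:
            return np.linalg.cholesky(cov + jitter * np.eye(len(cov)))
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise np.linalg.LinAlgError("field covariance is not positive definite")
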