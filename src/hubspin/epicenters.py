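"""Disease-epicenter mapping.

A disease epicenter is a region whose normative structural-connectivity
profile spatially mirrors the disorder's cortical-alteration map: for
each seed region the Pearson correlation between its connectome row
(seed's own entry removed) and the alteration map over the remaining
regions is computed, and significance is assessed with spin permutation
tests (the alteration map is rotated; the seed's slot is removed after
resampling).  Regions with significant one-tailed correlations form the
epicenter set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, DegenerateMapError, ShapeError
from .network import ConnectivityMatrix
from .spin import _batch_assignments, _random_rotations
from .surface import SphereParcellation

__all__ = ["EpicenterResult", "epicenter_scan", "overlap_with_predictors"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EpicenterResult:
    """Per-region epicenter correlations, spin p-values and the significant set."""

    parcel_id: tuple
    r_epi: np.ndarray
    p_spin: np.ndarray
    alpha: float
    n_rotations: int
    seed: object

    @property
    def significant(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(np.isnan(self.p_spin), False, self.p_spin < self.alpha)

    @property
    def significant_regions(self) -> list:
        return [lab for lab, s in zip(self.parcel_id, self.significant) if s]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parcel_id": list(self.parcel_id),
                "r_epi": self.r_epi,
                "p_spin": self.p_spin,
                "significant": self.significant,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_dict(self) -> dict:
        return {
            "alpha": float(self.alpha),
            "n_rotations": int(self.n_rotations),
            "significant_regions": self.significant_regions,
            "r_epi": {lab: (None if np.isnan(r) else float(r))
                      for lab, r in zip(self.parcel_id, self.r_epi)},
            "p_spin": {lab: (None if np.isnan(p) else float(p))
                       for lab, p in zip(self.parcel_id, self.p_spin)},
        }


def _corr_excluding(profile: np.ndarray, maps: np.ndarray, drop: int) -> np.ndarray:
    """Pearson r of ``profile`` (minus index ``drop``) with each row of
    ``maps`` (same index dropped)."""
    keep = np.ones(len(profile), dtype=bool)
    keep[drop] = False
    x = profile[keep]
    x = x - x.mean()
    xn = np.linalg.norm(x)
    M = maps[:, keep]
    M = M - M.mean(axis=1, keepdims=True)
    mn = np.linalg.norm(M, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (M @ x) / (mn * xn)
    return np.where(mn > 0, r, 0.0)


def epicenter_scan(
    connectome: ConnectivityMatrix,
    alteration_map,
    parcellation: SphereParcellation,
    n_rotations: int = 1000,
    alpha: float = 0.05,
    seed=None,
    shared_null: bool = True,
    fdr: bool = False,
) -> EpicenterResult:
    """Scan all regions for epicenter status against an alteration map.

    With ``shared_null=True`` (default) one set of rotated alteration
    maps is reused across all seed regions; with ``shared_null=False``
    each region gets its own independent rotation set.  ``fdr`` applies a
    Benjamini-Hochberg correction to the spin p-values before
    thresholding at ``alpha``.
    """
    amap = np.asarray(alteration_map, float)
    n = parcellation.n_parcels
    if connectome.n_regions != n or amap.shape != (n,):
        raise ShapeError("connectome, map and parcellation dimensions must agree")
    if connectome.labels != parcellation.parcel_id:
        raise AlignmentError("connectome labels do not match the parcellation")
    if amap.std() == 0:
        raise DegenerateMapError("alteration map is constant")

    rng = np.random.default_rng(seed)
    if shared_null:
        rotations = _random_rotations(n_rotations, rng)
        shared_maps = amap[_batch_assignments(parcellation, rotations)]

    r_epi = np.full(n, np.nan)
    p_spin = np.full(n, np.nan)
    for s in range(n):
        profile = connectome.weights[s]
        keep = np.ones(n, dtype=bool)
        keep[s] = False
        if profile[keep].std() == 0:
            logger.warning("region %s has a constant connectivity profile; excluded",
                           parcellation.parcel_id[s])
            continue
        if shared_null:
            null_maps = shared_maps
        else:
            rots = _random_rotations(n_rotations, rng)
            null_maps = amap[_batch_assignments(parcellation, rots)]
        r_obs = _corr_excluding(profile, amap[None], s)[0]
        null_r = _corr_excluding(profile, null_maps, s)
        r_epi[s] = r_obs
        p_spin[s] = (1.0 + np.sum(null_r >= r_obs)) / (1.0 + n_rotations)

    if fdr:
        valid = ~np.isnan(p_spin)
        from scipy.stats import false_discovery_control

        adj = p_spin.copy()
        adj[valid] = false_discovery_control(p_spin[valid])
        p_spin = adj
    return EpicenterResult(parcellation.parcel_id, r_epi, p_spin, alpha, n_rotations, seed)


def overlap_with_predictors(epicenters: EpicenterResult, predictor_edges) -> list:
    """Significant epicenter regions incident to a top-predictor edge.

    ``predictor_edges`` is a DataFrame with ``region_a``/``region_b``
    columns (as returned by CPM top-predictor extraction) or an iterable
    of region-label pairs.
    """
    if isinstance(predictor_edges, pd.DataFrame):
        pairs = list(zip(predictor_edges["region_a"], predictor_edges["region_b"]))
    else:
        pairs = [tuple(e) for e in predictor_edges]
    endpoints = {str(r) for pair in pairs for r in pair}
    known = set(epicenters.parcel_id)
    unknown = endpoints - known
    if unknown:
        raise AlignmentError(f"predictor edge regions not in the parcellation: {sorted(unknown)}")
    return [r for r in epicenters.significant_regions if r in endpoints]
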