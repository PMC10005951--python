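"""Synthetic cohort generator.

Generates the three data objects the analysis consumes — a subject
phenotype table, a subjects x parcels cortical-thickness matrix, and
per-subject structural connectomes — with the statistical structure the
downstream analyses assume:

* a hub-structured template connectome whose edge probability decays with
  geodesic distance and whose designated hub regions carry elevated
  connection probability and weight;
* per-subject connectomes equal to the template plus symmetric Gaussian
  edge deviations truncated at zero;
* a polygenic risk score (PRS) built from the deviations of a sparse set
  of planted edges plus Gaussian noise, then standardized — so the
  edge-level signal that connectome-based prediction should recover is
  known exactly;
* thickness maps with group, age and PRS effects whose amplitude is
  (partly) proportional to normalized node centrality, plus spatially
  autocorrelated noise.

All randomness flows from ``CohortConfig.seed`` through fixed substreams,
so identical configs give bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    DegeneratePRSError,
    InvalidArgumentError,
    ShapeError,
)
from .network import CentralityMap, ConnectivityMatrix, degree_centrality
from .surface import SphereParcellation, _field_cholesky, geodesic_distance_matrix

__all__ = [
    "CohortConfig",
    "SubjectConnectomes",
    "CohortData",
    "generate_template_connectome",
    "generate_subject_connectomes",
    "generate_phenotypes",
    "generate_thickness",
    "simulate_cohort",
    "write_cohort",
]

# substream indices off the master cohort seed
_STREAM_TEMPLATE = 0
_STREAM_EDGES = 1
_STREAM_PHENO = 2
_STREAM_THICK = 3

# template-connectome shape constants (weights are streamline-count scale)
_EDGE_WEIGHT_SHAPE = 2.0     # gamma shape of base edge weights
_EDGE_WEIGHT_SCALE = 5.0     # gamma scale -> mean base weight 10 streamlines
_HUB_WEIGHT_FACTOR = 2.5     # weight multiplier per hub endpoint
_HUB_PROB_SHRINK = 0.35      # distance-exponent shrink per hub endpoint


def _stream(seed: int, index: int) -> np.random.Generator:
    """Deterministic child generator ``index`` of a master seed."""
    child = np.random.SeedSequence(seed).spawn(index + 1)[index]
    return np.random.default_rng(child)


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration.

    Effect sizes are in mm of cortical thickness; ``hub_coupling`` is the
    fraction of the group/PRS effect amplitude that scales with normalized
    centrality (0 = spatially uniform effect, 1 = effect proportional to
    centrality).  ``planted_edges``/``planted_weights`` define the PRS
    signal; when left as None the six strongest template edges with
    weights (+1, +1, +1, -1, -1, -1) are used, and ``prs_noise_sd`` (when
    None) is set equal to the planted-signal standard deviation so the
    planted edges explain half of the PRS variance.

    Planted edges are drawn with ``planted_edge_sd_multiplier`` times the
    background between-subject edge sd: edges that carry an association
    with a trait must vary more between individuals than background
    edges, and the multiplier keeps each planted edge individually
    detectable against the false-selection noise of the edge screen (see
    the methods note for the dilution arithmetic behind the default).
    """

    n_subjects: int = 560
    proportion_case: float = 266 / 560
    age_range: tuple = (6.0, 35.0)
    n_sites: int = 5
    sex_ratio: float = 0.5          # fraction male
    n_pcs: int = 10
    group_effect: float = 0.1       # mm, ASD - CTL
    prs_effect: float = 0.05        # mm per PRS standard deviation
    hub_coupling: float = 0.8
    age_slope: float = -0.02        # mm / year
    interaction_coupling: float = 0.8
    noise_sd: float = 0.1           # mm
    noise_lengthscale: float = 0.5  # radians
    site_offset_sd: float = 0.05    # mm
    baseline: float = 2.5           # mm
    template_density: float = 0.35
    hub_set_size: int = 12
    subject_edge_sd: float = 2.0    # streamline units (background edges)
    planted_edge_sd_multiplier: float = 4.0
    planted_edges: tuple | None = None
    planted_weights: tuple | None = None
    prs_noise_sd: float | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("proportion_case", "sex_ratio", "hub_coupling",
                     "interaction_coupling", "template_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidArgumentError(f"{name} must be in [0, 1], got {v}")
        for name in ("noise_sd", "site_offset_sd", "subject_edge_sd"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be non-negative")
        if self.prs_noise_sd is not None and self.prs_noise_sd < 0:
            raise InvalidArgumentError("prs_noise_sd must be non-negative")
        if self.planted_edge_sd_multiplier <= 0:
            raise InvalidArgumentError("planted_edge_sd_multiplier must be positive")
        if self.n_subjects < 1:
            raise InvalidArgumentError("n_subjects must be positive")
        if self.noise_lengthscale <= 0:
            raise InvalidArgumentError("noise_lengthscale must be positive")
        if self.age_range[0] >= self.age_range[1]:
            raise InvalidArgumentError("age_range must be (lo, hi) with lo < hi")
        if self.planted_edges is not None:
            edges = [tuple(e) for e in self.planted_edges]
            if any(a == b for a, b in edges):
                raise InvalidArgumentError("planted edges must be off-diagonal")
            norm = {tuple(sorted(e)) for e in edges}
            if len(norm) != len(edges):
                raise InvalidArgumentError("planted edges must be distinct")
            object.__setattr__(self, "planted_edges", tuple(edges))
            if self.planted_weights is not None:
                if len(self.planted_weights) != len(edges):
                    raise InvalidArgumentError(
                        "planted_weights must match planted_edges in length"
                    )
                object.__setattr__(self, "planted_weights", tuple(float(w) for w in self.planted_weights))

    @classmethod
    def abide_like(cls, **overrides) -> "CohortConfig":
        """Clinical-cohort preset: 560 males, 266 cases / 294 controls."""
        base = dict(n_subjects=560, proportion_case=266 / 560, sex_ratio=1.0,
                    age_range=(6.0, 35.0), n_sites=5)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def ping_like(cls, **overrides) -> "CohortConfig":
        """General-population preset: 391 children, mixed sex, 20 genetic
        PCs, 13 scanner sites, no cases."""
        base = dict(n_subjects=391, proportion_case=0.0, sex_ratio=207 / 391,
                    age_range=(3.0, 21.0), n_sites=13, n_pcs=20)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def null(cls, **overrides) -> "CohortConfig":
        """All planted effects zero (type-I calibration conditions)."""
        base = dict(group_effect=0.0, prs_effect=0.0, age_slope=0.0,
                    hub_coupling=0.0, interaction_coupling=0.0)
        base.update(overrides)
        return cls(**base)


@dataclass
class SubjectConnectomes:
    """Per-subject connectomes plus the pre-truncation edge deviations.

    ``deviations`` has one row per subject and one column per strict
    upper-triangle edge in row-major (``numpy.triu_indices``) order —
    the same ordering used by :func:`hubspin.cpm.vectorize_edges`.
    ``edge_sd`` records the per-edge deviation sd actually used
    (background sd, multiplied up at planted edges).
    """

    matrices: list
    deviations: np.ndarray
    pairs: np.ndarray
    labels: tuple
    edge_sd: np.ndarray | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.matrices)


def generate_template_connectome(
    parcellation: SphereParcellation, config: CohortConfig
) -> ConnectivityMatrix:
    """Hub-structured template (expected streamline counts).

    Edge existence probability decays with geodesic distance and is
    boosted for edges incident to the designated hub set; edge weights
    are gamma-distributed with a multiplicative boost per hub endpoint.
    """
    if not 0.0 < config.template_density <= 1.0:
        raise InvalidArgumentError("template_density must be in (0, 1]")
    n = parcellation.n_parcels
    if config.hub_set_size >= n:
        raise InvalidArgumentError("hub_set_size must be smaller than the parcel count")
    rng = _stream(config.seed, _STREAM_TEMPLATE)
    hubs = np.sort(rng.choice(n, size=config.hub_set_size, replace=False))
    is_hub = np.zeros(n, dtype=bool)
    is_hub[hubs] = True

    d = geodesic_distance_matrix(parcellation.centroids)
    off = ~np.eye(n, dtype=bool)
    d_mean = d[off].mean()
    n_hub_end = is_hub[:, None].astype(int) + is_hub[None, :].astype(int)
    exponent = (d / d_mean) * (_HUB_PROB_SHRINK ** n_hub_end)
    p_exist = config.template_density ** exponent

    iu = np.triu_indices(n, k=1)
    exist = rng.random(len(iu[0])) < p_exist[iu]
    base_w = rng.gamma(_EDGE_WEIGHT_SHAPE, _EDGE_WEIGHT_SCALE, size=len(iu[0]))
    w = base_w * (_HUB_WEIGHT_FACTOR ** n_hub_end[iu]) * exist

    weights = np.zeros((n, n))
    weights[iu] = w
    weights += weights.T
    return ConnectivityMatrix(
        weights,
        parcellation.parcel_id,
        metadata={
            "hub_indices": [int(h) for h in hubs],
            "hubs": [parcellation.parcel_id[h] for h in hubs],
        },
    )


def generate_subject_connectomes(
    template: ConnectivityMatrix, config: CohortConfig
) -> SubjectConnectomes:
    """Template plus symmetric Gaussian edge deviations, truncated at 0.

    Background edges deviate with sd ``subject_edge_sd``; planted edges
    with ``planted_edge_sd_multiplier`` times that.  The pre-truncation
    deviations are stored so PRS generation can reuse them as the planted
    edge-level signal.
    """
    if config.subject_edge_sd < 0:
        raise InvalidArgumentError("subject_edge_sd must be non-negative")
    rng = _stream(config.seed, _STREAM_EDGES)
    n = template.n_regions
    iu = np.triu_indices(n, k=1)
    pairs = np.column_stack(iu)
    template_vec = template.weights[iu]

    edge_sd = np.full(len(template_vec), float(config.subject_edge_sd))
    cols, _, _ = _resolve_planted(config, template.labels, pairs, template)
    edge_sd[cols] *= config.planted_edge_sd_multiplier
    dev = (
        rng.standard_normal((config.n_subjects, len(template_vec))) * edge_sd
        if config.subject_edge_sd > 0
        else np.zeros((config.n_subjects, len(template_vec)))
    )

    matrices = []
    for s in range(config.n_subjects):
        vec = np.maximum(template_vec + dev[s], 0.0)
        w = np.zeros((n, n))
        w[iu] = vec
        w += w.T
        matrices.append(ConnectivityMatrix(w, template.labels))
    return SubjectConnectomes(matrices, dev, pairs, template.labels, edge_sd)


def _resolve_planted(config: CohortConfig, labels, pairs: np.ndarray,
                     template: ConnectivityMatrix | None):
    """Map planted edges to edge-column indices, filling defaults."""
    labels = tuple(labels)
    label_to_idx = {lab: i for i, lab in enumerate(labels)}
    pair_to_col = {(int(a), int(b)): k for k, (a, b) in enumerate(pairs)}

    if config.planted_edges is None:
        if template is None:
            return np.array([], dtype=int), np.array([]), []
        vec = template.weights[np.triu_indices(template.n_regions, k=1)]
        cols = np.argsort(vec)[::-1][:6]
        weights = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0][: len(cols)])
    else:
        cols = []
        for a, b in config.planted_edges:
            ia = label_to_idx[a] if isinstance(a, str) else int(a)
            ib = label_to_idx[b] if isinstance(b, str) else int(b)
            key = (min(ia, ib), max(ia, ib))
            if key not in pair_to_col:
                raise InvalidArgumentError(f"planted edge {(a, b)} is not a valid region pair")
            cols.append(pair_to_col[key])
        cols = np.asarray(cols, dtype=int)
        weights = (
            np.asarray(config.planted_weights, dtype=float)
            if config.planted_weights is not None
            else np.ones(len(cols))
        )
    cols = np.asarray(cols, dtype=int)
    labeled = [(labels[int(pairs[c, 0])], labels[int(pairs[c, 1])]) for c in cols]
    return cols, weights, labeled


def generate_phenotypes(
    config: CohortConfig,
    edge_deviations: SubjectConnectomes,
    template: ConnectivityMatrix | None = None,
) -> pd.DataFrame:
    """Subject table: group, age, sex, site, genetic PCs and PRS.

    PRS = sum over planted edges of weight * edge deviation, plus Gaussian
    noise, standardized to mean 0 / sd 1 across the cohort.
    """
    n = config.n_subjects
    if edge_deviations.deviations.shape[0] != n:
        raise ShapeError("edge deviations do not match n_subjects")
    rng = _stream(config.seed, _STREAM_PHENO)

    lo, hi = config.age_range
    age = rng.uniform(lo, hi, size=n)
    site = np.array([f"site{k + 1:02d}" for k in rng.integers(0, config.n_sites, size=n)])
    sex = np.where(rng.random(n) < config.sex_ratio, "M", "F")
    group = np.where(rng.random(n) < config.proportion_case, "ASD", "CTL")
    pcs = rng.standard_normal((n, config.n_pcs))

    cols, weights, _ = _resolve_planted(
        config, edge_deviations.labels, edge_deviations.pairs, template
    )
    signal = edge_deviations.deviations[:, cols] @ weights if len(cols) else np.zeros(n)
    if len(cols):
        sd_cols = (
            edge_deviations.edge_sd[cols]
            if edge_deviations.edge_sd is not None
            else np.full(len(cols), config.subject_edge_sd)
        )
        signal_sd = float(np.sqrt(np.sum((weights * sd_cols) ** 2)))
    else:
        signal_sd = 0.0
    noise_sd = config.prs_noise_sd
    if noise_sd is None:
        noise_sd = signal_sd if signal_sd > 0 else 1.0
    if len(cols) == 0 and noise_sd == 0:
        raise DegeneratePRSError("no planted edges and prs_noise_sd=0: PRS would be constant")
    prs = signal + (rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0)
    sd = prs.std()
    if sd == 0:
        raise DegeneratePRSError("generated PRS is constant")
    prs = (prs - prs.mean()) / sd

    table = pd.DataFrame(
        {
            "subject_id": [f"sub{i + 1:04d}" for i in range(n)],
            "group": group,
            "age": age,
            "sex": sex,
            "site": site,
            "prs": prs,
        }
    )
    for j in range(config.n_pcs):
        table[f"pc{j + 1}"] = pcs[:, j]
    return table


def generate_thickness(
    parcellation: SphereParcellation,
    subjects: pd.DataFrame,
    centrality: CentralityMap | np.ndarray,
    config: CohortConfig,
) -> pd.DataFrame:
    """Subjects x parcels cortical thickness (mm).

    T(s, p) = baseline + site offset
              + age_slope * (age_s - mean age) * (1 + interaction_coupling * c(p))
              + group_effect * 1[ASD] * ((1 - hub_coupling) + hub_coupling * c(p))
              + prs_effect * prs_s * ((1 - hub_coupling) + hub_coupling * c(p))
              + spatially smooth noise,
    with c the centrality map min-max normalized to [0, 1].
    """
    cvals = centrality.values if isinstance(centrality, CentralityMap) else np.asarray(centrality, float)
    n_parcels = parcellation.n_parcels
    if cvals.shape != (n_parcels,):
        raise ShapeError("centrality length must equal the number of parcels")
    n = len(subjects)
    rng = _stream(config.seed, _STREAM_THICK)

    rngc = cvals.max() - cvals.min()
    c = (cvals - cvals.min()) / rngc if rngc > 0 else np.zeros(n_parcels)

    site_levels = sorted(subjects["site"].unique())
    offsets = dict(zip(site_levels, rng.normal(0.0, config.site_offset_sd, len(site_levels))))
    site_off = subjects["site"].map(offsets).to_numpy()

    age_c = subjects["age"].to_numpy() - subjects["age"].to_numpy().mean()
    is_asd = (subjects["group"] == "ASD").to_numpy().astype(float)
    prs = subjects["prs"].to_numpy()
    hubw = (1.0 - config.hub_coupling) + config.hub_coupling * c

    T = (
        config.baseline
        + site_off[:, None]
        + config.age_slope * age_c[:, None] * (1.0 + config.interaction_coupling * c[None, :])
        + config.group_effect * is_asd[:, None] * hubw[None, :]
        + config.prs_effect * prs[:, None] * hubw[None, :]
    )
    if config.noise_sd > 0:
        chol = _field_cholesky(parcellation, config.noise_lengthscale, config.noise_sd**2)
        T = T + rng.standard_normal((n, n_parcels)) @ chol.T
    return pd.DataFrame(T, index=subjects["subject_id"].to_numpy(), columns=list(parcellation.parcel_id))


@dataclass
class CohortData:
    """Everything one simulated cohort produces, plus its ground truth."""

    parcellation: SphereParcellation
    config: CohortConfig
    template: ConnectivityMatrix
    connectomes: SubjectConnectomes
    subjects: pd.DataFrame
    thickness: pd.DataFrame
    centrality: CentralityMap
    truth: dict


def simulate_cohort(
    parcellation: SphereParcellation,
    config: CohortConfig,
    template: ConnectivityMatrix | None = None,
) -> CohortData:
    """Run the full generator: template -> subject connectomes ->
    phenotypes -> thickness.

    A pre-built ``template`` may be supplied so several cohorts share one
    normative network; otherwise it is generated from the config seed.
    """
    if template is None:
        template = generate_template_connectome(parcellation, config)
    connectomes = generate_subject_connectomes(template, config)
    subjects = generate_phenotypes(config, connectomes, template)
    centrality = degree_centrality(template, mode="weighted")
    thickness = generate_thickness(parcellation, subjects, centrality, config)

    cols, weights, labeled = _resolve_planted(
        config, connectomes.labels, connectomes.pairs, template
    )
    truth = {
        "hubs": template.metadata.get("hubs", []),
        "planted_edges": [list(e) for e in labeled],
        "planted_weights": [float(w) for w in weights],
        "planted_edge_columns": [int(c) for c in cols],
        "group_effect": config.group_effect,
        "prs_effect": config.prs_effect,
        "hub_coupling": config.hub_coupling,
        "age_slope": config.age_slope,
        "interaction_coupling": config.interaction_coupling,
        "noise_sd": config.noise_sd,
        "seed": config.seed,
    }
    return CohortData(parcellation, config, template, connectomes, subjects, thickness, centrality, truth)


def write_cohort(data: CohortData, outdir) -> None:
    """Write the cohort in the on-disk exchange formats.

    subjects.csv, thickness.tsv, template_connectome.tsv,
    connectome_<subject>.tsv per subject, parcellation.csv and a
    truth.json sidecar with the planted ground truth.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    data.parcellation.to_csv(out / "parcellation.csv")
    data.subjects.to_csv(out / "subjects.csv", index=False)
    data.thickness.to_csv(out / "thickness.tsv", sep="\t")
    data.template.to_tsv(out / "template_connectome.tsv")
    for sid, mat in zip(data.subjects["subject_id"], data.connectomes.matrices):
        mat.to_tsv(out / f"connectome_{sid}.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(data.truth, fh, indent=2)
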