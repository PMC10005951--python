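"""Full-analysis orchestration.

Runs the complete chain on synthetic data: simulate a clinical-style
cohort (group contrast) and a general-population-style cohort (PRS,
connectomes) sharing one template network; fit the four parcelwise GLMs;
compute centrality from the group-mean connectome; run the four spin
tests of alteration-map vs centrality overlap; run CPM of PRS on the
subject connectomes; scan for disease epicenters with the group
alteration map; and intersect epicenters with CPM top-predictor regions.

All randomness derives from one master seed through fixed per-stage
streams, so any single stage can be re-run from its on-disk inputs and
reproduce the orchestrated run exactly.  The default configuration is
demo-scale (small cohorts, 200 rotations, 100 permutations).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, generate_template_connectome, simulate_cohort, write_cohort
from .cpm import CPMConfig, ConnectomePredictiveModel
from .epicenters import epicenter_scan, overlap_with_predictors
from .exceptions import InvalidArgumentError
from .glm import fit_parcelwise_glm
from .network import degree_centrality, group_connectome
from .spin import spin_test_multi
from .surface import build_parcellation

__all__ = ["PipelineConfig", "run_pipeline"]

_SPIN_KEYS = {
    "abide_group": "group_vs_centrality",
    "abide_age_by_group": "ageXgroup_vs_centrality",
    "ping_prs": "prs_vs_centrality",
    "ping_age_by_prs": "ageXprs_vs_centrality",
}


@dataclass(frozen=True)
class PipelineConfig:
    """Master configuration; nested dicts override cohort/CPM defaults."""

    seed: int = 0
    n_per_hemisphere: int = 31
    clinical: dict = field(default_factory=lambda: {"n_subjects": 120, "sex_ratio": 1.0})
    population: dict = field(default_factory=lambda: {
        "n_subjects": 100, "proportion_case": 0.0, "sex_ratio": 0.5, "n_pcs": 5, "n_sites": 4,
    })
    n_rotations: int = 200
    tail: str = "greater"
    alteration_statistic: str = "t"   # 't' or 'beta'
    cpm: dict = field(default_factory=lambda: {"k": 10, "n_permutations": 100})
    epicenter_alpha: float = 0.05
    epicenter_rotations: int | None = None   # defaults to n_rotations

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidArgumentError(f"unknown pipeline config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise InvalidArgumentError("pipeline config must set a seed")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_seeds(master: int) -> dict:
    rng = np.random.default_rng(master)
    names = ("template", "clinical", "population", "spin", "cpm", "epicenters")
    vals = rng.integers(0, 2**31, size=len(names))
    return {n: int(v) for n, v in zip(names, vals)}


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage, write all artifacts under ``outdir`` and
    return (and write) the machine-readable report."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    timing: dict = {}
    report: dict = {
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "versions": _versions(),
    }

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timing[name] = time.perf_counter() - self.t0

        return _T()

    with stage("simulate"):
        parcellation = build_parcellation(config.n_per_hemisphere)
        parcellation.to_csv(out / "parcellation.csv")
        template_cfg = CohortConfig(seed=seeds["template"])
        template = generate_template_connectome(parcellation, template_cfg)
        clinical_cfg = dataclasses.replace(
            CohortConfig.abide_like(**config.clinical), seed=seeds["clinical"]
        )
        population_cfg = dataclasses.replace(
            CohortConfig.ping_like(**config.population), seed=seeds["population"]
        )
        clinical = simulate_cohort(parcellation, clinical_cfg, template=template)
        population = simulate_cohort(parcellation, population_cfg, template=template)
        write_cohort(clinical, out / "clinical")
        write_cohort(population, out / "population")

    with stage("glm"):
        cohorts = {"abide_group": clinical, "abide_age_by_group": clinical,
                   "ping_prs": population, "ping_age_by_prs": population}
        glm_results = {}
        for family, cohort in cohorts.items():
            res = fit_parcelwise_glm(cohort.thickness, cohort.subjects, family)
            res.to_tsv(out / f"statmap_{family}.tsv")
            glm_results[family] = res

    with stage("centrality"):
        normative = group_connectome(population.connectomes.matrices)
        normative.to_tsv(out / "group_connectome.tsv")
        centrality = degree_centrality(normative, mode="weighted")
        centrality.to_tsv(out / "centrality.tsv")

    with stage("spin_tests"):
        maps = {
            key: glm_results[family].alteration_map(config.alteration_statistic)
            for family, key in _SPIN_KEYS.items()
        }
        # one shared rotation set: all four tests rotate the same centrality map
        results = spin_test_multi(
            maps, centrality.values, parcellation,
            n_rotations=config.n_rotations, tail=config.tail, seed=seeds["spin"],
        )
        spins = {}
        for key, res in results.items():
            with open(out / f"spin_{key}.json", "w") as fh:
                json.dump(res.to_dict(), fh, indent=2)
            spins[key] = {
                "observed_r": res.observed_r, "p_spin": res.p_spin,
                "n_rotations": res.n_rotations, "tail": res.tail, "seed": seeds["spin"],
            }
        report["spin_tests"] = spins

    with stage("cpm"):
        cpm_cfg = CPMConfig(seed=seeds["cpm"], **config.cpm)
        model = ConnectomePredictiveModel.from_matrices(
            population.connectomes.matrices, population.subjects["prs"].to_numpy(), cpm_cfg
        )
        cpm_res = model.permutation_significance(model.fit())
        top = cpm_res.top_predictors()
        top.to_csv(out / "top_edges.tsv", sep="\t", index=False)
        with open(out / "cpm.json", "w") as fh:
            json.dump(cpm_res.to_dict(), fh, indent=2)
        report["cpm"] = {
            "r_true_pred": cpm_res.r_true_pred,
            "p_perm": cpm_res.p_perm,
            "p_parametric": cpm_res.p_parametric,
            "n_top_predictors": int(len(top)),
            "empty_folds": cpm_res.empty_folds,
        }

    with stage("epicenters"):
        amap = glm_results["abide_group"].alteration_map(config.alteration_statistic)
        epi = epicenter_scan(
            normative, amap, parcellation,
            n_rotations=config.epicenter_rotations or config.n_rotations,
            alpha=config.epicenter_alpha, seed=seeds["epicenters"],
        )
        epi.to_tsv(out / "epicenters.tsv")
        overlap = overlap_with_predictors(epi, top)
        report["epicenters"] = {
            "alpha": epi.alpha,
            "significant_regions": epi.significant_regions,
        }
        report["overlap_regions"] = overlap

    report["timing"] = {k: round(v, 3) for k, v in timing.items()}
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _versions() -> dict:
    import scipy
    import sklearn

    return {
        "hubspin": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }
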