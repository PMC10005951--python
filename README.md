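# hubspin

Parcel-level analysis of how structural brain-network architecture shapes
cortical alterations — in a clinical contrast (autism spectrum disorder,
ASD, vs controls) and along the continuum of polygenic risk for ASD in
the general population.

`hubspin` implements the full analysis chain on 62-region parcellated
data, together with a synthetic-cohort generator with known ground truth
so every stage can be validated end to end:

1. **Mass-univariate GLMs** on subjects × parcels cortical thickness
   (mm).  Four model families: `abide_group`
   (`T = β₀ + β₁·Site + β₂·Group + β₃·Age + ε`, Age mean-centred),
   `abide_age_by_group` (adds `Age×Group`), `ping_prs`
   (`T = β₀ + β₁·Age + β₂·PRS + β₃·PC₁…₂₀ + β₄·Scanner + β₅·Sex + ε`)
   and `ping_age_by_prs` (adds `Age×PRS`).  The per-parcel t-map of the
   coefficient of interest is the "alteration map" used downstream.
2. **Hub mapping** on a structural connectome (symmetric region × region
   mean-streamline matrix, zero edges retained, weights untransformed):
   weighted degree centrality `s_i = Σ_j w_ij` and a top-quantile hub
   set.
3. **Spin permutation tests** of spatial overlap between two parcel
   maps.  The null rotates the spherical representation of the cortex by
   Haar-uniform rotations R (right hemisphere by the mirrored rotation
   M·R·M), resamples the rotated map at the nearest rotated centroid per
   parcel, and recomputes the Pearson correlation;
   `p_spin = (1 + #{r_null ≥ r_obs}) / (1 + n_rotations)` (one-tailed
   "greater" by default).
4. **Connectome predictive modeling (CPM)** of a polygenic risk score
   (PRS): per cross-validation fold, edges are screened by training-set
   correlation with the target (`p < 0.01`, split by sign), summarized
   into positive/negative network strengths, and fed to an OLS model;
   out-of-fold predictions give `r(true, predicted)`, with significance
   by target permutation.
5. **Disease-epicenter mapping**: for each seed region, the correlation
   between its connectivity profile (self entry excluded) and the
   alteration map, with per-region spin significance; epicenters are
   intersected with CPM top-predictor regions.
6. **Power utilities**: Fisher-z correlation power, exact noncentral-t
   sample-size search, and a two-sided variance-ratio F test.

The synthetic generator plants the structure these analyses look for:
hub-structured connectomes whose edge probability decays with geodesic
distance, group/age/PRS thickness effects whose amplitude is coupled to
node centrality, and a PRS built from a sparse set of planted connectome
edges plus noise.

## Worked example

```python
import hubspin as hs

parcellation = hs.build_parcellation(31)          # 62 parcels, mirrored hemispheres
cohort = hs.simulate_cohort(parcellation, hs.CohortConfig(seed=7))

glm = hs.ParcelwiseGLM(cohort.thickness, cohort.subjects, "abide_group").fit()
print(glm.summary())

overlap = hs.spin_test(glm.alteration_map(), cohort.centrality.values,
                       parcellation, n_rotations=1000, seed=1)
print(f"hub overlap: r = {overlap.observed_r:.2f}, p_spin = {overlap.p_spin:.4f}")

model = hs.ConnectomePredictiveModel.from_matrices(
    cohort.connectomes.matrices, cohort.subjects["prs"].to_numpy(),
    hs.CPMConfig(seed=1, n_permutations=100))
print(model.permutation_significance(model.fit()).summary())
```

prints

```
Parcelwise GLM [abide_group] — coefficient: Group[ASD]
parcels: 62   residual df: 553
beta: mean +0.0319  range [+0.0003, +0.0822]
t:    mean +3.594  range [+0.039, +8.706]
parcels with p < 0.05: 46 / 62

hub overlap: r = 0.89, p_spin = 0.0010

CPM (combined network, kfold, k=10)
subjects: 560   edges: 1891
r(true, predicted) = +0.606   parametric p = 2.03e-57
permutation p = 0.009901 (100 permutations)
edges selected per fold: median 26
```

Read: with the default generator (0.1 mm group effect, 80% of it scaled
by normalized centrality, 0.1 mm smooth noise, n = 560), ASD parcels are
thicker (all Group betas positive), the group t-map co-localizes with
the centrality map far beyond the rotation null (r = 0.89 at the
smallest attainable p of 1/1001), and the subject connectomes predict
the standardized PRS out of fold at r ≈ 0.61 — below the √0.5 ≈ 0.71
ceiling set by the planted signal fraction, as expected from
edge-screening dilution.

## Command line

Every stage is also a subcommand operating on CSV/TSV/JSON files:

```bash
hubspin simulate --out data/ --seed 7
hubspin glm --model abide_group --thickness data/thickness.tsv \
        --subjects data/subjects.csv --out statmap.tsv
hubspin centrality --connectome data/template_connectome.tsv --out centrality.tsv
hubspin spin-test --map-a statmap.tsv --map-b centrality.tsv \
        --parcellation data/parcellation.csv --rotations 1000 --seed 1 --out spin.json
hubspin cpm --connectomes-dir data/ --subjects data/subjects.csv \
        --target prs --folds 10 --perms 1000 --seed 1 --out cpm.json
hubspin epicenters --connectome data/template_connectome.tsv --map statmap.tsv \
        --parcellation data/parcellation.csv --seed 1 --out epicenters.tsv
hubspin power --test corr --r 0.2 --n 391
hubspin run --out run/ --seed 5          # full pipeline + report.json
```

The pipeline report schema is published in `docs/report_schema.json`;
the modelling details, generator assumptions and numerical choices are
documented in `docs/methods.md`.

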