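# Methods

This note documents the models implemented in `hubspin`, the synthetic
data they are validated on, the numerical choices, and the limits of
what the synthetic validation shows.

## Spherical surface model

Parcels are points on the unit sphere: the left hemisphere is a
Fibonacci lattice on the open hemisphere x < 0 (for n parcels, point i
has cosine `u = (i + 0.5)/n` from the −x axis and azimuth `2πi/φ` with φ
the golden ratio), and the right hemisphere is its exact mirror image
(x negated).  The default 31 parcels per hemisphere give the 62-region
resolution of the analyses; at that density the minimum within-
hemisphere angular separation is ≈ 0.39 rad.  All distances are geodesic
(arc length), matching the semantics of spherical rotation.

Spatially autocorrelated maps are draws from a zero-mean Gaussian
process with squared-exponential kernel
`k(a,b) = σ² exp(−d(a,b)² / (2ℓ²))` in geodesic distance, sampled by
Cholesky factorization with a relative diagonal jitter of 1e−8
(escalated tenfold on failure).  The default lengthscale ℓ = 0.5 rad
stands in for the smoothness that surface-based blurring imposes on real
cortical thickness maps: at 0.5 rad neighbouring parcels correlate at
≈ 0.7–0.9, dropping below 0.05 beyond ~1.2 rad.

## Synthetic cohorts

`CohortConfig` defaults describe a clinical-scale cohort: n = 560
subjects, case fraction 266/560, ages uniform on 6–35 y, five sites,
baseline thickness 2.5 mm.  Presets `abide_like()` (all male, 266/294
case/control) and `ping_like()` (n = 391, 207 M / 184 F, ages 3–21 y,
13 scanner sites, 20 genetic principal components, no cases) mirror the
two study populations the model families are named for.

**Template connectome.**  Edge existence probability is
`density^(d/d̄ · 0.35^h)` where d is geodesic distance, d̄ its off-
diagonal mean, and h ∈ {0,1,2} the number of endpoints in a designated
hub set (12 regions by default, drawn at random and recorded in the
matrix metadata); at density 1 the graph is complete.  Existing edges
get gamma(2, 5) weights (mean 10 streamlines) times 2.5 per hub
endpoint.  These constants were set so that every hub's weighted degree
exceeds the 75th percentile of non-hub degrees and the top-20% strength
rule recovers the planted hub set with Jaccard ≥ 0.6, across seeds.

**Subject connectomes.**  Each subject's matrix is the template plus
symmetric zero-diagonal Gaussian edge deviations truncated at zero.
Background edges deviate with sd 2 (streamline units); the planted
PRS-carrying edges deviate with 4× that sd.  The multiplier encodes the
premise that edges carrying an individual-differences signal must vary
more between individuals than background edges, and it is what makes
the planted signal recoverable by screening-based prediction: with
selection threshold p < 0.01 over E = 1891 edges, every cross-validation
fold admits ≈ 0.01·E ≈ 19 false edges whose variance dilutes the
network-strength scores.  With K planted edges per sign of variance
m²σ² against F false edges of variance σ², the two-score model's
attainable R² is `0.5 · K m² / (K m² + F)`; at K = 3, m = 1 this is
≈ 0.12 (out-of-fold r ≈ 0.35) — the planted signal would be lost to
dilution — while m = 4 gives ≈ 0.42 (r ≈ 0.65), comfortably detectable
yet below the √0.5 ceiling, which is the regime the validation targets.

**PRS.**  `prs = Σ_e w_e · deviation_e + N(0, σ_noise)`, standardized.
Defaults: the six strongest template edges with weights
(+1, +1, +1, −1, −1, −1), and σ_noise equal to the planted-signal sd, so
the planted edges explain exactly half of the PRS variance.  No
genotypes are simulated: the score is defined directly on connectome
deviations because the validation needs a target with known edge-level
ground truth, not a realistic genetic architecture.

**Thickness.**  For subject s and parcel p, with c̃(p) the min-max
normalized centrality of the template and age mean-centred:

```
T(s,p) = baseline + site_offset(site(s))
       + age_slope · age_c(s) · (1 + ic · c̃(p))
       + group_effect · 1[ASD] · ((1 − hc) + hc · c̃(p))
       + prs_effect  · prs(s)  · ((1 − hc) + hc · c̃(p))
       + GP noise (sd = noise_sd, lengthscale = noise_lengthscale)
```

Defaults: group_effect 0.1 mm, prs_effect 0.05 mm/SD, hub coupling
hc = 0.8, age slope −0.02 mm/y (cortical thinning) with interaction
coupling ic = 0.8, site offsets N(0, 0.05 mm), noise 0.1 mm.  The mm
scale of the PRS effect has no empirical anchor; it was chosen so the
PRS map is detectable at the cohort sizes used, and should be read as a
test-power choice, not an effect-size claim.  All stages draw from
fixed substreams of the config seed, so identical configs reproduce
bit-identical cohorts.

## Parcelwise GLM

Ordinary least squares per parcel, vectorized across parcels (shared
design matrix; per-parcel residual variance).  Categorical covariates
are one-hot coded against the first level in sort order with an explicit
intercept; the group indicator is 1 for ASD so positive betas mean
ASD > CTL; age is mean-centred before interaction products are formed.
Rank deficiency is detected up front (pivoted QR names the offending
columns); residual df below 10 is refused.  Two-sided p-values come from
the t distribution with n − rank(X) df.  The map passed to overlap and
epicenter analyses is the t-map by default — t is scale-free across
parcels — with betas available via `alteration_map("beta")`.

## Spin permutation test

Rotations are Haar-uniform on SO(3) (`scipy.stats.special_ortho_group`).
The left hemisphere rotates by R, the right by M·R·M (M negates x), so
mirrored anatomy stays mirrored under the null.  Each parcel takes the
value of the geodesically nearest rotated centroid *within its own
hemisphere*, ties broken by lowest index; sources may repeat.  p-values
use the add-one convention `(1 + #{null ≥ obs}) / (1 + n)`, one-tailed
"greater" by default (two-sided and Spearman variants available), so the
smallest attainable p at 1000 rotations is 1/1001 ≈ 0.001.  The
centrality (normative) map is conventionally the rotated one.

Calibration: for two independent smooth GP maps the rejection rate at
p < 0.05 is ≈ 0.05.  Nearest-neighbour resampling with replacement
duplicates sources, which slightly inflates null-correlation variance
when the fixed map is heavy-tailed (e.g. a raw connectivity profile);
such pairings test mildly conservatively.  When several fixed maps are
tested against the same rotated map (the pipeline's four alteration
maps vs one centrality map), the rotated-map null is computed once and
shared (`spin_test_multi`) — the null distribution does not depend on
the fixed map.

## CPM

Per fold (k = 10 shuffled folds by default; leave-one-out available):
edges are correlated with the training target; those with p < 0.01 form
positive and negative masks by sign; network scores are plain sums of
the masked edge weights; an OLS with intercept on the (up to two) scores
predicts the held-out subjects.  Folds with no selected edges predict
the training-target mean (logged), which keeps permutation nulls
defined.  Significance permutes the target and reruns the entire
cross-validated pipeline, `p_perm = (1 + #{r_null ≥ r_obs}) / (1 + n)`;
a parametric p for the observed r is also reported, since at 1000
permutations the permutation p cannot resolve below ≈ 0.001.  Top
predictors are edges selected (either sign) in all folds by default,
sorted by mean |training correlation|.  Out-of-fold null predictions
carry the usual small negative correlation bias of cross-validation;
at n = 300 the permuted-target mean r is within ±0.05 of zero.

## Epicenter scan

For each seed region, Pearson correlation between its connectivity
profile (its own entry excluded — the structural zero on the diagonal
would otherwise distort r) and the alteration map restricted to the
remaining regions; significance by rotating the alteration map, removing
the seed's slot after resampling, one-tailed greater.  One rotation set
is shared across the 62 seed regions by default (per-region independent
nulls via `shared_null=False`; Benjamini–Hochberg correction via
`fdr=True`, off by default).  Regions with constant profiles are
excluded with a warning.

The 62 regional tests within one scan are *not* independent: profiles of
nearby regions correlate, and a single rotated-map draw can align with
the connectome's global structure and push many regions over threshold
together.  The per-region type-I rate is nominal (≈ 0.05 measured over
300 null scans), but the significant-count distribution is overdispersed
relative to Poisson (sd ≈ 3.3 vs 1.8 at mean 3.1), whether nulls are
shared or independent.  Family-wise summaries of epicenter counts should
therefore not assume independence across regions.

## Pipeline

`run_pipeline` simulates a clinical cohort (group contrast, all male)
and a general-population cohort (PRS, mixed sex, PC block) on one shared
template network; fits the four GLMs; computes weighted degree
centrality from the population group-mean connectome; runs the four spin
tests against centrality (shared rotation set); CPM of PRS on the
population connectomes; the epicenter scan of the group t-map; and the
epicenter × top-predictor overlap.  All stage seeds derive from one
master seed and are recorded in the report, so any stage re-run from its
on-disk inputs reproduces the orchestrated result exactly.  Default
configuration is demo-scale — 120/100 subjects, 200 rotations, 100
permutations — sized for quick exploration; full-scale runs set cohort
sizes and rotation/permutation counts in the YAML config.

## Power utilities

Correlation power uses the Fisher z approximation
(`z = atanh(r)·√(n−3)`); against an exact-simulation oracle the
approximation is accurate to < 0.01 over the tested grid (r = 0.2,
n = 100–400).  Two-sample t sample size does integer bisection on exact
noncentral-t power, returning the smallest per-group n meeting the
target (d = 1, α = 0.05, power 0.8 → n = 17).  The variance-ratio test
is the standard two-sided F test,
`p = 2·min(P(F' ≥ F), P(F' ≤ F))` with (n_a−1, n_b−1) df.

## What the synthetic validation does and does not show

The generator produces exactly the structure the analyses assume:
Gaussian smooth fields, linear covariate effects, truncated-Gaussian
edge noise, and a PRS that is a linear function of connectome edges.
Passing tests therefore demonstrate correctness of the statistical
machinery and internal consistency of the chain (planted hubs are
found, planted overlap is detected at the stated rates, planted edges
are recovered, type-I rates are nominal under the null generator) — not
that real cortical data satisfy these assumptions.  In particular:
streamline counts here are continuous, not integer; thickness noise is
stationary on the sphere, unlike real cortical maps; site effects are
pure intercept shifts; and the PRS–thickness effect scale is a test
design choice.  Printed correlations from real-data studies are not
reproduction targets of this package.
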