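# Methods

This note documents the models implemented in `isomix`, their
assumptions, the defaults that matter, and what the synthetic-data
generator does and does not emulate.

## Collagen quality control

Bone/dentine collagen that has undergone diagenesis gives unreliable
δ13C and δ15N. Samples are screened on the atomic C/N ratio, accepted
inside a window of 2.9–3.6 (the van Klinken convention for
archaeological bone; `QCConfig.cn_min/cn_max`, configurable), and on
collagen yield, with a default minimum of 1% by weight
(`QCConfig.min_yield`). A sample whose collagen fails is excluded from
carbonate statistics as well: diagenesis severe enough to degrade the
protein fraction casts doubt on the bioapatite, so carbonate exclusion
propagates from collagen failure. Exclusion percentages are reported
per human/fauna group, rounded to one decimal place; full precision is
retained internally.

Group comparisons use the two-sided Mann–Whitney test. The statistic
is reported as U = min(U1, U2) with ties counted half (midranks); this
is the convention under which small published U values with large
n1·n2 are interpretable. P-values come from exact enumeration when the
data are tie-free and n1·n2 ≤ 10,000, otherwise from the tie-corrected
normal approximation (both via `scipy.stats.mannwhitneyu`). One caveat
for users comparing against published tables: a U statistic can never
exceed n1·n2, so a reported "U" above that bound is a rank sum, not a
U, and cannot be reproduced as one.

## Oxygen conversion chain

Bioapatite carbonate δ18O (VPDB) is converted to ingested-water δ18O
(VSMOW) through three affine regressions applied in sequence:

    δ18O_VSMOW     = 1.03092 · δ18O_VPDB + 30.92
    δ18O_phosphate = 1.0322  · δ18O_carbonate(VSMOW) − 9.6849
    δ18O_water     = 1.55    · δ18O_phosphate − 33.49

The chain is exact and exactly invertible (`water_to_carbonate_vpdb`);
round-trip error is at machine precision. Values are only rounded to
one decimal place at report time. A conservative 2‰ uncertainty is
attached to modelled water values for individuals — the regression,
cooking/brewing and diagenesis uncertainties dwarf analytical error —
while a cluster mean carries the standard error of the cluster mean
instead. Both are configurable. The chain is applied only to samples
whose carbonate passed QC. No species-specific body-water models or
enamel-vs-bone offsets are applied.

## Bayesian dietary mixing

The mixing model estimates the caloric contribution vector α of K
food groups from a consumer group's proxy means (collagen δ13C, δ15N,
carbonate δ13C) under mass balance, in the FRUITS model family:

* Each source k is split into macronutrient fractions f ∈ {protein,
  energy} with caloric concentrations c_{k,f} (summing to 1 within a
  source) and per-fraction isotopic signals s_{k,f,i}.
* For a proxy i with routing weights R over fractions,

      pred_i = Δ_i + Σ_f R_{i,f} · (Σ_k α_k c_{k,f} s_{k,f,i}) / (Σ_k α_k c_{k,f})

  Collagen δ13C routes 75% protein / 25% energy, δ15N 100% protein.
  Carbonate δ13C uses a "whole-diet" routing in which fraction weights
  are the caloric shares Σ_k α_k c_{k,f} themselves (they sum to 1, so
  the prediction is the concentration-weighted mean over the whole
  diet).
* Diet-to-tissue offsets default to Δδ13C_collagen = 4.8 ± 0.5‰,
  Δδ15N = 5.5 ± 0.5‰, Δδ13C_carbonate = 10.1 ± 1.0‰ — standard
  mixing-literature values, fully overridable, and not to be read as
  measured data. The same applies to the default source signals in
  `default_sources()` (C3/C4 photosynthetic endmembers near −26.5‰ and
  −11.5‰, trophic-level δ15N for terrestrial meat, marine enrichment
  to ~12‰): they are configuration for a plausible late-medieval
  Mediterranean economy, meant to be replaced by site-specific food
  values where available.
* The base prior on α is uniform on the simplex; user-declared linear
  inequality priors (e.g. α_C3 ≥ 0.3) are part of the prior and are
  enforced by rejection. Infeasible constraint systems are detected at
  build time by Dirichlet sampling and refused.

Inference is random-walk Metropolis on the additive-logistic (softmax)
transform of the simplex (K−1 free logits, last pinned at 0; the
transform's Jacobian Σ log α_k makes the base prior uniform). Source
signals, offsets and concentrations are latent values: each iteration
alternates (1) a z-step with the latents held fixed and (2) an
independence refresh of all latents from their priors (prior terms
cancel in the acceptance ratio), a valid Metropolis-within-Gibbs
scheme that fully propagates source and offset uncertainty rather
than merely inflating the likelihood variance. Per-chain step sizes
adapt toward 30% acceptance during burn-in and are frozen afterwards.
Defaults: 4 chains, 2000 burn-in, 4000 retained iterations per chain.
Split R-hat and effective sample size (via `arviz`) are always
computed; the posterior is flagged unconverged, with a loud warning,
when any R-hat exceeds 1.05. Degenerate case: a one-source problem
returns the exact point posterior α = 1.

Calibration rather than reproduction: the published per-site interval
estimates depend on unpublished model settings (food signal tables,
priors), so they are not a reproduction target. The sampler is instead
held to simulation-based calibration — with α drawn from the prior and
data generated from the model, nominal 95% equal-tailed intervals must
achieve 90–99% pooled empirical coverage over 100 replicates
(`interval_coverage_study`) — plus exact recovery on the analytically
solvable two-source problem within Monte-Carlo error.

## Mixture clustering

Dietary structure: full EM over 2-D (δ13C_collagen, δ15N) points for
every k in 1–5 and covariance family in {spherical, diagonal, full},
k-means++ initialisation, 20 seeded restarts, a 1e−6 variance floor,
convergence at relative log-likelihood change < 1e−8 (max 500
iterations). The minimum-BIC solution is returned, with BIC =
−2·loglik + p·ln n; ties break toward smaller k, then the simpler
family. The per-iteration log-likelihood trajectory is retained so its
monotonicity — the defining property of EM — can be asserted in tests;
scikit-learn's `GaussianMixture` is the independent cross-check.

Mobility structure: trimmed classification-EM on 1-D δ18O_water with
k = 2 and a 5% trimming threshold. At each iteration the lowest-density
points are set aside as outliers and excluded from the parameter
updates. The trim count follows the tclust convention, n_trim = n −
floor((1−α)·n), which coincides with floor(α·n) whenever α·n is
integral. A variance-ratio restriction (largest/smallest cluster
variance ≤ 12, the tclust default) prevents the classification
likelihood from collapsing onto a near-degenerate two-point cluster.
Outliers are excluded from cluster means/sds but reported alongside.
Clusters are always reported sorted by mean, so solutions are
deterministic up to the seed. Points are unweighted; a measurement-
uncertainty weighting was considered and left as future configuration
since the reference workflow's behaviour on this point is unstated.

## Isoscape and residence assignment

The drinking-water δ18O baseline is smoothed from point predictions
(lon, lat, mean, se) by Gaussian-process regression with a Matérn-5/2
kernel, per-point observation noise se², and a fitted white-noise
nugget; hyperparameters maximise the marginal likelihood. The smoother
is a contract of properties, not of kernel choice: it must reproduce a
constant field exactly, interpolate low-noise observations to within
0.01‰, and recover a known smooth field with grid RMSE < 0.5‰. The
grid is a cell-centred 0.5° lattice over a configurable bounding box
(default 10°W–30°E, 35°N–60°N). No land mask is applied by default.

Residence assignment compares a measured water value x (uncertainty
σ_m) against every cell's predictive mean μ_c and sd σ_c:

    w_c ∝ exp(−(x − μ_c)² / (2(σ_m² + σ_c²))) / sqrt(σ_m² + σ_c²)

normalised to a probability surface over the grid. Individuals use the
2‰ conversion uncertainty; cluster means use the cluster standard
error. Increasing σ_m can only flatten the map (entropy is
non-decreasing), and for equal cell sds probability decreases
monotonically with |x − μ_c|. `map_summary` reports the smallest cell
set reaching a cumulative probability level plus the modal cell.
Because δ18O isolines are not spatially unique, a residence map is a
compatibility surface, not a point estimate of origin.

## Synthetic data

The generators emulate the statistical structure of the target
assemblage so every stage has seeded ground truth: 134 humans and 21
fauna across three sites (113/17/4); a 12% collagen QC failure rate
injected by pushing C/N out of window; two dietary clusters in a 15:63
ratio, one along a C3→C4 protein mixing line and one along a C3→marine
line, with per-individual α interpolated between archetype endpoints
and proxies produced by the forward mixing model plus 0.35‰ Gaussian
noise; a mobility mixture of 57 residents (water −7.7 ± 0.8‰), 5
migrants (−12.9 ± 0.9‰) and four fixed extreme values (−16.4, −16.5,
−10.8, −5.3‰), back-converted to carbonate through the exact inverse
chain; elevated faunal δ15N baselines; and an isoscape field with a
southward-enriched latitudinal gradient plus an alpine depletion bump
(≈ −7.1‰ in the study area, ≈ −14‰ in the high Alps). An optional
nursing offset adds to neonate δ15N.

What passing tests on these fixtures do *not* show: real assemblages
have non-Gaussian measurement structure, spatially correlated
baselines, unknown true source signals, and mobility histories that
mix water sources within one skeleton. Planted-structure recovery here
demonstrates correctness of the algorithms under their own
assumptions, not field performance.

## Problem sizes and numerical choices

Defaults were chosen so a full synthetic pipeline run completes in
seconds and the calibration study in about two minutes: 100-replicate
coverage runs use 4 chains × (1500 burn-in + 2000 retained)
iterations; clustering restarts default to 20 (10 inside the
pipeline). Quantile intervals are equal-tailed empirical quantiles of
the pooled draws. All randomness flows from explicit integer seeds;
identical seeds reproduce identical draws, assignments and files
(SHA-256 digests in the run manifest).

## Known limitations

* Dietary estimates are group-level (cluster or site means ± sd);
  no individual-level informative priors.
* Single-isotope geographic assignment is inherently ambiguous along
  isolines; no Sr or multi-isotope joint assignment.
* No modelling of breastfeeding physiology (only a synthetic nursing
  offset), collagen degradation chemistry, or tooth-section time
  series.
* The default food-source table is a documented stand-in; serious use
  requires site-specific food isotopic data.
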