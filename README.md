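# isomix

Bayesian multi-proxy inference of palaeodiet and residential mobility
from stable-isotope measurements on archaeological skeletal remains
(bone/dentine collagen δ13C and δ15N, bioapatite carbonate δ13C and
δ18O). Written for bioarchaeologists and isotope analysts who want the
full workflow — quality control, unit conversions, mixing-model diet
estimation, clustering, and isoscape-based origin assignment — as
tested, scriptable Python instead of a chain of point-and-click tools.

## What it does

1. **Quality control** (`isomix.samples`) — screens collagen on the
   atomic C/N ratio (2.9–3.6) and collagen yield, propagates collagen
   failure to carbonate results, and reports per-group exclusion
   percentages, summary statistics (mean ± sd per group) and
   Mann–Whitney *U* comparisons (U = min(U₁,U₂), exact or
   tie-corrected p).
2. **δ18O conversion** (`isomix.oxygen`) — the affine chain from
   carbonate VPDB through VSMOW and phosphate to drinking-water δ18O:
   δ18O_VSMOW = 1.03092·δ18O_VPDB + 30.92;
   δ18O_phosphate = 1.0322·δ18O_carbonate − 9.6849;
   δ18O_water = 1.55·δ18O_phosphate − 33.49 — exactly invertible, with
   a conservative 2‰ modelled-water uncertainty.
3. **Bayesian dietary mixing** (`isomix.mixing`) — a FRUITS-family
   concentration-dependent mixing model: food sources split into
   protein/energy fractions, macronutrient routing per proxy,
   diet-to-tissue offsets, inequality priors on the contribution
   vector α, and MCMC on the simplex with full propagation of source
   and offset uncertainty. Reports means, medians and 68%/95%
   equal-tailed credible intervals per source plus the derived
   protein-vs-energy caloric split, with R-hat/ESS diagnostics.
4. **Clustering** (`isomix.cluster`) — 2-D Gaussian-mixture EM with
   BIC model selection over covariance families for (δ13C, δ15N)
   dietary structure, and trimmed (5%) classification-EM on 1-D
   δ18O_water to separate residents from migrants and flag outliers.
5. **Isoscape & assignment** (`isomix.isoscape`) — Gaussian-process
   smoothing of environmental water-δ18O point data onto a grid, and
   normalised residence-probability maps
   w_c ∝ exp(−(x−μ_c)²/(2(σ_m²+σ_c²)))/√(σ_m²+σ_c²).
6. **Synthetic data** (`isomix.synth`) — seeded generators reproducing
   the statistical structure of a 134-human/21-fauna medieval
   assemblage (two dietary mixing lines, resident/migrant δ18O
   mixture, ~12% QC failures) with ground truth for every stage.
7. **Pipeline & CLI** (`isomix.pipeline`, `isomix` command) —
   config-driven end-to-end runs with SHA-256 manifests and cached
   partial reruns.

## Worked example

Separate residents from migrants in a synthetic assemblage and locate
the migrant cluster against a water-isotope baseline:

```python
import numpy as np
from isomix import synth, cluster as cl
from isomix.oxygen import convert_array
from isomix.isoscape import GridSpec, fit_isoscape, assign_residence, map_summary

mob = synth.generate_mobility(synth.PopulationSpec(seed=1))
water = convert_array(mob["d18O_carb_vpdb"].to_numpy())
sol = cl.fit_trimmed_1d(water, k=2, trim_fraction=0.05, restarts=20, seed=1)
print("cluster sizes:", sol.cluster_sizes(), "outliers:", sol.n_outliers)
print("cluster means (permil):", np.round(sol.means, 1))

pts = synth.generate_isoscape_points(n=250, seed=52)
surface = fit_isoscape(pts, GridSpec(cell=1.0), seed=1)
mean, se = surface.local_estimate(15.1, 41.5)
print(f"local baseline: {mean:.1f} +/- {se:.2f} permil")

rm = assign_residence(surface, float(sol.means[0]),
                      sigma_m=float(np.sqrt(sol.covariances[0] / 4)))
s = map_summary(rm, 0.5)
print("migrant cluster argmax cell:", s["argmax"], "| 50% region:", s["n_cells"], "cells")
```

Output:

```
cluster sizes: {0: 4, 1: 58} outliers: 4
cluster means (permil): [-13.3  -7.6]
local baseline: -7.1 +/- 0.26 permil
migrant cluster argmax cell: {'lon': 13.5, 'lat': 59.5} | 50% region: 27 cells
```

Reading this: the trimmed clustering recovers the planted structure —
a 58-strong resident cluster at −7.6‰ (matching the smoothed local
baseline of −7.1 ± 0.26‰ at the study-area coordinates), a small
depleted cluster at −13.3‰, and four extreme values set aside as
outliers. The migrant cluster's residence map is spread over 27 cells
at the 50% level: single-isotope assignment is a compatibility
surface, and here both the Alpine bump and the far north of the grid
carry water values near −13‰, so the map is honestly ambiguous
between them.

The same workflow end to end, from the shell:

```sh
isomix simulate --seed 1 --outdir run
isomix qc run/samples.csv --out-accepted run/accepted.csv --out-report run/qc.json
isomix convert run/accepted.csv --out run/converted.csv
isomix cluster oxygen run/converted.csv --seed 1 --trim 0.05
isomix run config.yaml --outdir run --seed 1   # full pipeline from a config file
```

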