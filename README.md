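# infilstat

Spatial-statistics quantification of immune-cell infiltration in tumours
from 2-D point patterns of cell centroids.

Digital-pathology pipelines can extract the (x, y) coordinates of every
stained immune cell (e.g. CD68+ macrophages) in a region of interest, but a
bare point cloud is hard to interpret. `infilstat` turns such point
patterns into quantitative infiltration estimates for researchers working
with immunohistochemistry data:

* **Spatial statistics.** The pair correlation function g(r), the
  nearest-neighbour CDF G(r), the spherical-contact (empty-space) CDF F(r)
  and the J-function J(r) = (1 − G)/(1 − F), with an analytic
  annulus–window edge correction for g on rectangular windows. Three
  scalar features summarise a pattern: g_max (peak clustering intensity),
  F_max (radius of the largest "immune desert") and J_min (depth of
  clustering).
* **Synthetic tissue generator.** Two-compartment tumour-nest/stroma
  geometries from thresholded Gaussian random fields with nest length
  scale l, filled with a hard-core point process (0.02 mm exclusion,
  about one cell diameter). The infiltration ratio ρ = d_t/d_s — nest
  density over stroma density — labels each pattern: ρ = 0 means full
  immune exclusion, ρ = 1 a uniform distribution. Densities follow the
  head-and-neck CD68+ cohort (Normal(333, 170) cells/mm², truncated at
  150).
* **Maximum-likelihood inference.** Per feature, the per-ρ training mean
  and SD are fitted with exponentials μ(ρ) = a·e^(−bρ) + c; features are
  modelled as (multivariate) normal with empirical cross-correlations,
  and ρ is estimated from any subset of {g_max, F_max, J_min} by
  profiling ln L(ρ) = −½(ln|Σ| + (x−μ)ᵀΣ⁻¹(x−μ) + k ln 2π) over a dense
  grid, with 95% Wilks profile confidence intervals
  {ρ : ln L ≥ ln L(η) − ½ χ²₀.₉₅,₁}.

See `docs/methods.md` for the model details, numerical choices and
limitations.

## Worked example

```python
import warnings
import numpy as np
from infilstat import GenerationParams, generate_pattern, summary_features
from infilstat.evaluate import simulate_feature_table
from infilstat.mle import fit_feature_curves, estimate_rho
from infilstat.synthetic import RHO_GRID

# train a small feature model (50 patterns per rho)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    train = simulate_feature_table(np.repeat(RHO_GRID, 50), seed=0)
    model = fit_feature_curves(train)

# one synthetic ROI with known infiltration
pattern, geometry = generate_pattern(
    GenerationParams(rho=0.2, d=333.0, l=0.4), seed=42)
feats = summary_features(pattern, seed=7)
print(f"n = {pattern.n} cells, density d = {feats.d:.1f} cells/mm^2")
print(f"g_max = {feats.g_max:.3f}, F_max = {feats.F_max:.3f} mm, "
      f"J_min = {feats.J_min:.3f}")
est = estimate_rho(feats, model, subset="gFJ")
print(f"eta_gFJ = {est.eta:.3f}, 95% CI = [{est.ci_lower:.3f}, {est.ci_upper:.3f}]")
```

prints

```
n = 749 cells, density d = 332.9 cells/mm^2
g_max = 1.391, F_max = 0.133 mm, J_min = 0.319
eta_gFJ = 0.270, 95% CI = [0.084, 0.370]
```

The pattern was generated with a true infiltration ratio of ρ = 0.2 at the
cohort's mean density in a 1.5 mm × 1.5 mm window. Its features — a modest
clustering peak (g_max 1.39), largest empty circle of radius 0.13 mm and a
J-function dipping to 0.32 — are scored against the trained feature model;
combining all three statistics gives the estimate η = 0.27 with a 95%
profile-likelihood interval that covers the truth.

For batch work the same steps are available from the shell:

```sh
infilstat synth-generate --out-dir data --reps 200 --n-validation 500 --seed 1
infilstat featurize --manifest data/training/train_manifest.csv --out train.csv
infilstat train --features train.csv --out model.json
infilstat featurize --manifest data/validation/val_manifest.csv --out val.csv
infilstat predict --features val.csv --model model.json --out preds.csv
infilstat validate --predictions preds.csv
infilstat reproduce-figures --features train.csv --model model.json \
    --predictions preds.csv --out-dir figures
```

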