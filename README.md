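# biduomap

Bivariate Bayesian shared-component disease mapping for small-area mortality
data.

When two diseases share a risk factor with a geographical footprint (for
example asbestos exposure driving both pleural and ovarian cancer mortality),
their area-level risk surfaces are correlated — but raw standardized mortality
ratios (SMRs) in small areas are far too noisy for a correlation of maps to
mean anything. `biduomap` addresses this with joint hierarchical Poisson
models whose latent structure separates what the two diseases share from what
is specific to each, and with principled tools for deciding how much any of
the candidate models should be trusted.

It is aimed at spatial epidemiologists and biostatisticians who have
area-level death counts, population denominators and an adjacency structure,
and want shared-component inference with explicit model-uncertainty reporting.

## The model family

Observed deaths in area *i* for disease *k ∈ {P, O}* follow

```
O_ik ~ Poisson(E_ik · θ_ik)
```

where `E_ik` is the expected count under internal indirect standardization
(stratum-specific regional rates applied to the area's person-years, so that
Σ_i E_ik = Σ_i O_ik). The log relative risk combines up to four latent
components:

```
log θ_iP = α_P + δ·u_i + u_iP + ω·v_i + v_iP
log θ_iO = α_O + u_i/δ + u_iO + v_i/ω + v_iO
```

* `u_ik`, `u_i` — spatially structured "clustering" fields (intrinsic CAR:
  each area's effect is conditionally normal around its neighbours' mean with
  precision λ·n_i), disease-specific and shared;
* `v_ik`, `v_i` — unstructured i.i.d. Gaussian "heterogeneity" fields;
* `δ, ω` — scaling parameters that let the shared components load
  asymmetrically on the two diseases (log-normal priors, log ~ N(0, 0.17));
* precisions carry diffuse Gamma(0.5, 0.0005) hyperpriors, intercepts are flat.

The nine supported specifications **M1–M9** are all subsets of this structure:
M1 (`Uk Vk`) is two independent Besag–York–Mollié models, M7 (`Uk U Vk V`) the
full shared model, M4 (`U Vk V`) the parsimonious shared-clustering variant,
and so on.

Inference is Metropolis-within-Gibbs MCMC (single-site adaptive random-walk
updates for fields, conjugate Gibbs for precisions and intercepts, log-scale
random walk for δ and ω) with multiple chains and Gelman–Rubin convergence
diagnostics. Models are scored on two axes:

* **support** — WAIC computed from the per-observation log-likelihood draws,
  `WAIC = −2·lppd + 2·p_WAIC`;
* **robustness** — the median calibrated Kullback–Leibler divergence: per
  observation, the Gaussian KL between the posterior log-relative-risk
  marginals under a reference model and an alternative, re-expressed as the
  `p ∈ [0.5, 1)` solving `KL(Bernoulli(0.5), Bernoulli(p)) = c`. A model that
  changes nothing scores 0.5; values near 1 mean the alternative would revise
  the risk map substantially.

## Worked example

Simulate a 10×10 municipality lattice from the shared-clustering world
(shared field SD 0.6, δ = 0.5, expected counts 20–200), fit the generating
model M4 and the no-sharing model M1, and compare:

```python
import numpy as np
import biduomap as bm
from biduomap.comparison import comparison_table

cfg = bm.SimulationConfig(rows=10, cols=10, sd_shared_clustering=0.6, delta=0.5,
                          e_min=20, e_max=200, seed=7)
data, truth, graph = bm.simulate_bivariate_dataset(cfg)
fits = {name: bm.fit_model(name, data, graph, n_chains=2, n_iter=2000,
                           burn_in=800, thin=3, seed=42)
        for name in ("M4", "M1")}

d = fits["M4"].pooled_scalar("delta")
print(f"delta posterior median {np.median(d):.3f}, "
      f"95% CrI [{np.percentile(d, 2.5):.3f}, {np.percentile(d, 97.5):.3f}]")
print(comparison_table(bm.compare_models(fits, "M4")).round(3).to_string(index=False))
```

prints

```
delta posterior median 0.506, 95% CrI [0.468, 0.539]
model description     waic     lppd  p_waic  calibrated_kl_median
   M4      U Vk V 1543.942 -681.916  90.055                  0.50
   M1       Uk Vk 1563.235 -678.939 102.679                  0.66
```

The true δ = 0.5 sits inside its credible interval; WAIC prefers the
generating shared model by ~19 points, and the calibrated KL of 0.66 says that
dropping the shared component would materially change the inferred risk
surfaces (0.50 would mean "no change").

The same pipeline is available from the shell:

```sh
biduomap simulate --config sim.json --out sim/
biduomap fit M4 --config fit.json --out fit_M4/
biduomap compare --config cmp.json --out cmp/
biduomap summarize --config sum.json --out summary/
```

with all inputs and outputs as CSV/GAL/JSON files (`standardize` turns a
stratified counts CSV into expected counts and an SMR/funnel table first).

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch at run time, the package's
headline reference quantity — the median calibrated KL of a reference model
evaluated against itself, over a freshly generated set of posterior marginals —
and writes it to JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
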