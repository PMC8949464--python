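# Methods

## Standardization and funnel statistics

Expected counts use *internal* indirect standardization: for each disease the
stratum-specific rate of the whole study region (stratum = age class ×
calendar year by default; an age-only collapse is a configuration option) is
applied to each area's person-years and summed. This makes Σ_i E_ik = Σ_i O_ik
per disease an identity, which the code asserts to 1e-9 relative tolerance.
Areas with zero person-years carry E = 0, are flagged rather than divided when
SMRs are formed, and are excluded from the model likelihood (0/0 carries no
information about relative risk).

The funnel exceedance p-value is the exact one-sided Poisson upper tail
P(X ≥ O | E), not mid-p — the conservative convention used with funnel-plot
control limits. Funnel bands solve for the smallest integer count q with
P(X ≥ q | E) ≤ 1 − level and convert to the SMR scale as q/E, with no
continuity correction or interpolation: the bands are exact, reproducible,
and sawtoothed at small E as exact Poisson quantiles are. Because published
tables round E to two decimals, recomputed O/E ratios and tail probabilities
can differ from printed ones in the last digit; the tests propagate that
rounding explicitly rather than loosening the formulas.

## The model family

All nine models are Poisson log-linear models whose random-effect structure is
a subset of {disease-specific clustering Uk, shared clustering U,
disease-specific heterogeneity Vk, shared heterogeneity V}. Clustering fields
have intrinsic CAR priors in the pairwise-difference form
−λ/2 Σ_edges (u_i − u_l)², equivalent to each site being conditionally normal
around its neighbour mean with precision λ·n_i. The ICAR density is improper:
its precision matrix λ(D − W) has rank n − c for c connected components, and
the precision Gibbs update and the log-prior normalizing term both use that
rank. Shared components load on disease P multiplied by the scaling (δ for
clustering, ω for heterogeneity) and on disease O divided by it, exactly as
the linear predictors above; which disease receives the multiplication is a
convention, and swapping it is equivalent to replacing δ by 1/δ.

Priors: Gamma(0.5, 0.0005) (shape, rate) on every precision; N(0, 0.17) on
log δ and log ω (i.e. a diffuse log-normal on the scalings); improper flat on
the intercepts. The σ² = 0.17 is read as a *variance*; it corresponds to a
95% prior range of roughly (0.45, 2.2) for δ itself.

## Sampler

Metropolis-within-Gibbs, designed for WinBUGS-like genericity across all nine
specifications without derivative code:

* **Fields** — single-site Gaussian random-walk Metropolis. Sites are grouped
  by a greedy colouring of the adjacency graph; within a colour class no two
  sites are neighbours, so their full conditionals are mutually independent
  given the rest and the per-site accept/reject steps vectorise without
  changing the kernel. Heterogeneity fields are conditionally independent
  across all areas and form a single class. Per-site proposal scales adapt
  toward acceptance ≈ 0.4 during burn-in only (step size decaying as 5/t,
  capped at 0.1) and are frozen afterwards, so the post-burn-in kernel is a
  fixed, valid Metropolis kernel.
* **Precisions** — conjugate Gamma Gibbs draws (heterogeneity: shape + n/2;
  clustering: shape + rank/2 with the pairwise sum of squared differences in
  the rate).
* **Intercepts** — exact Gibbs: with a flat prior, exp(α_k) given everything
  else is Gamma(Σ O_k, Σ E exp(η − α_k)). This soaks the regional total, so
  the posterior predictive total matches the observed total up to Monte Carlo
  error (asserted in the tests).
* **δ, ω** — random walk on the log scale against the N(0, 0.17) prior,
  adaptive during burn-in.
* **Identifiability** — the ICAR prior is flat along constants, and a shared
  or specific clustering field can trade a constant against the intercepts.
  After every sweep each clustering field and the shared heterogeneity field
  is mean-centred, with the removed mean absorbed into the intercepts through
  the δ/ω scalings; the linear predictor is exactly invariant (asserted to
  1e-12). Island (degree-0) areas are excluded from the centring mean and are
  never field-updated; disease-specific heterogeneity has a proper prior and
  is left uncentred.
* **Initialization** — intercepts at log(ΣO/ΣE), fields at chain-specific
  N(0, 0.1²) jitter, δ = ω = 1, precisions at 10. Chains are seeded by
  spawning independent streams from the master seed, so a fixed seed and
  configuration reproduce draws bit-identically.
* **Defaults** — 2 chains, 4 000 iterations, 1 500 burn-in, thinning 5 at
  library level; the tests run shorter chains (2 000/800/3) at desk scale,
  which the strong identification of δ at expected counts of 20–200 supports.
  No published chain lengths exist to match; these are implementation
  choices. Convergence is monitored by the classic Gelman–Rubin potential
  scale reduction factor per scalar parameter, flagged above 1.1.

## Model comparison

WAIC is computed from the stored per-observation log-likelihood matrix with
lppd through log-sum-exp and p_WAIC as the K−1 sample variance per
observation. Observations are ordered disease-P block first, then disease-O,
and E = 0 observations are excluded — the same fixed order used for the
calibrated KL so the two measures always refer to the same data points.

For model influence, each observation's posterior of log θ_ik is summarised by
its pooled-draw mean and SD (a normal approximation that is accurate here
because the log-relative-risk marginals are near-Gaussian at these counts);
the KL divergence from the reference model's marginal (the "actual belief",
first argument) to the alternative's is the closed-form Gaussian KL, and is
calibrated by solving KL(B(0.5), B(p)) = c for p ∈ [0.5, 1) with bracketed
root-finding to 1e-10 (verified against the forward Bernoulli KL to 1e-8).
The per-model summary is the median over all observations pooled across both
diseases — the headline figure — with per-disease medians also emitted, since
it is ambiguous whether a pooled or per-disease median is the more natural
summary.

## Synthetic data

The generator states a world with the same structure the models assume: an
adjacency lattice (rook or queen contiguity), ICAR-distributed clustering
fields, i.i.d. heterogeneity fields, asymmetric shared scalings, and Poisson
counts. Defaults mirror the validation setting used throughout the tests:
20 × 20 rook lattice (400 areas), shared clustering SD 0.6, δ = 0.5,
specific heterogeneity SD 0.1, expected counts log-uniform on (20, 200).

Design choices worth knowing:

* **Field scaling.** Clustering fields are drawn exactly from the ICAR law via
  the eigendecomposition of the graph Laplacian restricted to its positive
  eigenspace (exact and feasible to ~5 000 areas), then rescaled so their
  *empirical* across-area SD equals the configured value. The conditional
  ICAR scale and the marginal spread differ by a graph-dependent factor;
  stating the marginal SD makes the configured value directly comparable to
  how fitted field variability is reported, and makes the shared-contribution
  SDs exactly sd·δ and sd/δ.
* **Expected counts** are log-uniform to emulate the several-orders-of-
  magnitude spread of real municipality populations. The validation world
  truncates this to (20, 200): large enough to identify δ sharply, small
  enough that a 20-replicate recovery study runs in minutes. Real data reach
  both far smaller (E < 0.01, where the likelihood is nearly flat) and far
  larger expecteds.
* **Ground truth** (all fields, δ, ω, the realized log θ surfaces, the seed)
  is returned with every dataset and serializable to JSON, so recovery tests
  score the posterior against the exact generative values.
* A stratified-population generator produces person-years and deaths by
  area × age class × year with a geometric age gradient in the rates, to
  exercise the standardization pipeline end-to-end. It does not attempt
  realistic demography (no cohort structure, no migration, flat time trend),
  and the lattice worlds carry none of the size heterogeneity, irregular
  adjacency or registration artefacts of real municipality data — a green
  recovery test establishes correctness of the inference machinery under the
  stated world, not field performance on administrative mortality data.

## Known limitations

* Single-site random-walk updates mix slowly for very strong spatial fields
  or very large lattices; chain lengths should be scaled up (and R-hat
  checked) beyond desk scale.
* ω is weakly identified when the shared heterogeneity variance is small —
  its R-hat is the usual first flag; the likelihood carries little
  information about a scaling whose field is near zero.
* The exact Poisson funnel p-values are conservative at very small E; areas
  with E below ~0.5 can never reach p < 0.001 regardless of the observed
  count's excess ratio.
* Choropleth rendering is out of scope; per-area CSVs are emitted for joining
  to external geography.
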