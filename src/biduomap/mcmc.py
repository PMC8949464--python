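"""Metropolis-within-Gibbs sampler for the M1-M9 bivariate disease-mapping models.

The sampler mixes exact Gibbs steps where conjugacy allows them with adaptive
random-walk Metropolis elsewhere:

* latent fields — single-site Gaussian random-walk Metropolis.  Sites are
  grouped by a greedy graph colouring so that no two neighbours are updated
  simultaneously; within a colour class the single-site full conditionals are
  mutually independent given the rest, so the per-site accept/reject steps can
  be vectorised without changing the kernel.  Heterogeneity fields are one
  colour class (their conditionals are independent across areas).
* precisions — conjugate Gamma Gibbs draws; the clustering update uses the
  rank of the intrinsic CAR precision, ``n - n_components``.
* intercepts — exact Gibbs: with a flat prior, ``exp(alpha_k)`` given the rest
  is Gamma(sum O_k, sum E exp(eta - alpha_k)).
* scalings delta, omega — random walk on the log scale against the
  Normal(0, sigma^2) prior on the log.
* identifiability — after every sweep each clustering field and the shared
  heterogeneity field is mean-centred with the removed mean absorbed into the
  intercepts through the shared-component scalings, leaving the likelihood
  exactly unchanged (the intrinsic CAR prior is flat along constants, so the
  posterior is invariant too).

Proposal scales adapt per site during burn-in toward acceptance ~0.4 and are
frozen afterwards, preserving the correct stationary distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.special import gammaln

from .models import ModelParams, ModelSpec, PriorConfig, model_registry, observation_index
from .spatial import AreaGraph, BivariateAreaData, DISEASES

__all__ = [
    "PosteriorDraws",
    "fit_model",
    "update_precision",
    "recentre_fields",
    "gelman_rubin",
    "rhat_table",
]

_TARGET_ACC = 0.4


@dataclass
class PosteriorDraws:
    """Thinned posterior draws from one or more chains.

    ``scalars[name]`` has shape (chains, draws); ``fields[name]`` and
    ``log_theta[disease]`` have shape (chains, draws, n_areas); ``loglik`` has
    shape (chains, draws, n_observations) in the order given by ``obs_index``.
    """

    spec: ModelSpec
    area_ids: tuple[str, ...]
    obs_index: list[tuple[str, str]]
    scalars: dict[str, np.ndarray]
    fields: dict[str, np.ndarray]
    log_theta: dict[str, np.ndarray]
    loglik: np.ndarray
    acceptance: dict[str, float]
    seed: int
    n_iter: int
    burn_in: int
    thin: int

    @property
    def n_chains(self) -> int:
        return self.loglik.shape[0]

    @property
    def n_draws(self) -> int:
        return self.loglik.shape[1]

    def pooled_loglik(self) -> np.ndarray:
        """(chains*draws, n_obs) pointwise log-likelihood matrix for WAIC."""
        return self.loglik.reshape(-1, self.loglik.shape[-1])

    def pooled_log_theta(self, disease: str) -> np.ndarray:
        return self.log_theta[disease].reshape(-1, self.log_theta[disease].shape[-1])

    def pooled_scalar(self, name: str) -> np.ndarray:
        return self.scalars[name].reshape(-1)

    def pooled_field(self, name: str) -> np.ndarray:
        return self.fields[name].reshape(-1, self.fields[name].shape[-1])


def gelman_rubin(draws: np.ndarray) -> float:
    """Potential scale reduction factor R-hat for one scalar parameter.

    ``draws`` has shape (chains, draws).  R-hat = sqrt(((n-1)/n W + B/n)/W)
    with W the mean within-chain variance and B = n * variance of the chain
    means; values above ~1.1 indicate non-convergence.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("need >= 2 chains")
    m, n = draws.shape
    if n < 10:
        raise ValueError("need >= 10 draws per chain")
    w = draws.var(axis=1, ddof=1).mean()
    b = n * draws.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def rhat_table(draws: PosteriorDraws) -> dict[str, float]:
    """R-hat for every stored scalar parameter (requires >= 2 chains)."""
    return {name: gelman_rubin(vals) for name, vals in draws.scalars.items()}


def update_precision(
    field_values: np.ndarray,
    rng: np.random.Generator,
    priors: PriorConfig = PriorConfig(),
    graph: AreaGraph | None = None,
) -> float:
    """Conjugate Gibbs draw for a field precision.

    Heterogeneity (``graph=None``): Gamma(shape + n/2, rate + sum v^2 / 2).
    Clustering: Gamma(shape + (n - n_components)/2, rate + 1/2 sum over edges
    of the squared difference) — the shape uses the rank of the intrinsic CAR
    precision, so a constant field contributes nothing to the rate.
    """
    v = np.asarray(field_values, dtype=float)
    if graph is None:
        shape = priors.precision_shape + v.size / 2.0
        rate = priors.precision_rate + 0.5 * float(v @ v)
    else:
        i, j = graph.edge_arrays()
        d = v[i] - v[j]
        shape = priors.precision_shape + (graph.n_areas - graph.n_components()) / 2.0
        rate = priors.precision_rate + 0.5 * float(d @ d)
    return float(rng.gamma(shape, 1.0 / rate))


def _graph_coloring(graph: AreaGraph) -> list[np.ndarray]:
    """Colour classes of non-island sites (greedy colouring; neighbours differ)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(graph.n_areas))
    g.add_edges_from(graph.edges)
    colors = nx.coloring.greedy_color(g, strategy="largest_first")
    deg = graph.n_i
    classes: dict[int, list[int]] = {}
    for node, c in colors.items():
        if deg[node] > 0:
            classes.setdefault(c, []).append(node)
    return [np.asarray(sorted(v), dtype=int) for _, v in sorted(classes.items())]


class _Sampler:
    """One-chain sampler state.  Internal; use :func:`fit_model`."""

    def __init__(
        self,
        spec: ModelSpec,
        data: BivariateAreaData,
        graph: AreaGraph,
        priors: PriorConfig,
        rng: np.random.Generator,
        likelihood: bool = True,
        fix_precisions: dict[str, float] | None = None,
    ):
        self.spec, self.graph, self.priors, self.rng = spec, graph, priors, rng
        self.likelihood = likelihood
        self.fix_precisions = fix_precisions or {}
        n = graph.n_areas
        self.n = n
        self.O = {k: np.asarray(data.observed[k], dtype=float) for k in DISEASES}
        self.E = {k: np.asarray(data.expected[k], dtype=float) for k in DISEASES}
        for k in DISEASES:
            if ((self.E[k] == 0) & (self.O[k] > 0)).any():
                raise ValueError("observed deaths with zero expected count")
        self.gammaln_o = {k: gammaln(self.O[k] + 1.0) for k in DISEASES}
        self.obs_mask = {k: self.E[k] > 0 for k in DISEASES}
        # sparse adjacency for neighbour sums
        i, j = graph.edge_arrays()
        rows = np.concatenate([i, j])
        cols = np.concatenate([j, i])
        self.W = sparse.csr_matrix(
            (np.ones(rows.size), (rows, cols)), shape=(n, n)
        )
        self.deg = graph.n_i.astype(float)
        self.non_island = self.deg > 0
        self.colors = _graph_coloring(graph)
        self.all_sites = np.arange(n)

        tot_o = {k: self.O[k].sum() for k in DISEASES}
        tot_e = {k: self.E[k].sum() for k in DISEASES}
        if likelihood and any(tot_o[k] <= 0 for k in DISEASES):
            raise ValueError("each disease needs a positive total observed count")
        jitter = lambda: 0.1 * rng.standard_normal(n)  # chain-specific start spread, sd 0.1
        self.alpha = {
            k: (np.log(tot_o[k] / tot_e[k]) if likelihood else 0.0) for k in DISEASES
        }
        self.fields: dict[str, np.ndarray] = {}
        self.prec: dict[str, float] = {}
        if spec.shared_clustering:
            self.fields["shared_clustering"] = jitter() * self.non_island
            self.prec["shared_clustering"] = self.fix_precisions.get("shared_clustering", 10.0)
        if spec.specific_clustering:
            for k in DISEASES:
                self.fields[f"specific_clustering_{k}"] = jitter() * self.non_island
                self.prec[f"specific_clustering_{k}"] = self.fix_precisions.get(
                    f"specific_clustering_{k}", 10.0
                )
        if spec.shared_heterogeneity:
            self.fields["shared_heterogeneity"] = jitter()
            self.prec["shared_heterogeneity"] = self.fix_precisions.get("shared_heterogeneity", 10.0)
        if spec.specific_heterogeneity:
            for k in DISEASES:
                self.fields[f"specific_heterogeneity_{k}"] = jitter()
                self.prec[f"specific_heterogeneity_{k}"] = self.fix_precisions.get(
                    f"specific_heterogeneity_{k}", 10.0
                )
        self.delta = 1.0 if spec.shared_clustering else None
        self.omega = 1.0 if spec.shared_heterogeneity else None

        self.scales = {name: np.full(n, 0.3) for name in self.fields}
        self.scale_delta = 0.1
        self.scale_omega = 0.1
        self.acc_counts: dict[str, float] = {}
        self.acc_trials: dict[str, float] = {}
        self.iteration = 0
        self.eta = {k: self._compute_eta(k) for k in DISEASES}
        if not all(np.isfinite(self.eta[k]).all() for k in DISEASES):
            raise ValueError("non-finite linear predictor at initialization")

    # -- linear predictor bookkeeping -------------------------------------

    def _field_scale(self, name: str, disease: str) -> float:
        """Coefficient of a field in the given disease's linear predictor."""
        if name == "shared_clustering":
            return self.delta if disease == "P" else 1.0 / self.delta
        if name == "shared_heterogeneity":
            return self.omega if disease == "P" else 1.0 / self.omega
        # disease-specific: enters its own disease with coefficient 1
        return 1.0 if name.endswith(disease) else 0.0

    def _compute_eta(self, disease: str) -> np.ndarray:
        eta = np.full(self.n, self.alpha[disease])
        for name, f in self.fields.items():
            c = self._field_scale(name, disease)
            if c != 0.0:
                eta = eta + c * f
        return eta

    def _record_acc(self, block: str, accepted: float, trials: float) -> None:
        self.acc_counts[block] = self.acc_counts.get(block, 0.0) + accepted
        self.acc_trials[block] = self.acc_trials.get(block, 0.0) + trials

    def _adapt(self, scales: np.ndarray, accepted: np.ndarray, idx) -> None:
        step = min(0.1, 5.0 / max(self.iteration, 10))
        scales[idx] *= np.exp(step * (accepted - _TARGET_ACC))

    # -- update blocks ----------------------------------------------------

    def _loglik_delta(self, disease: str, idx: np.ndarray, d_eta: np.ndarray) -> np.ndarray:
        """Change in Poisson log-likelihood at sites ``idx`` when eta shifts by d_eta."""
        if not self.likelihood:
            return np.zeros(len(idx))
        o = self.O[disease][idx]
        mu = self.E[disease][idx] * np.exp(self.eta[disease][idx])
        return o * d_eta - mu * np.expm1(d_eta)

    def update_field_sites(self, name: str, idx: np.ndarray, adapt: bool) -> None:
        """Single-site Metropolis update of field ``name`` at the (independent) sites ``idx``."""
        rng = self.rng
        f = self.fields[name]
        lam = self.prec[name]
        step = self.scales[name][idx] * rng.standard_normal(idx.size)
        if "clustering" in name:
            nbr_sum = np.asarray(self.W[idx] @ f).ravel()
            ni = self.deg[idx]
            new = f[idx] + step
            d_prior = -0.5 * lam * (ni * (new**2 - f[idx] ** 2) - 2.0 * step * nbr_sum)
        else:
            new = f[idx] + step
            d_prior = -0.5 * lam * (new**2 - f[idx] ** 2)
        d_post = d_prior
        for k in DISEASES:
            c = self._field_scale(name, k)
            if c != 0.0:
                d_post = d_post + self._loglik_delta(k, idx, c * step)
        accept = np.log(rng.uniform(size=idx.size)) < d_post
        if accept.any():
            sel = idx[accept]
            f[sel] += step[accept]
            for k in DISEASES:
                c = self._field_scale(name, k)
                if c != 0.0:
                    self.eta[k][sel] += c * step[accept]
        if adapt:
            self._adapt(self.scales[name], accept.astype(float), idx)
        else:
            self._record_acc(name, float(accept.sum()), float(accept.size))

    def _update_field(self, name: str, adapt: bool) -> None:
        if "clustering" in name:
            for idx in self.colors:
                self.update_field_sites(name, idx, adapt)
        else:
            self.update_field_sites(name, self.all_sites, adapt)

    def _update_scaling(self, which: str, adapt: bool) -> None:
        rng = self.rng
        cur = self.delta if which == "delta" else self.omega
        fname = "shared_clustering" if which == "delta" else "shared_heterogeneity"
        scale = self.scale_delta if which == "delta" else self.scale_omega
        f = self.fields[fname]
        log_new = np.log(cur) + scale * rng.standard_normal()
        new = float(np.exp(log_new))
        d_post = (log_new**2 - np.log(cur) ** 2) * (-0.5 / self.priors.log_scaling_var)
        coeffs = {"P": (new - cur), "O": (1.0 / new - 1.0 / cur)}
        if self.likelihood:
            for k in DISEASES:
                d_eta = coeffs[k] * f
                d_post += float(np.sum(self._loglik_delta(k, self.all_sites, d_eta)))
        accept = np.log(rng.uniform()) < d_post
        if accept:
            for k in DISEASES:
                self.eta[k] += coeffs[k] * f
            if which == "delta":
                self.delta = new
            else:
                self.omega = new
        if adapt:
            step = min(0.1, 5.0 / max(self.iteration, 10))
            newscale = scale * np.exp(step * (float(accept) - _TARGET_ACC))
            if which == "delta":
                self.scale_delta = newscale
            else:
                self.scale_omega = newscale
        else:
            self._record_acc(which, float(accept), 1.0)

    def _update_intercepts(self) -> None:
        # flat prior => exp(alpha) | rest ~ Gamma(sum O, sum E exp(eta - alpha))
        if not self.likelihood:
            return
        for k in DISEASES:
            rest = self.eta[k] - self.alpha[k]
            rate = float(np.sum(self.E[k] * np.exp(rest)))
            shape = float(self.O[k].sum())
            new = float(np.log(self.rng.gamma(shape, 1.0 / rate)))
            self.eta[k] += new - self.alpha[k]
            self.alpha[k] = new

    def _update_precisions(self) -> None:
        for name in self.prec:
            if name in self.fix_precisions:
                continue
            graph = self.graph if "clustering" in name else None
            self.prec[name] = update_precision(
                self.fields[name], self.rng, self.priors, graph=graph
            )

    def _recentre(self) -> None:
        recentre_fields(self)

    def sweep(self, adapt: bool) -> None:
        self.iteration += 1
        for name in self.fields:
            self._update_field(name, adapt)
        if self.spec.shared_clustering:
            self._update_scaling("delta", adapt)
        if self.spec.shared_heterogeneity:
            self._update_scaling("omega", adapt)
        self._update_intercepts()
        self._update_precisions()
        self._recentre()
        if self.iteration % 200 == 0:  # guard against float drift in the eta caches
            self.eta = {k: self._compute_eta(k) for k in DISEASES}

    # -- draw extraction --------------------------------------------------

    def scalar_state(self) -> dict[str, float]:
        out = {f"alpha_{k}": self.alpha[k] for k in DISEASES}
        if self.delta is not None:
            out["delta"] = self.delta
        if self.omega is not None:
            out["omega"] = self.omega
        for name, lam in self.prec.items():
            out[f"prec_{name}"] = lam
        return out

    def pointwise_loglik(self) -> np.ndarray:
        out = []
        for k in DISEASES:
            m = self.obs_mask[k]
            mu = self.E[k][m] * np.exp(self.eta[k][m])
            out.append(self.O[k][m] * np.log(mu) - mu - self.gammaln_o[k][m])
        return np.concatenate(out)


def recentre_fields(state: _Sampler) -> None:
    """Mean-centre clustering and shared fields, absorbing the mean into intercepts.

    The removed mean enters disease P's intercept multiplied by the shared
    scaling (delta or omega) and disease O's divided by it, so every linear
    predictor is exactly unchanged.  Islands are excluded from the centring
    mean (the intrinsic CAR prior carries no information about them).
    Disease-specific heterogeneity has a proper prior and is left alone.
    """
    for name in state.fields:
        if name.startswith("specific_heterogeneity"):
            continue
        f = state.fields[name]
        if "clustering" in name:
            m = float(f[state.non_island].mean())
        else:
            m = float(f.mean())
        if m == 0.0:
            continue
        f -= m
        if name == "shared_clustering":
            state.alpha["P"] += m * state.delta
            state.alpha["O"] += m / state.delta
        elif name == "shared_heterogeneity":
            state.alpha["P"] += m * state.omega
            state.alpha["O"] += m / state.omega
        else:  # disease-specific clustering
            k = name[-1]
            state.alpha[k] += m


def fit_model(
    spec: ModelSpec | str,
    data: BivariateAreaData,
    graph: AreaGraph,
    priors: PriorConfig = PriorConfig(),
    n_chains: int = 2,
    n_iter: int = 4000,
    burn_in: int = 1500,
    thin: int = 5,
    seed: int = 0,
    likelihood: bool = True,
    fix_precisions: dict[str, float] | None = None,
) -> PosteriorDraws:
    """Fit a model specification by Metropolis-within-Gibbs MCMC.

    Runs ``n_chains`` independent chains (each seeded deterministically from
    ``seed``), adapts proposal scales during burn-in only, and retains every
    ``thin``-th post-burn-in sweep.  Per-draw pointwise log-likelihoods and
    log relative risks are stored for WAIC and calibrated-KL computation.

    Parameters
    ----------
    likelihood
        If False, sample from the prior only (for sampler validation);
        typically combined with ``fix_precisions``.
    fix_precisions
        Map field name -> fixed precision excluded from the Gibbs update.
    """
    if isinstance(spec, str):
        spec = model_registry(spec)
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    if tuple(data.area_ids) != tuple(graph.area_ids):
        raise ValueError("data and graph must share the same area ids, in order")
    n_draws = (n_iter - burn_in) // thin
    if n_draws < 1:
        raise ValueError("no retained draws: lower thin or raise n_iter")
    seeds = np.random.SeedSequence(seed).spawn(n_chains)
    obs_index = observation_index(data)
    n_obs = len(obs_index)
    n = graph.n_areas

    chains = [
        _Sampler(spec, data, graph, priors, np.random.default_rng(s), likelihood, fix_precisions)
        for s in seeds
    ]
    scalar_names = sorted(chains[0].scalar_state())
    field_names = sorted(chains[0].fields)
    scalars = {nm: np.empty((n_chains, n_draws)) for nm in scalar_names}
    fields_out = {nm: np.empty((n_chains, n_draws, n)) for nm in field_names}
    log_theta = {k: np.empty((n_chains, n_draws, n)) for k in DISEASES}
    loglik = np.empty((n_chains, n_draws, n_obs))

    for c, chain in enumerate(chains):
        d = 0
        for it in range(n_iter):
            chain.sweep(adapt=it < burn_in)
            if it >= burn_in and (it - burn_in) % thin == thin - 1:
                if d < n_draws:
                    st = chain.scalar_state()
                    for nm in scalar_names:
                        scalars[nm][c, d] = st[nm]
                    for nm in field_names:
                        fields_out[nm][c, d] = chain.fields[nm]
                    for k in DISEASES:
                        log_theta[k][c, d] = chain.eta[k]
                    loglik[c, d] = chain.pointwise_loglik()
                    d += 1

    acc = {}
    for chain in chains:
        for blk, cnt in chain.acc_counts.items():
            acc[blk] = acc.get(blk, 0.0) + cnt / chain.acc_trials[blk] / n_chains
    return PosteriorDraws(
        spec=spec,
        area_ids=tuple(data.area_ids),
        obs_index=obs_index,
        scalars=scalars,
        fields=fields_out,
        log_theta=log_theta,
        loglik=loglik,
        acceptance=acc,
        seed=seed,
        n_iter=n_iter,
        burn_in=burn_in,
        thin=thin,
    )
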