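"""The nine bivariate disease-mapping model specifications M1-M9.

Each model is a Poisson log-linear model for observed deaths O_ik ~
Poisson(E_ik * theta_ik) over areas i and diseases k in {P, O}, whose log
relative risk combines up to four latent components:

    Uk  disease-specific clustering   (intrinsic CAR per disease)
    U   shared clustering             (one ICAR field, x delta for P, / delta for O)
    Vk  disease-specific heterogeneity (i.i.d. Gaussian per disease)
    V   shared heterogeneity          (one i.i.d. field, x omega for P, / omega for O)

M1 (Uk Vk) is the classical Besag-York-Mollie model fitted independently per
disease; M7 (Uk U Vk V) is the full shared-component model.  Precisions carry
Gamma(0.5, 0.0005) hyperpriors, the log scalings log delta and log omega a
Normal(0, 0.17) prior, and intercepts improper flat priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .spatial import AreaGraph, BivariateAreaData, DISEASES

__all__ = [
    "MODEL_REGISTRY",
    "ModelSpec",
    "ModelParams",
    "PriorConfig",
    "model_registry",
    "linear_predictor",
    "pointwise_loglik",
    "log_prior",
    "observation_index",
]

# Component sets exactly as tabulated in the model family description.
_REGISTRY: dict[str, frozenset[str]] = {
    "M1": frozenset({"Uk", "Vk"}),
    "M2": frozenset({"Uk", "U", "Vk"}),
    "M3": frozenset({"Uk", "U", "V"}),
    "M4": frozenset({"U", "Vk", "V"}),
    "M5": frozenset({"Uk", "Vk", "V"}),
    "M6": frozenset({"U", "V"}),
    "M7": frozenset({"Uk", "U", "Vk", "V"}),
    "M8": frozenset({"U", "Vk"}),
    "M9": frozenset({"Uk", "V"}),
}
MODEL_REGISTRY = dict(_REGISTRY)


@dataclass(frozen=True)
class ModelSpec:
    """Which latent components a model includes."""

    name: str
    specific_clustering: bool  # Uk
    shared_clustering: bool  # U
    specific_heterogeneity: bool  # Vk
    shared_heterogeneity: bool  # V

    @property
    def description(self) -> str:
        parts = []
        if self.specific_clustering:
            parts.append("Uk")
        if self.shared_clustering:
            parts.append("U")
        if self.specific_heterogeneity:
            parts.append("Vk")
        if self.shared_heterogeneity:
            parts.append("V")
        return " ".join(parts)


def model_registry(name: str) -> ModelSpec:
    """Look up one of the nine model specifications by name (``"M1"``..``"M9"``)."""
    if name not in _REGISTRY:
        raise ValueError(f"unknown model name {name!r}; expected one of {sorted(_REGISTRY)}")
    comps = _REGISTRY[name]
    return ModelSpec(
        name=name,
        specific_clustering="Uk" in comps,
        shared_clustering="U" in comps,
        specific_heterogeneity="Vk" in comps,
        shared_heterogeneity="V" in comps,
    )


@dataclass(frozen=True)
class PriorConfig:
    """Hyperprior constants.

    ``precision_shape``/``precision_rate`` parameterize the Gamma hyperprior on
    every precision (shape-rate convention); ``log_scaling_var`` is the
    variance of the Normal prior on log delta and log omega.  Intercepts are
    improper flat.
    """

    precision_shape: float = 0.5
    precision_rate: float = 0.0005
    log_scaling_var: float = 0.17

    def __post_init__(self) -> None:
        if self.precision_shape <= 0 or self.precision_rate <= 0 or self.log_scaling_var <= 0:
            raise ValueError("prior constants must be positive")


@dataclass
class ModelParams:
    """Current values of all parameters of a model specification.

    Absent components are ``None`` (structurally absent, not zero-filled).
    Field arrays are in the canonical area order of the accompanying graph.
    """

    alpha: dict[str, float]
    specific_clustering: dict[str, np.ndarray] | None = None  # u_ik
    shared_clustering: np.ndarray | None = None  # u_i
    specific_heterogeneity: dict[str, np.ndarray] | None = None  # v_ik
    shared_heterogeneity: np.ndarray | None = None  # v_i
    delta: float | None = None
    omega: float | None = None
    prec_specific_clustering: dict[str, float] | None = None  # lambda_uk
    prec_shared_clustering: float | None = None  # lambda_u
    prec_specific_heterogeneity: dict[str, float] | None = None  # lambda_vk
    prec_shared_heterogeneity: float | None = None  # lambda_v

    def check(self, spec: ModelSpec, n_areas: int) -> None:
        def _chk_field(x, present, label):
            if present:
                if x is None:
                    raise ValueError(f"{label} required by {spec.name} but absent")
                arrs = x.values() if isinstance(x, dict) else [x]
                for a in arrs:
                    if np.asarray(a).shape != (n_areas,):
                        raise ValueError(f"{label}: field length != number of areas")
            elif x is not None:
                raise ValueError(f"{label} present but not part of {spec.name}")

        _chk_field(self.specific_clustering, spec.specific_clustering, "specific clustering")
        _chk_field(self.shared_clustering, spec.shared_clustering, "shared clustering")
        _chk_field(self.specific_heterogeneity, spec.specific_heterogeneity, "specific heterogeneity")
        _chk_field(self.shared_heterogeneity, spec.shared_heterogeneity, "shared heterogeneity")
        if spec.shared_clustering and (self.delta is None or self.delta <= 0):
            raise ValueError("delta must be present and > 0")
        if spec.shared_heterogeneity and (self.omega is None or self.omega <= 0):
            raise ValueError("omega must be present and > 0")


def _shared_scale(value: float, disease: str) -> float:
    """Asymmetric shared-component scaling: x value for P, / value for O."""
    return value if disease == "P" else 1.0 / value


def linear_predictor(
    spec: ModelSpec, params: ModelParams, disease: str, area: int | None = None
):
    """log theta_ik for one disease: intercept plus every present component.

    Shared clustering contributes ``delta * u_i`` for disease P and
    ``u_i / delta`` for disease O; shared heterogeneity analogously via omega.
    With ``area=None`` the full vector over areas is returned.
    """
    if disease not in DISEASES:
        raise ValueError(f"unknown disease {disease!r}")
    sel = slice(None) if area is None else area
    total = np.asarray(params.alpha[disease], dtype=float)
    if spec.shared_clustering:
        if params.delta is None or params.delta <= 0:
            raise ValueError("delta must be > 0")
        total = total + _shared_scale(params.delta, disease) * np.asarray(params.shared_clustering)[sel]
    if spec.specific_clustering:
        total = total + np.asarray(params.specific_clustering[disease])[sel]
    if spec.shared_heterogeneity:
        if params.omega is None or params.omega <= 0:
            raise ValueError("omega must be > 0")
        total = total + _shared_scale(params.omega, disease) * np.asarray(params.shared_heterogeneity)[sel]
    if spec.specific_heterogeneity:
        total = total + np.asarray(params.specific_heterogeneity[disease])[sel]
    return float(total) if area is not None else total


def observation_index(data: BivariateAreaData) -> list[tuple[str, str]]:
    """Fixed observation order: all areas for disease P, then all for disease O.

    Areas with E = 0 are excluded (no information about the relative risk).
    """
    out = []
    for k in DISEASES:
        for i, a in enumerate(data.area_ids):
            if data.expected[k][i] > 0:
                out.append((a, k))
    return out


def pointwise_loglik(spec: ModelSpec, params: ModelParams, data: BivariateAreaData) -> np.ndarray:
    """Poisson log-pmf per observation, in the fixed (P-block then O-block) order."""
    out = []
    for k in DISEASES:
        e = data.expected[k]
        o = data.observed[k]
        if not np.allclose(o, np.round(o)):
            raise ValueError("observed counts must be integers")
        mask = e > 0
        mu = e[mask] * np.exp(linear_predictor(spec, params, k))[mask]
        out.append(stats.poisson.logpmf(o[mask].astype(int), mu))
    return np.concatenate(out)


def _icar_pairwise(field_vals: np.ndarray, graph: AreaGraph) -> float:
    i, j = graph.edge_arrays()
    d = field_vals[i] - field_vals[j]
    return float(d @ d)


def log_prior(
    spec: ModelSpec, params: ModelParams, graph: AreaGraph, priors: PriorConfig = PriorConfig()
) -> float:
    """Joint log prior density (up to the additive constants of improper terms).

    Clustering fields use the intrinsic CAR pairwise-difference form
    ``-lambda/2 * sum_edges (u_i - u_l)^2`` plus the proper normalizing part in
    lambda, ``(n - n_comp)/2 * log lambda``; heterogeneity fields are
    Normal(0, 1/lambda); each precision carries the Gamma hyperprior; log delta
    and log omega are Normal(0, sigma^2); intercepts are flat (contribute 0).
    """
    params.check(spec, graph.n_areas)
    lp = 0.0
    rank = graph.n_areas - graph.n_components()

    def gamma_lp(lam):
        if lam is None or lam <= 0:
            raise ValueError("precision must be > 0")
        return float(stats.gamma.logpdf(lam, priors.precision_shape, scale=1.0 / priors.precision_rate))

    if spec.specific_clustering:
        for k in DISEASES:
            lam = params.prec_specific_clustering[k]
            lp += gamma_lp(lam)
            lp += 0.5 * rank * np.log(lam) - 0.5 * lam * _icar_pairwise(
                np.asarray(params.specific_clustering[k]), graph
            )
    if spec.shared_clustering:
        lam = params.prec_shared_clustering
        lp += gamma_lp(lam)
        lp += 0.5 * rank * np.log(lam) - 0.5 * lam * _icar_pairwise(
            np.asarray(params.shared_clustering), graph
        )
        lp += float(stats.norm.logpdf(np.log(params.delta), 0.0, np.sqrt(priors.log_scaling_var)))
    if spec.specific_heterogeneity:
        for k in DISEASES:
            lam = params.prec_specific_heterogeneity[k]
            lp += gamma_lp(lam)
            v = np.asarray(params.specific_heterogeneity[k])
            lp += float(np.sum(stats.norm.logpdf(v, 0.0, 1.0 / np.sqrt(lam))))
    if spec.shared_heterogeneity:
        lam = params.prec_shared_heterogeneity
        lp += gamma_lp(lam)
        v = np.asarray(params.shared_heterogeneity)
        lp += float(np.sum(stats.norm.logpdf(v, 0.0, 1.0 / np.sqrt(lam))))
        lp += float(stats.norm.logpdf(np.log(params.omega), 0.0, np.sqrt(priors.log_scaling_var)))
    return float(lp)
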