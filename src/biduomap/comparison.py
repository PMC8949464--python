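"""Model support (WAIC) and model robustness (calibrated Kullback-Leibler influence).

WAIC scores a model's pointwise predictive accuracy from MCMC draws:
``WAIC = -2 lppd + 2 p_WAIC`` with the log pointwise predictive density
``lppd = sum_i log mean_k p(y_i | theta^(k))`` and the effective number of
parameters ``p_WAIC = sum_i var_k log p(y_i | theta^(k))``.

Model influence asks a different question: how much would the inferences (the
per-observation posterior of the log relative risk) change if the reference
model were replaced by an alternative?  Approximating each marginal by a
normal, the per-observation discrepancy is the Gaussian Kullback-Leibler
divergence, which is then calibrated on a probability scale by solving
``KL(Bernoulli(0.5), Bernoulli(p)) = c`` for p in [0.5, 1) (McCulloch's
calibration): 0.5 means the alternative changes nothing, values near 1 a gross
revision of beliefs.  The per-model summary is the median calibrated KL over
all observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import logsumexp

from .mcmc import PosteriorDraws
from .spatial import DISEASES

__all__ = [
    "ComparisonRecord",
    "MarginalSummary",
    "waic",
    "normal_approx_marginals",
    "kl_divergence_normal",
    "bernoulli_kl",
    "calibrate_kl",
    "median_calibrated_kl",
    "compare_models",
    "comparison_table",
]


def waic(loglik_draws: np.ndarray) -> tuple[float, float, float]:
    """(WAIC, lppd, p_WAIC) from a (draws x observations) log-likelihood matrix.

    lppd is computed stably through log-sum-exp; p_WAIC uses the K-1 sample
    variance across draws.
    """
    ll = np.asarray(loglik_draws, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a (draws x observations) matrix with >= 2 draws")
    if np.isneginf(ll).any():
        bad = int(np.where(np.isneginf(ll).any(axis=0))[0][0])
        raise ValueError(f"-inf log-likelihood at observation {bad}")
    if not np.isfinite(ll).all():
        raise ValueError("non-finite log-likelihood values")
    k = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(k)))
    p_waic = float(np.sum(ll.var(axis=0, ddof=1)))
    return -2.0 * lppd + 2.0 * p_waic, lppd, p_waic


@dataclass
class MarginalSummary:
    """Normal approximation of per-observation posteriors of log relative risk."""

    obs_index: list[tuple[str, str]]
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape or len(self.obs_index) != self.mean.size:
            raise ValueError("mean/sd/index size mismatch")
        if (self.sd <= 0).any():
            raise ValueError("degenerate (zero-variance) posterior marginal")


def normal_approx_marginals(draws: PosteriorDraws) -> MarginalSummary:
    """Per-observation mean and SD of log theta across pooled post-burn-in draws."""
    if draws.n_chains * draws.n_draws < 10:
        raise ValueError("need >= 10 retained draws")
    pos = {a: i for i, a in enumerate(draws.area_ids)}
    pooled = {k: draws.pooled_log_theta(k) for k in DISEASES}
    means, sds = [], []
    for area, k in draws.obs_index:
        x = pooled[k][:, pos[area]]
        means.append(x.mean())
        sds.append(x.std(ddof=1))
    return MarginalSummary(list(draws.obs_index), np.asarray(means), np.asarray(sds))


def kl_divergence_normal(m0: float, s0: float, m1: float, s1: float):
    """KL(N(m0, s0^2) || N(m1, s1^2)) = 1/2[(m1-m0)^2/s1^2 - 1 + s0^2/s1^2 - log(s0^2/s1^2)].

    Accepts arrays (broadcast elementwise).  Non-negative, zero iff identical.
    """
    m0, s0, m1, s1 = (np.asarray(x, dtype=float) for x in (m0, s0, m1, s1))
    if (s0 <= 0).any() or (s1 <= 0).any():
        raise ValueError("standard deviations must be positive")
    r = s0**2 / s1**2
    out = 0.5 * ((m1 - m0) ** 2 / s1**2 - 1.0 + r - np.log(r))
    return float(out) if out.ndim == 0 else out


def bernoulli_kl(p: float, q: float) -> float:
    """KL(Bernoulli(p) || Bernoulli(q))."""
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")

    def term(a, b):
        return 0.0 if a == 0 else a * np.log(a / b)

    return float(term(p, q) + term(1 - p, 1 - q))


def calibrate_kl(c) -> float | np.ndarray:
    """Calibrated KL: the p in [0.5, 1) with KL(Bernoulli(0.5), Bernoulli(p)) = c.

    KL(B(0.5), B(p)) = 0.5 log(0.5/p) + 0.5 log(0.5/(1-p)); the root is taken
    on the p >= 0.5 branch by bracketed bisection to 1e-10, so the calibration
    is monotone increasing in c with p(0) = 0.5 and p -> 1 as c -> infinity.
    """
    c_arr = np.asarray(c, dtype=float)
    if (c_arr < 0).any():
        raise ValueError("KL divergence must be >= 0")

    def solve(ci: float) -> float:
        if ci == 0:
            return 0.5
        f = lambda p: bernoulli_kl(0.5, p) - ci
        hi = 1.0 - 1e-16
        if f(hi) <= 0:  # c beyond representable tail
            return hi
        return brentq(f, 0.5, hi, xtol=1e-12, rtol=8.9e-16)

    if c_arr.ndim == 0:
        return solve(float(c_arr))
    return np.asarray([solve(float(ci)) for ci in c_arr.ravel()]).reshape(c_arr.shape)


def calibrated_kl_per_observation(
    reference: MarginalSummary, alternative: MarginalSummary
) -> np.ndarray:
    """Calibrated KL of each observation, reference model as the actual belief M0."""
    if reference.obs_index != alternative.obs_index:
        raise ValueError("reference and alternative cover different observation sets")
    kl = kl_divergence_normal(reference.mean, reference.sd, alternative.mean, alternative.sd)
    return np.asarray(calibrate_kl(kl))


def median_calibrated_kl(reference: MarginalSummary, alternative: MarginalSummary) -> float:
    """Median over observations of the calibrated per-observation KL divergences."""
    return float(np.median(calibrated_kl_per_observation(reference, alternative)))


@dataclass
class ComparisonRecord:
    model: str
    description: str
    waic: float
    lppd: float
    p_waic: float
    calibrated_kl_median: float
    calibrated_kl_by_disease: dict[str, float]

    def __post_init__(self) -> None:
        if not np.isclose(self.waic, -2 * self.lppd + 2 * self.p_waic):
            raise ValueError("inconsistent WAIC decomposition")


def compare_models(
    fits: dict[str, PosteriorDraws], reference_name: str
) -> list[ComparisonRecord]:
    """WAIC plus median calibrated KL against the reference, per fitted model.

    All fits must share data and observation order.  The returned list is
    sorted by WAIC (best first); the reference's own calibrated KL is 0.5
    by construction.
    """
    if reference_name not in fits:
        raise ValueError(f"reference model {reference_name!r} not among fits")
    ref_draws = fits[reference_name]
    for name, d in fits.items():
        if d.obs_index != ref_draws.obs_index:
            raise ValueError(f"fit {name!r} has a different observation set than the reference")
    ref = normal_approx_marginals(ref_draws)
    diseases = np.asarray([k for _, k in ref.obs_index])
    records = []
    for name, d in fits.items():
        w, lppd, p_w = waic(d.pooled_loglik())
        alt = normal_approx_marginals(d)
        cal = calibrated_kl_per_observation(ref, alt)
        by_disease = {k: float(np.median(cal[diseases == k])) for k in DISEASES}
        records.append(
            ComparisonRecord(
                model=name,
                description=d.spec.description,
                waic=w,
                lppd=lppd,
                p_waic=p_w,
                calibrated_kl_median=float(np.median(cal)),
                calibrated_kl_by_disease=by_disease,
            )
        )
    return sorted(records, key=lambda r: r.waic)


def comparison_table(records: list[ComparisonRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model": [r.model for r in records],
            "description": [r.description for r in records],
            "waic": [r.waic for r in records],
            "lppd": [r.lppd for r in records],
            "p_waic": [r.p_waic for r in records],
            "calibrated_kl_median": [r.calibrated_kl_median for r in records],
        }
    )
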