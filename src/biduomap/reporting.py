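"""Posterior summaries, exceedance probabilities and residual diagnostics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import PosteriorDraws
from .spatial import BivariateAreaData, DISEASES

__all__ = [
    "AreaPosteriorSummary",
    "posterior_summaries",
    "summary_table",
    "exceedance_probability",
    "pearson_residuals",
]


@dataclass(frozen=True)
class AreaPosteriorSummary:
    """Relative-risk posterior for one area and disease."""

    area_id: str
    disease: str
    rr_median: float
    rr_mean: float
    rr_lower: float  # 2.5%
    rr_upper: float  # 97.5%


def posterior_summaries(draws: PosteriorDraws) -> list[AreaPosteriorSummary]:
    """Per-area relative-risk summaries: exp(log theta) draws pooled over chains,
    summarized by median, mean and the equal-tailed 95% credible interval."""
    out = []
    for k in DISEASES:
        rr = np.exp(draws.pooled_log_theta(k))
        med = np.median(rr, axis=0)
        mean = rr.mean(axis=0)
        lo, hi = np.percentile(rr, [2.5, 97.5], axis=0)
        for i, a in enumerate(draws.area_ids):
            out.append(AreaPosteriorSummary(a, k, float(med[i]), float(mean[i]), float(lo[i]), float(hi[i])))
    return out


def summary_table(summaries: list[AreaPosteriorSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "area_id": [s.area_id for s in summaries],
            "disease": [s.disease for s in summaries],
            "rr_median": [s.rr_median for s in summaries],
            "rr_mean": [s.rr_mean for s in summaries],
            "rr_lower95": [s.rr_lower for s in summaries],
            "rr_upper95": [s.rr_upper for s in summaries],
        }
    )


def exceedance_probability(
    draws: PosteriorDraws, component: str = "shared_clustering", threshold: float = 0.0
) -> np.ndarray:
    """Per-area posterior probability that a latent component exceeds ``threshold``.

    The headline use is Prob(U > 0): the posterior probability of direction of
    the shared clustering component, mapping areas where the latent shared risk
    factor elevates both diseases.
    """
    if component not in draws.fields:
        raise ValueError(
            f"component {component!r} not part of model {draws.spec.name} "
            f"(available: {sorted(draws.fields)})"
        )
    pooled = draws.pooled_field(component)
    return (pooled > threshold).mean(axis=0)


def pearson_residuals(data: BivariateAreaData, draws: PosteriorDraws) -> pd.DataFrame:
    """Pearson residuals (O - mu)/sqrt(mu) with mu = E x posterior-mean RR.

    Residuals with |r| > 2 are flagged as extreme; areas with mu = 0 (zero
    expected count) are excluded with a flag instead of dividing.
    """
    rows = []
    for k in DISEASES:
        rr_mean = np.exp(draws.pooled_log_theta(k)).mean(axis=0)
        mu = data.expected[k] * rr_mean
        for i, a in enumerate(data.area_ids):
            if mu[i] > 0:
                r = (data.observed[k][i] - mu[i]) / np.sqrt(mu[i])
                rows.append((a, k, data.observed[k][i], mu[i], r, abs(r) > 2, False))
            else:
                rows.append((a, k, data.observed[k][i], mu[i], np.nan, False, True))
    return pd.DataFrame(
        rows,
        columns=["area_id", "disease", "observed", "fitted", "pearson_residual", "extreme", "excluded"],
    )
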