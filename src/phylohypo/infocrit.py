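"""Model comparison by the size-corrected Akaike information criterion.

For a fitted model i with maximized log-likelihood logL_i, K free parameters
and sample size n (alignment columns):

    AIC_i  = -2 logL_i + 2 K
    AICc_i = AIC_i + 2 K (K + 1) / (n - K - 1)
    dAICc_i = AICc_i - min_j AICc_j
    w_i    = exp(-dAICc_i / 2) / sum_j exp(-dAICc_j / 2)

The small-sample correction matters whenever n / K < 40, which is the usual
regime for constrained phylogenetic fits where K counts every branch length.
Weights are computed in log space so comparisons remain stable when dAICc
runs into the hundreds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "ModelFit",
    "aic",
    "aicc",
    "akaike_weights",
    "weights_from_delta",
    "small_sample_flag",
]


@dataclass(frozen=True)
class ModelFit:
    """Maximum-likelihood fit summary for one hypothesis/model."""

    model_name: str
    log_likelihood: float
    n_params: int
    n_sites: int

    def __post_init__(self):
        if self.n_params < 0:
            raise ValueError("n_params must be non-negative")
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")


def aic(fit: ModelFit) -> float:
    """Akaike information criterion, -2 logL + 2K."""
    return -2.0 * fit.log_likelihood + 2.0 * fit.n_params


def aicc(fit: ModelFit) -> float:
    """Size-corrected AIC, AIC + 2K(K+1)/(n-K-1); needs n > K + 1."""
    if fit.n_sites <= fit.n_params + 1:
        raise ValueError(
            f"AICc undefined for {fit.model_name!r}: "
            f"n={fit.n_sites} <= K+1={fit.n_params + 1}"
        )
    k = fit.n_params
    return aic(fit) + 2.0 * k * (k + 1) / (fit.n_sites - k - 1)


def small_sample_flag(fit: ModelFit) -> bool:
    """True when n/K < 40, i.e. AICc rather than AIC should be reported."""
    if fit.n_params <= 0:
        raise ValueError("n_params must be positive for the n/K rule")
    return fit.n_sites / fit.n_params < 40


def weights_from_delta(delta: np.ndarray) -> np.ndarray:
    """Akaike weights from dAICc values, normalized in log space."""
    delta = np.asarray(delta, dtype=float)
    log_w = -delta / 2.0
    return np.exp(log_w - logsumexp(log_w))


def akaike_weights(fits: list) -> pd.DataFrame:
    """Full AIC/AICc comparison table for a set of model fits.

    Returns one row per model with AIC, AICc, dAICc (relative to the best,
    i.e. lowest, AICc), the Akaike weight, and the n/K small-sample flag;
    ``best`` marks the minimum-AICc row.
    """
    if not fits:
        raise ValueError("at least one model fit is required")
    rows = []
    for fit in fits:
        rows.append(
            {
                "model": fit.model_name,
                "logL": fit.log_likelihood,
                "K": fit.n_params,
                "n": fit.n_sites,
                "AIC": aic(fit),
                "AICc": aicc(fit),
                "small_sample": small_sample_flag(fit) if fit.n_params else True,
            }
        )
    table = pd.DataFrame(rows)
    table["delta_AICc"] = table["AICc"] - table["AICc"].min()
    table["weight"] = weights_from_delta(table["delta_AICc"].to_numpy())
    table["best"] = table["AICc"] == table["AICc"].min()
    return table
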