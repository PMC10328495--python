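"""Bayes factors from run-level stepping-stone log marginal likelihoods.

Stepping-stone (or path-sampling) estimators are usually run in independent
replicates; the replicate log marginals ln P(X|M) are combined here by
averaging on the likelihood scale, i.e. log-mean-exp:

    combined = ln( (1/R) * sum_r exp(v_r) )

computed stably relative to max(v_r). Note this is *not* the arithmetic mean
of the logs: the combined value is always within [max - ln R, max] and is
dominated by the best run, which is the desired behaviour for averaging
likelihoods. The Bayes factor of M0 against M1 is e to the difference of
combined log marginals, and evidence is banded on the conventional
2 ln(BF) scale: 0-2 negligible, 2-6 positive, 6-10 strong, >10 very strong,
mirrored with "... against M0" for negative values; band edges belong to the
stronger category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "MarginalRunSet",
    "BayesFactorResult",
    "combine_log_marginals",
    "bayes_factor",
    "interpret_evidence",
]


@dataclass(frozen=True)
class MarginalRunSet:
    """Per-run log marginal likelihoods for one model."""

    model_name: str
    run_log_marginals: tuple

    def __post_init__(self):
        vals = tuple(float(v) for v in self.run_log_marginals)
        if not vals:
            raise ValueError("at least one run is required")
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("run log marginals must be finite")
        object.__setattr__(self, "run_log_marginals", vals)

    @property
    def combined_log_marginal(self) -> float:
        return combine_log_marginals(self.run_log_marginals)


def combine_log_marginals(values) -> float:
    """Combine replicate log marginals by the log of the mean likelihood."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("no run values supplied")
    if not np.all(np.isfinite(vals)):
        raise ValueError("run log marginals must be finite")
    return float(logsumexp(vals) - math.log(vals.size))


@dataclass(frozen=True)
class BayesFactorResult:
    """BF of M0 vs M1 kept on the log scale alongside a base-10 rendering."""

    ln_bf: float

    @property
    def bf(self) -> float:
        # may over/underflow to inf/0 for |ln_bf| > ~709; use mantissa/exponent
        # for serialization of extreme values
        return math.exp(self.ln_bf) if abs(self.ln_bf) < 700 else (
            math.inf if self.ln_bf > 0 else 0.0
        )

    @property
    def log10_bf(self) -> float:
        return self.ln_bf / math.log(10.0)

    @property
    def mantissa_exponent(self) -> tuple:
        """(m, e) with BF = m * 10**e, 1 <= m < 10; survives 1e-94 scales."""
        exponent = math.floor(self.log10_bf)
        mantissa = 10.0 ** (self.log10_bf - exponent)
        return mantissa, exponent

    @property
    def category(self) -> str:
        return interpret_evidence(self.ln_bf)

    def scientific(self, sig: int = 2) -> str:
        m, e = self.mantissa_exponent
        m = round(m, sig - 1)
        if m >= 10.0:  # rounding spill, e.g. 9.97 -> 10.0
            m, e = m / 10.0, e + 1
        return f"{m:g}e{e:+d}"


def bayes_factor(ln_ml_m0: float, ln_ml_m1: float) -> BayesFactorResult:
    """Bayes factor P(X|M0)/P(X|M1) = exp(ln_ml_m0 - ln_ml_m1)."""
    if not (math.isfinite(ln_ml_m0) and math.isfinite(ln_ml_m1)):
        raise ValueError("log marginal likelihoods must be finite")
    return BayesFactorResult(ln_bf=ln_ml_m0 - ln_ml_m1)


_BANDS = [(2.0, "negligible"), (6.0, "positive"), (10.0, "strong")]


def interpret_evidence(ln_bf: float) -> str:
    """Band 2 ln(BF) on the conventional evidence scale.

    Positive values are evidence for M0, negative for M1 ("... against M0");
    a value exactly on a band edge takes the stronger label.
    """
    two_ln = 2.0 * ln_bf
    magnitude = abs(two_ln)
    label = "very strong"
    for edge, name in _BANDS:
        if magnitude < edge:
            label = name
            break
    if label == "negligible":
        return "negligible"
    side = "for M0" if two_ln > 0 else "against M0"
    return f"{label} evidence {side}"
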