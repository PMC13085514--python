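"""Convert Gaussian log10 half-life distributions into REACH persistence
probabilities and confidence categories.

For a threshold T (days) the exceedance probability is

    p(log DT50 >= log T) = 1 - Phi((log10(T) - mu) / sd)

with Phi the standard normal CDF. p(P) uses T = 120 d, p(vP) uses
T = 180 d, and p(nP) = 1 - p(P).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

from scipy.stats import norm

from .bayes_halflife import HalfLifeDistribution
from .prob_models import PredictiveDistribution

#: predicted-SD cutoffs for confidence categories (log10 days)
GOOD_SD_THRESHOLD = 0.5
ACCEPTABLE_SD_THRESHOLD = 0.7


@dataclass(frozen=True)
class RegulatoryThresholds:
    """Half-life thresholds in days; defaults are the REACH soil values."""

    T_P: float = 120.0
    T_vP: float = 180.0

    def __post_init__(self):
        if not (self.T_vP > self.T_P > 0):
            raise ValueError("thresholds must satisfy T_vP > T_P > 0")


@dataclass(frozen=True)
class PersistenceAssessment:
    """Probabilities of the REACH persistence classes plus a confidence
    category derived from the distribution's SD."""

    p_nP: float
    p_P: float
    p_vP: float
    confidence: str  # good | acceptable | low
    source: str      # bayesian | predicted

    def __post_init__(self):
        if abs(self.p_nP + self.p_P - 1.0) > 1e-12:
            raise ValueError("p_nP + p_P must equal 1")
        if not (0.0 <= self.p_vP <= self.p_P + 1e-12):
            raise ValueError("need 0 <= p_vP <= p_P")

    def as_percent(self) -> tuple[int, int, int]:
        """(p_nP, p_P, p_vP) as integer percents, rounded half-up."""
        return (
            round_percent(self.p_nP),
            round_percent(self.p_P),
            round_percent(self.p_vP),
        )


def round_percent(p: float) -> int:
    """Round a probability to an integer percent with half-up ties."""
    return int(math.floor(100.0 * p + 0.5))


def exceedance_probability(mu: float, sd: float, T_days: float) -> float:
    """Probability that log10 DT50 >= log10(T_days) under Normal(mu, sd^2).

    Raises a domain error for sd <= 0; use the point classifier
    (:func:`soildt50.bayes_halflife.classify_with_ci`) for degenerate SDs.
    """
    if sd <= 0:
        raise ValueError(f"sd must be > 0 (got {sd}); use the point-rule classifier")
    if T_days <= 0:
        raise ValueError("T_days must be > 0")
    return float(norm.sf((math.log10(T_days) - mu) / sd))


def confidence_category(sd: float) -> str:
    """'good' if sd < 0.5, 'acceptable' if 0.5 <= sd < 0.7, else 'low'."""
    if sd < GOOD_SD_THRESHOLD:
        return "good"
    if sd < ACCEPTABLE_SD_THRESHOLD:
        return "acceptable"
    return "low"


def assess(
    dist: Union[PredictiveDistribution, HalfLifeDistribution],
    thresholds: RegulatoryThresholds = RegulatoryThresholds(),
) -> PersistenceAssessment:
    """Persistence assessment for a Bayesian or model-predicted
    distribution. The confidence rule is identical for both sources."""
    if isinstance(dist, HalfLifeDistribution):
        mu, sd, source = dist.mu_mean, dist.mu_std, "bayesian"
    else:
        mu, sd, source = dist.pred_mean, dist.pred_std, "predicted"
    p_P = exceedance_probability(mu, sd, thresholds.T_P)
    p_vP = exceedance_probability(mu, sd, thresholds.T_vP)
    return PersistenceAssessment(
        p_nP=1.0 - p_P,
        p_P=p_P,
        p_vP=p_vP,
        confidence=confidence_category(sd),
        source=source,
    )
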