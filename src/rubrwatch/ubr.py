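"""Per-category beta-binomial model for UBR membership.

Each UBR category ``u`` is modeled independently: the indicator that a
subject belongs to the category is Bernoulli(p^u), so the aggregated count
among ``m`` enrollees is Binomial(m, p^u).  The conjugate prior is
``p^u ~ Beta(alpha, beta)`` with ``alpha = p0 * n * P`` (prior successes)
and ``beta = (1 - p0) * n * P`` (prior failures), sharing the global
confidence ``P`` with the accrual prior.  The posterior after observing
``S_m`` successes among ``m`` is ``Beta(alpha + S_m, beta + m - S_m)``.

Future counts over a remaining sample size are drawn by sampling one
``p_j`` per prediction draw and then a Binomial; with the remaining size
held fixed this is exactly the beta-binomial distribution, which serves as
the closed-form oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import stats

from .design import CategorySpec, TrialDesign
from .exceptions import ImproperPosteriorError, ValidationError

__all__ = [
    "BetaParams",
    "build_ubr_prior",
    "update_ubr_posterior",
    "draw_future_counts",
    "fixed_n_betabinomial_pmf",
]

SeedLike = Union[None, int, np.random.SeedSequence, np.random.Generator]


@dataclass(frozen=True)
class BetaParams:
    """Beta(alpha, beta) prior or posterior for a category rate.

    Zero parameters are allowed at construction (the flat-prior limit
    ``P = 0`` gives Beta(0, 0)); sampling requires a proper distribution,
    checked via :attr:`is_proper`.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValidationError("alpha and beta must be >= 0")

    @property
    def is_proper(self) -> bool:
        return self.alpha > 0 and self.beta > 0

    @property
    def mean(self) -> float:
        if self.alpha + self.beta == 0:
            return float("nan")
        return self.alpha / (self.alpha + self.beta)

    def require_proper(self, context: str = "") -> "BetaParams":
        if not self.is_proper:
            raise ImproperPosteriorError(
                f"improper Beta({self.alpha}, {self.beta})"
                + (f" for {context}" if context else "")
                + "; with a flat prior (P = 0) both observed successes and "
                "failures are required. If the elicited p0 is 0 or 1, nudge "
                "it slightly into (0, 1) rather than relying on silent "
                "regularization."
            )
        return self


def build_ubr_prior(category: CategorySpec, design: TrialDesign) -> BetaParams:
    """Beta prior with alpha = p0*n*P successes and beta = (1-p0)*n*P failures."""
    npp = design.n_target * design.confidence_P
    return BetaParams(
        alpha=category.prior_rate_p0 * npp,
        beta=(1.0 - category.prior_rate_p0) * npp,
    )


def update_ubr_posterior(prior: BetaParams, m: int, S_m: int) -> BetaParams:
    """Conjugate update Beta(alpha + S_m, beta + m - S_m); must be proper."""
    if not 0 <= S_m <= m:
        raise ValidationError(f"need 0 <= S_m <= m, got S_m={S_m}, m={m}")
    post = BetaParams(alpha=prior.alpha + S_m, beta=prior.beta + (m - S_m))
    return post.require_proper("posterior")


def draw_future_counts(
    posterior: BetaParams,
    remaining: np.ndarray,
    seed: SeedLike = None,
) -> np.ndarray:
    """Predictive draws of the future category count.

    For each entry ``remaining[j]`` (the not-yet-enrolled sample size of the
    j-th accrual draw), one rate ``p_j ~ Beta(alpha, beta)`` is drawn and
    then ``S_j ~ Binomial(remaining[j], p_j)``.  Drawing a fresh ``p_j`` per
    accrual draw propagates the parameter uncertainty into the prediction.
    The p vector is drawn first, then the binomial vector.
    """
    posterior.require_proper()
    remaining = np.asarray(remaining, dtype=np.int64)
    if (remaining < 0).any():
        raise ValidationError("remaining sample sizes must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = rng.beta(posterior.alpha, posterior.beta, size=remaining.shape)
    return rng.binomial(remaining, p)


def fixed_n_betabinomial_pmf(posterior: BetaParams, remaining_n: int):
    """Closed-form beta-binomial predictive for a *fixed* remaining size.

    Returns a frozen scipy ``betabinom(remaining_n, alpha, beta)``; its pmf
    over {0..remaining_n} sums to 1 and has mean
    ``remaining_n * alpha / (alpha + beta)``.  For ``remaining_n = 0`` it is
    a point mass at zero.
    """
    posterior.require_proper()
    if remaining_n < 0:
        raise ValidationError("remaining_n must be >= 0")
    return stats.betabinom(remaining_n, posterior.alpha, posterior.beta)
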