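"""Exponential waiting-time accrual model.

Waiting times between enrollments, ``w_i = t_i - t_{i-1}``, are i.i.d.
exponential with mean ``theta``.  The conjugate prior is inverse-gamma,
``theta ~ IG(k, V)`` with ``k = n P`` and ``V = T P`` where ``P`` is the
researcher's prior confidence.  Parameterization: IG(A, B) has density
proportional to ``theta^-(A+1) exp(-B/theta)`` (shape-scale; the reciprocal
``1/theta`` is Gamma with shape A and rate B), so the posterior mean of
theta is ``B/(A-1)`` for ``A > 1``.

After observing ``m`` enrollments over time ``t_m`` the posterior is
``IG(A, B)`` with ``A = k + m`` and ``B = V + t_m``.  The posterior
predictive number of *additional* enrollments in a remaining budget ``L``
is Poisson(L/theta) mixed over the inverse-gamma posterior, which is
exactly negative binomial with size ``A`` and success probability
``B/(B + L)`` — the closed-form oracle that the Monte-Carlo sampler is
tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Union

import numpy as np
from scipy import stats

from .design import InterimData, TrialDesign
from .exceptions import ImproperPosteriorError, ValidationError

__all__ = [
    "AccrualPrior",
    "AccrualPosterior",
    "AccrualPrediction",
    "build_accrual_prior",
    "update_accrual_posterior",
    "draw_predicted_sample_sizes",
    "predictive_count_pmf",
]

SeedLike = Union[None, int, np.random.SeedSequence, np.random.Generator]


@dataclass(frozen=True)
class AccrualPrior:
    """Inverse-gamma prior IG(k, V) for the mean waiting time.

    ``shape_k = n P`` acts as a prior count of enrollments, ``scale_V = T P``
    as a prior total waiting time; both are zero iff ``P = 0`` (flat prior).
    """

    shape_k: float
    scale_V: float

    def __post_init__(self) -> None:
        if self.shape_k < 0 or self.scale_V < 0:
            raise ValidationError("prior shape and scale must be >= 0")


@dataclass(frozen=True)
class AccrualPosterior:
    """Proper inverse-gamma posterior IG(A, B) for the mean waiting time."""

    shape_A: float
    scale_B: float

    def __post_init__(self) -> None:
        if self.shape_A <= 0 or self.scale_B <= 0:
            raise ImproperPosteriorError(
                "accrual posterior requires shape_A > 0 and scale_B > 0; "
                "a flat prior (P = 0) with no enrollments yet gives no "
                "information about the accrual rate"
            )

    @property
    def mean(self) -> float:
        """Posterior mean of theta, B/(A-1); NaN if A <= 1."""
        if self.shape_A <= 1:
            return float("nan")
        return self.scale_B / (self.shape_A - 1)

    def draw_theta(self, rng: np.random.Generator, size: int) -> np.ndarray:
        # 1/theta ~ Gamma(shape=A, rate=B)
        return self.scale_B / rng.gamma(self.shape_A, size=size)


@dataclass(frozen=True)
class AccrualPrediction:
    """Posterior-predictive draws of the total sample size at the horizon.

    ``draws[j]`` is ``n_j^p = m + (additional enrollments that fit in the
    remaining budget)``; every draw is therefore at least
    ``m_at_prediction``.
    """

    draws: np.ndarray
    m_at_prediction: int
    seed: object = None
    mean: float = field(init=False)
    median: float = field(init=False)
    ci95: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        draws = np.asarray(self.draws, dtype=np.int64)
        if draws.size < 1:
            raise ValidationError("prediction requires at least one draw")
        if (draws < self.m_at_prediction).any():
            raise ValidationError("predicted totals cannot fall below m")
        object.__setattr__(self, "draws", draws)
        object.__setattr__(self, "mean", float(draws.mean()))
        object.__setattr__(self, "median", float(np.median(draws)))
        lo, hi = np.percentile(draws, [2.5, 97.5])
        object.__setattr__(self, "ci95", (float(lo), float(hi)))

    @property
    def s(self) -> int:
        return int(self.draws.size)


def build_accrual_prior(design: TrialDesign) -> AccrualPrior:
    """Prior IG(k, V) with k = n_target * P and V = horizon_T * P."""
    return AccrualPrior(
        shape_k=design.n_target * design.confidence_P,
        scale_V=design.horizon_T * design.confidence_P,
    )


def update_accrual_posterior(
    prior: AccrualPrior, interim: InterimData
) -> AccrualPosterior:
    """Conjugate update: A = k + m, B = V + t_m."""
    return AccrualPosterior(
        shape_A=prior.shape_k + interim.m,
        scale_B=prior.scale_V + interim.t_m,
    )


def _as_generator(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _count_sequential(
    rng: np.random.Generator, theta: np.ndarray, budget: float
) -> np.ndarray:
    """Count exponential waiting times whose cumulative sum stays <= budget.

    Vectorized over draws: each pass appends one waiting time to every
    still-active draw.
    """
    s = theta.shape[0]
    counts = np.zeros(s, dtype=np.int64)
    totals = np.zeros(s)
    active = np.ones(s, dtype=bool)
    while active.any():
        idx = np.flatnonzero(active)
        w = rng.exponential(theta[idx])
        totals[idx] += w
        within = totals[idx] <= budget
        counts[idx[within]] += 1
        active[idx[~within]] = False
    return counts


def draw_predicted_sample_sizes(
    posterior: AccrualPosterior,
    interim: InterimData,
    horizon_T: float,
    s: int = 10_000,
    seed: SeedLike = None,
    method: Literal["poisson", "sequential"] = "poisson",
) -> AccrualPrediction:
    """Monte-Carlo posterior-predictive draws of the total sample size.

    For each of ``s`` draws, a mean waiting time ``theta_j`` is drawn from
    the IG(A, B) posterior and the number of additional enrollments that fit
    in the remaining budget ``max(0, T - t_m)`` is counted.  ``method``
    selects how the count is generated:

    * ``"poisson"`` (default) — one Poisson(L/theta_j) draw, exploiting the
      renewal/Poisson-process identity;
    * ``"sequential"`` — literal counting of exponential waiting times whose
      partial sums stay within the budget.

    The two are distributionally identical.  A fixed seed reproduces the
    draw vector bit-for-bit: the theta vector is drawn first, then the count
    vector.
    """
    if horizon_T <= 0:
        raise ValidationError("horizon_T must be > 0")
    if s < 1:
        raise ValidationError("s must be >= 1")
    rng = _as_generator(seed)
    budget = max(0.0, horizon_T - interim.t_m)
    if budget == 0.0:
        counts = np.zeros(s, dtype=np.int64)
    else:
        theta = posterior.draw_theta(rng, s)
        if method == "poisson":
            counts = rng.poisson(budget / theta)
        elif method == "sequential":
            counts = _count_sequential(rng, theta, budget)
        else:  # pragma: no cover - defensive
            raise ValidationError(f"unknown method {method!r}")
    return AccrualPrediction(
        draws=interim.m + counts, m_at_prediction=interim.m, seed=seed
    )


def predictive_count_pmf(posterior: AccrualPosterior, remaining_budget_L: float):
    """Exact marginal distribution of the additional enrollment count.

    Poisson(L/theta) mixed over theta ~ IG(A, B) is negative binomial with
    size A and success probability ``B/(B + L)`` (mean ``L*A/B``).  For
    ``L = 0`` this degenerates to a point mass at zero (``p = 1``).  Returns
    a frozen scipy distribution with ``pmf``/``cdf``/``mean`` methods.
    """
    if remaining_budget_L < 0:
        raise ValidationError("remaining budget must be >= 0")
    B = posterior.scale_B
    p = B / (B + remaining_budget_L)
    return stats.nbinom(posterior.shape_A, p)
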