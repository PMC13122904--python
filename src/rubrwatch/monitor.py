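"""Joint accrual + rUBR monitoring.

Couples the exponential-waiting-time accrual model with the per-category
beta-binomial model into paired posterior-predictive draws.  For each draw
``j``:

1. a total sample size ``n_j^p`` is drawn from the accrual predictive;
2. for every category ``u``, a future count is drawn on the remaining
   ``n_j^p - m`` subjects and added to the observed count ``S_m^u``;
3. the combined rate is ``rUBR_j^p = sum_u S^u_{n_j^p} / n_j^p``.

Because aggregated counts cannot record cross-category overlap, the
combined rUBR is a sum of proportions and may exceed 1 when overlap is
heavy; draws above 1 trigger an :class:`~rubrwatch.exceptions.OverlapWarning`
and are never clamped.

The statsmodels-style entry point is :class:`AccrualUBRMonitor` (model)
whose :meth:`~AccrualUBRMonitor.fit` returns :class:`AccrualUBRResults`
carrying the draws, posteriors, summaries and meeting probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import accrual as _accrual
from . import ubr as _ubr
from .design import FinalCounts, InterimData, TrialDesign, validate_interims_ordered
from .exceptions import ImproperPosteriorError, OverlapWarning, ValidationError

__all__ = [
    "JointPrediction",
    "predict_joint",
    "final_rubr",
    "prob_meeting",
    "summarize_interims",
    "AccrualUBRMonitor",
    "AccrualUBRResults",
]

SeedLike = Union[None, int, np.random.SeedSequence, np.random.Generator]


def _summary(x: np.ndarray) -> dict:
    lo, hi = np.percentile(x, [2.5, 97.5])
    return {
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "ci95": (float(lo), float(hi)),
    }


@dataclass(frozen=True)
class JointPrediction:
    """Paired posterior-predictive draws of sample size, counts and rUBR."""

    sample_size_draws: np.ndarray
    category_total_draws: Mapping[str, np.ndarray]
    rubr_draws: np.ndarray
    m_at_prediction: int
    seed: object = None

    def __post_init__(self) -> None:
        n = np.asarray(self.sample_size_draws, dtype=np.int64)
        object.__setattr__(self, "sample_size_draws", n)
        object.__setattr__(
            self,
            "category_total_draws",
            {k: np.asarray(v, dtype=np.int64) for k, v in self.category_total_draws.items()},
        )
        object.__setattr__(self, "rubr_draws", np.asarray(self.rubr_draws, dtype=float))
        if not (len(self.rubr_draws) == len(n)):
            raise ValidationError("draw vectors must have equal length")

    @property
    def s(self) -> int:
        return int(self.sample_size_draws.size)

    @property
    def sample_size_summary(self) -> dict:
        return _summary(self.sample_size_draws)

    @property
    def rubr_summary(self) -> dict:
        return _summary(self.rubr_draws)

    def category_summary(self, label: str) -> dict:
        return _summary(self.category_total_draws[label])


def predict_joint(
    design: TrialDesign,
    interim: InterimData,
    s: int = 10_000,
    seed: SeedLike = None,
    method: Literal["poisson", "sequential"] = "poisson",
) -> JointPrediction:
    """Joint posterior-predictive simulation at one monitoring look.

    One seeded generator drives the whole call: the accrual draws come
    first, then each category's draws in design order, so a fixed seed
    reproduces the prediction exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    prior = _accrual.build_accrual_prior(design)
    posterior = _accrual.update_accrual_posterior(prior, interim)
    acc = _accrual.draw_predicted_sample_sizes(
        posterior, interim, design.horizon_T, s=s, seed=rng, method=method
    )
    n_draws = acc.draws
    remaining = n_draws - interim.m

    totals: dict[str, np.ndarray] = {}
    rubr = np.zeros(s, dtype=float)
    # guard the m = 0 division: with no data and no budget there is nothing
    # to predict (the accrual update has already raised if also P = 0)
    safe_n = np.maximum(n_draws, 1)
    for cat in design.categories:
        cat_prior = _ubr.build_ubr_prior(cat, design)
        cat_post = _ubr.update_ubr_posterior(cat_prior, interim.m, interim.count(cat.label))
        future = _ubr.draw_future_counts(cat_post, remaining, seed=rng)
        total = interim.count(cat.label) + future
        totals[cat.label] = total
        rubr += total / safe_n

    if (rubr > 1.0).any():
        warnings.warn(
            "combined rUBR draws exceed 1: aggregated counts double-count "
            "subjects belonging to several UBR categories",
            OverlapWarning,
            stacklevel=2,
        )
    return JointPrediction(
        sample_size_draws=n_draws,
        category_total_draws=totals,
        rubr_draws=rubr,
        m_at_prediction=interim.m,
        seed=seed if not isinstance(seed, np.random.Generator) else None,
    )


def final_rubr(final: FinalCounts) -> float:
    """Observed final rUBR: the sum over categories of ``n_f^u / n_f``.

    Full precision is returned; display rounds to three decimals.
    """
    return float(sum(final.counts.values()) / final.n_f)


def prob_meeting(
    prediction: JointPrediction, n_target: int, rubr_target: float
) -> tuple[float, float]:
    """Proportions of draws meeting the targets (ties count as meeting).

    Returns ``(p_accrual, p_rubr)`` where ``p_accrual`` is the fraction of
    draws with ``n_j^p >= n_target`` and ``p_rubr`` the fraction with
    ``rUBR_j^p >= rubr_target``.
    """
    if prediction.s < 1:
        raise ValidationError("empty prediction")
    p_acc = float(np.mean(prediction.sample_size_draws >= n_target))
    p_rubr = float(np.mean(prediction.rubr_draws >= rubr_target))
    return p_acc, p_rubr


def summarize_interims(
    design: TrialDesign,
    interims: Sequence[InterimData],
    s: int = 10_000,
    seed: SeedLike = None,
    method: Literal["poisson", "sequential"] = "poisson",
) -> pd.DataFrame:
    """Interim report table: one row per look.

    Columns give the median (default point estimate; the predictive
    sample-size distribution is skewed) and mean, with the equal-tailed 95%
    credible interval, for the predicted sample size and rUBR, plus the
    probabilities of meeting the design targets where set.  Per-look seeds
    are spawned deterministically from ``seed``.
    """
    validate_interims_ordered(list(interims))
    children = np.random.SeedSequence(seed).spawn(len(interims))
    rows = []
    for i, (interim, child) in enumerate(zip(interims, children), start=1):
        pred = predict_joint(design, interim, s=s, seed=np.random.default_rng(child), method=method)
        nsum = pred.sample_size_summary
        rsum = pred.rubr_summary
        row = {
            "interim": i,
            "m": interim.m,
            "t_m": interim.t_m,
            "n_median": nsum["median"],
            "n_mean": nsum["mean"],
            "n_lo": nsum["ci95"][0],
            "n_hi": nsum["ci95"][1],
            "rubr_median": rsum["median"],
            "rubr_mean": rsum["mean"],
            "rubr_lo": rsum["ci95"][0],
            "rubr_hi": rsum["ci95"][1],
        }
        p_acc, p_rubr = prob_meeting(
            pred,
            design.n_target,
            design.rubr_target if design.rubr_target is not None else np.nan,
        )
        row["p_accrual"] = p_acc
        row["p_rubr"] = p_rubr if design.rubr_target is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


class AccrualUBRMonitor:
    """Joint accrual/rUBR model for one trial at one (or more) interim looks.

    Parameters
    ----------
    design : TrialDesign
        Planned sample size, horizon, prior confidence and UBR categories.
    interim : InterimData
        Aggregated observed data at the monitoring look.

    Examples
    --------
    >>> from rubrwatch import TrialDesign, CategorySpec, InterimData
    >>> design = TrialDesign(1355, 48.0, 0.3,
    ...                      (CategorySpec("NW", 0.45), CategorySpec("H", 0.15)))
    >>> interim = InterimData(m=300, t_m=12.0, counts={"NW": 90, "H": 60})
    >>> res = AccrualUBRMonitor(design, interim).fit(draws=10_000, seed=7)
    >>> res.prediction.s
    10000
    """

    def __init__(self, design: TrialDesign, interim: InterimData):
        self.design = design
        self.interim = interim
        self.accrual_prior = _accrual.build_accrual_prior(design)
        self.ubr_priors = {
            c.label: _ubr.build_ubr_prior(c, design) for c in design.categories
        }

    @classmethod
    def from_enrollment(
        cls, log, design: TrialDesign, at_time: Optional[float] = None
    ) -> "AccrualUBRMonitor":
        """Build the monitor from a subject-level enrollment log.

        ``at_time`` defaults to the last enrollment time in the log.
        """
        from .synthetic import aggregate_at

        if at_time is None:
            at_time = float(log.frame["enroll_time"].iloc[-1]) if len(log.frame) else 0.0
        return cls(design, aggregate_at(log, at_time))

    def fit(
        self,
        draws: int = 10_000,
        seed: SeedLike = None,
        method: Literal["poisson", "sequential"] = "poisson",
    ) -> "AccrualUBRResults":
        """Update the posteriors and run the joint predictive simulation."""
        posterior = _accrual.update_accrual_posterior(self.accrual_prior, self.interim)
        ubr_posteriors = {
            label: _ubr.update_ubr_posterior(
                prior, self.interim.m, self.interim.count(label)
            )
            for label, prior in self.ubr_priors.items()
        }
        prediction = predict_joint(
            self.design, self.interim, s=draws, seed=seed, method=method
        )
        # keep only serializable seed tokens in the results record
        seed_token = seed if isinstance(seed, (int, type(None))) else None
        return AccrualUBRResults(
            model=self,
            accrual_posterior=posterior,
            ubr_posteriors=ubr_posteriors,
            prediction=prediction,
            seed=seed_token,
            method=method,
        )


@dataclass
class AccrualUBRResults:
    """Fitted posteriors and posterior-predictive draws for one look."""

    model: AccrualUBRMonitor
    accrual_posterior: _accrual.AccrualPosterior
    ubr_posteriors: Mapping[str, _ubr.BetaParams]
    prediction: JointPrediction
    seed: object = None
    method: str = "poisson"

    def prob_meeting(
        self,
        n_target: Optional[int] = None,
        rubr_target: Optional[float] = None,
    ) -> tuple[float, float]:
        """Meeting probabilities against explicit or design targets."""
        design = self.model.design
        if n_target is None:
            n_target = design.n_target
        if rubr_target is None:
            rubr_target = design.rubr_target
        if rubr_target is None:
            raise ValidationError("no rUBR target set in the design or the call")
        return prob_meeting(self.prediction, n_target, rubr_target)

    def summary(self) -> str:
        """Human-readable interim report (sample sizes as integers,
        rates to three decimals)."""
        design = self.model.design
        interim = self.model.interim
        pred = self.prediction
        nsum = pred.sample_size_summary
        rsum = pred.rubr_summary
        lines = [
            "Accrual & rUBR interim prediction",
            "=" * 49,
            f"design: n_target={design.n_target}, T={design.horizon_T:g}, "
            f"P={design.confidence_P:g}",
            f"observed: m={interim.m}, t_m={interim.t_m:g}",
            f"accrual posterior: IG(A={self.accrual_posterior.shape_A:g}, "
            f"B={self.accrual_posterior.scale_B:g})",
            f"draws: s={pred.s}",
            "-" * 49,
            f"predicted sample size: {nsum['median']:.0f} "
            f"(95% CI {nsum['ci95'][0]:.0f}, {nsum['ci95'][1]:.0f}); "
            f"mean {nsum['mean']:.0f}",
            f"predicted rUBR:        {rsum['median']:.3f} "
            f"(95% CI {rsum['ci95'][0]:.3f}, {rsum['ci95'][1]:.3f}); "
            f"mean {rsum['mean']:.3f}",
        ]
        for label in pred.category_total_draws:
            csum = pred.category_summary(label)
            lines.append(
                f"  {label}: predicted total {csum['median']:.0f} "
                f"(95% CI {csum['ci95'][0]:.0f}, {csum['ci95'][1]:.0f})"
            )
        if design.rubr_target is not None:
            p_acc, p_rubr = self.prob_meeting()
            lines += [
                "-" * 49,
                f"P(final n >= {design.n_target}) = {p_acc:.3f}",
                f"P(final rUBR >= {design.rubr_target:g}) = {p_rubr:.3f}",
            ]
        return "\n".join(lines)

    def to_report_block(self, index: int = 1) -> dict:
        """JSON-serializable per-interim block (see rubrwatch.io schema)."""
        design = self.model.design
        interim = self.model.interim
        pred = self.prediction
        block = {
            "index": index,
            "m": interim.m,
            "t_m": interim.t_m,
            "sample_size": pred.sample_size_summary,
            "rubr": pred.rubr_summary,
            "categories": {
                label: pred.category_summary(label)
                for label in pred.category_total_draws
            },
        }
        p_acc, _ = prob_meeting(pred, design.n_target, np.inf)
        block["prob_meeting"] = {"accrual": p_acc}
        if design.rubr_target is not None:
            _, p_rubr = prob_meeting(pred, design.n_target, design.rubr_target)
            block["prob_meeting"]["rubr"] = p_rubr
        return block
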