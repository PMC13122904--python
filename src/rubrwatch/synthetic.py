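"""Synthetic trial generator.

Produces subject-level enrollment logs with exactly the statistical
structure the models assume: i.i.d. exponential inter-arrival times with
mean ``theta_true`` and, per subject, independent Bernoulli membership
flags for each UBR category.  Generation stops at whichever of the subject
cap ``n_max`` or the horizon ``horizon_T`` binds first, mirroring trials
that end at target or at time.

An optional ``overlap_mode="paired"`` makes consecutive category pairs
share a single membership flag — the extreme of the cross-category overlap
that aggregated counts cannot record — to demonstrate how the additive
combined rUBR double-counts overlapping subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .design import FinalCounts, InterimData, TrialDesign, CategorySpec
from .exceptions import ValidationError

__all__ = [
    "SyntheticTrialConfig",
    "EnrollmentLog",
    "generate_trial",
    "aggregate_at",
    "final_counts",
    "adore_like_config",
    "adore_like_design",
    "look_times",
]


@dataclass(frozen=True)
class SyntheticTrialConfig:
    """Ground truth for one synthetic trial.

    theta_true is the true mean waiting time between enrollments (study
    time-units per subject); p_true maps category labels to true membership
    probabilities.
    """

    theta_true: float
    p_true: Mapping[str, float] = field(default_factory=dict)
    horizon_T: float = 1.0
    n_max: Optional[int] = None
    overlap_mode: str = "independent"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_true", dict(self.p_true))
        if self.theta_true <= 0:
            raise ValidationError("theta_true must be > 0")
        if self.horizon_T <= 0:
            raise ValidationError("horizon_T must be > 0")
        for label, p in self.p_true.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"p_true[{label!r}] must be in [0, 1]")
        if self.overlap_mode not in ("independent", "paired"):
            raise ValidationError("overlap_mode must be 'independent' or 'paired'")
        if self.n_max is not None and self.n_max < 0:
            raise ValidationError("n_max must be >= 0")


@dataclass(frozen=True)
class EnrollmentLog:
    """Subject-level enrollment records, sorted by enrollment time.

    ``frame`` has columns ``subject_id``, ``enroll_time`` and one 0/1
    column per category label.
    """

    frame: pd.DataFrame
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "categories", tuple(self.categories))
        required = ["subject_id", "enroll_time", *self.categories]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"enrollment log missing columns: {missing}")
        t = self.frame["enroll_time"].to_numpy()
        if len(t) and (np.diff(t) < 0).any():
            raise ValidationError("enrollment times must be non-decreasing")
        for c in self.categories:
            vals = self.frame[c].to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise ValidationError(f"flags in column {c!r} must be 0/1")

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def generate_trial(config: SyntheticTrialConfig) -> EnrollmentLog:
    """Simulate one enrollment log under the generative model.

    Inter-arrival times are drawn in blocks until the cumulative time
    passes the horizon (or ``n_max`` subjects have enrolled); the result is
    seed-reproducible.
    """
    rng = np.random.default_rng(config.seed)
    expected = config.horizon_T / config.theta_true
    block = max(16, int(expected + 6 * np.sqrt(expected) + 10))
    times = np.array([], dtype=float)
    total = 0.0
    while total <= config.horizon_T:
        w = rng.exponential(config.theta_true, size=block)
        times = np.concatenate([times, total + np.cumsum(w)])
        total = float(times[-1])
    times = times[times <= config.horizon_T]
    if config.n_max is not None:
        times = times[: config.n_max]
    n = len(times)

    labels = list(config.p_true)
    flags: dict[str, np.ndarray] = {}
    if config.overlap_mode == "independent":
        for label in labels:
            flags[label] = (rng.random(n) < config.p_true[label]).astype(np.int64)
    else:  # paired: categories (0,1), (2,3), ... share one flag
        for i in range(0, len(labels), 2):
            shared = (rng.random(n) < config.p_true[labels[i]]).astype(np.int64)
            flags[labels[i]] = shared
            if i + 1 < len(labels):
                flags[labels[i + 1]] = shared.copy()

    frame = pd.DataFrame(
        {"subject_id": np.arange(1, n + 1), "enroll_time": times, **flags}
    )
    return EnrollmentLog(frame=frame, categories=tuple(labels))


def aggregate_at(log: EnrollmentLog, at_time: float) -> InterimData:
    """Aggregated interim counts at a monitoring time.

    ``m`` counts subjects with ``t_i <= at_time``; ``t_m`` is the m-th
    enrollment time (0 when nobody has enrolled); counts sum the flags
    among those ``m`` subjects.
    """
    if at_time < 0:
        raise ValidationError("at_time must be >= 0")
    sub = log.frame[log.frame["enroll_time"] <= at_time]
    m = len(sub)
    t_m = float(sub["enroll_time"].iloc[-1]) if m else 0.0
    counts = {c: int(sub[c].sum()) for c in log.categories}
    return InterimData(m=m, t_m=t_m, counts=counts)


def final_counts(log: EnrollmentLog) -> FinalCounts:
    """Whole-log totals as FinalCounts (the completed-trial view)."""
    return FinalCounts(
        n_f=len(log),
        counts={c: int(log.frame[c].sum()) for c in log.categories},
    )


def adore_like_design() -> TrialDesign:
    """A design shaped like a large preterm-birth prevention trial:
    target 1355 over 48 months at confidence 0.3, two UBR categories."""
    return TrialDesign(
        n_target=1355,
        horizon_T=48.0,
        confidence_P=0.3,
        categories=(
            CategorySpec("NW", prior_rate_p0=0.45),
            CategorySpec("H", prior_rate_p0=0.15),
        ),
        rubr_target=0.496,
    )


def adore_like_config(seed: Optional[int] = None) -> SyntheticTrialConfig:
    """Ground truth emulating the published shape of that trial: roughly
    1100 enrollments over 45 months, category rates near 302/1100 and
    244/1100.  Only the published summary shape is emulated; no real
    subject-level data are involved."""
    return SyntheticTrialConfig(
        theta_true=45.2 / 1100.0,
        p_true={"NW": 302 / 1100, "H": 244 / 1100},
        horizon_T=48.0,
        n_max=1100,
        seed=seed,
    )


def look_times(
    log: EnrollmentLog,
    burn_in_m: int = 300,
    spacing: float = 3.0,
    n_looks: int = 10,
) -> list[float]:
    """Monitoring schedule: first look when ``burn_in_m`` subjects have
    enrolled, then every ``spacing`` time-units, ``n_looks`` looks total."""
    if len(log) < burn_in_m:
        raise ValidationError(
            f"log has {len(log)} subjects; cannot schedule a look after "
            f"{burn_in_m} enrollments"
        )
    start = float(log.frame["enroll_time"].iloc[burn_in_m - 1])
    return [start + i * spacing for i in range(n_looks)]
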