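"""Trial-design and interim-data containers.

A monitored trial is described by three small immutable records:

* :class:`TrialDesign` — the planned sample size ``n``, the recruitment
  horizon ``T`` (study time-units), the researcher's prior confidence
  ``P`` in meeting the target (elicited on a 1-10 scale and rescaled to
  [0, 1]), and the list of UBR categories with their prior expected rates.
* :class:`InterimData` — what a DSMB report provides at a monitoring look:
  ``m`` subjects enrolled, the time ``t_m`` of the m-th enrollment (the sum
  of the observed waiting times), and the aggregated per-category counts
  ``S_m^u``.
* :class:`FinalCounts` — the final enrollment and per-category totals of a
  completed trial, from which the observed final rUBR is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .exceptions import ValidationError

__all__ = ["CategorySpec", "TrialDesign", "InterimData", "FinalCounts"]


@dataclass(frozen=True)
class CategorySpec:
    """One underrepresented-in-biomedical-research (UBR) category.

    Parameters
    ----------
    label : str
        Short category name, e.g. ``"NW"`` (non-white), ``"H"`` (Hispanic),
        ``"R"`` (rural).
    prior_rate_p0 : float
        Prior expected rate of membership in this category, ``p0`` in
        [0, 1]; typically the investigator's target rate for the category.
    target_rate : float, optional
        Monitoring target for this category (unused by the combined-rUBR
        probability, which uses the design-level ``rubr_target``).
    """

    label: str
    prior_rate_p0: float
    target_rate: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.label:
            raise ValidationError("category label must be non-empty")
        if not 0.0 <= self.prior_rate_p0 <= 1.0:
            raise ValidationError(
                f"prior_rate_p0 for {self.label!r} must be in [0, 1], "
                f"got {self.prior_rate_p0}"
            )
        if self.target_rate is not None and not 0.0 <= self.target_rate <= 1.0:
            raise ValidationError(
                f"target_rate for {self.label!r} must be in [0, 1]"
            )


@dataclass(frozen=True)
class TrialDesign:
    """Planned trial: target size, horizon, prior confidence, categories.

    ``confidence_P`` is the 1-10 elicitation divided by 10: ``P = 0`` is a
    flat prior (no confidence), ``P = 1`` a fully informative one.
    """

    n_target: int
    horizon_T: float
    confidence_P: float
    categories: tuple[CategorySpec, ...] = field(default_factory=tuple)
    rubr_target: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_target < 1:
            raise ValidationError("n_target must be >= 1")
        if self.horizon_T <= 0:
            raise ValidationError("horizon_T must be > 0")
        if not 0.0 <= self.confidence_P <= 1.0:
            raise ValidationError("confidence_P must be in [0, 1]")
        object.__setattr__(self, "categories", tuple(self.categories))
        labels = [c.label for c in self.categories]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate category labels: {labels}")
        if self.rubr_target is not None and self.rubr_target < 0:
            raise ValidationError("rubr_target must be >= 0")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.categories)

    def category(self, label: str) -> CategorySpec:
        for c in self.categories:
            if c.label == label:
                return c
        raise KeyError(label)


@dataclass(frozen=True)
class InterimData:
    """Aggregated observed data at a monitoring look.

    ``t_m`` is the enrollment time of the m-th subject, i.e. the sum of the
    observed waiting times; a look strictly between enrollments does not
    contribute the censored in-progress waiting time.
    """

    m: int
    t_m: float
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", dict(self.counts))
        if self.m < 0:
            raise ValidationError("m must be >= 0")
        if self.t_m < 0:
            raise ValidationError("t_m must be >= 0")
        if self.m == 0:
            if self.t_m != 0:
                raise ValidationError("m = 0 requires t_m = 0")
            if any(v != 0 for v in self.counts.values()):
                raise ValidationError("m = 0 requires all counts zero")
        for label, s in self.counts.items():
            if not 0 <= s <= self.m:
                raise ValidationError(
                    f"count for {label!r} must satisfy 0 <= S <= m "
                    f"(got S={s}, m={self.m})"
                )

    def count(self, label: str) -> int:
        return int(self.counts.get(label, 0))


@dataclass(frozen=True)
class FinalCounts:
    """Final enrollment ``n_f`` and per-category totals of a completed trial."""

    n_f: int
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", dict(self.counts))
        if self.n_f <= 0:
            raise ValidationError("n_f must be a positive integer")
        for label, s in self.counts.items():
            if not 0 <= s <= self.n_f:
                raise ValidationError(
                    f"final count for {label!r} must satisfy 0 <= count <= n_f"
                )


def validate_interims_ordered(interims: Sequence[InterimData]) -> None:
    """Raise unless interim looks are ordered by non-decreasing (m, t_m)."""
    for a, b in zip(interims, interims[1:]):
        if b.t_m < a.t_m or b.m < a.m:
            raise ValidationError(
                "interim looks must be ordered by non-decreasing t_m and m"
            )
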