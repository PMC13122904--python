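"""Plotting helper: joint scatter of predicted rUBR vs predicted sample size."""

from __future__ import annotations

from typing import Optional

from .monitor import JointPrediction

__all__ = ["plot_prediction"]


def plot_prediction(
    prediction: JointPrediction,
    n_target: Optional[int] = None,
    rubr_target: Optional[float] = None,
    ax=None,
    **scatter_kwargs,
):
    """Scatter the paired (rUBR, sample size) draws with target lines.

    Returns the matplotlib Axes.  Reference lines mark the accrual target
    (horizontal) and the rUBR target (vertical) when given.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    scatter_kwargs.setdefault("s", 4)
    scatter_kwargs.setdefault("alpha", 0.25)
    ax.scatter(prediction.rubr_draws, prediction.sample_size_draws, **scatter_kwargs)
    if n_target is not None:
        ax.axhline(n_target, color="red", linestyle="--", linewidth=1)
    if rubr_target is not None:
        ax.axvline(rubr_target, color="red", linestyle="--", linewidth=1)
    ax.set_xlabel("predicted rUBR")
    ax.set_ylabel("predicted sample size")
    return ax
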