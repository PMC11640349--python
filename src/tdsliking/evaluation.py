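"""Fit metrics for predicted liking curves and box-whisker summaries.

Each validation curve is scored on its own over the time grid:
RMSE = sqrt(mean((obs - pred)^2)) and R^2 = 1 - SS_res / SS_tot, so an
ensemble of 16 models validated on 10 curves each yields 160 metric
values.  Distributions of those values are summarized Tukey-style
(quartiles by linear interpolation, whiskers at the most extreme data
within 1.5 x IQR of the box, everything outside flagged as outliers,
arithmetic mean reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FitMetrics", "BoxSummary", "score_curve", "summarize", "box_plot"]


@dataclass(frozen=True)
class FitMetrics:
    """RMSE and coefficient of determination for one curve.

    ``r2_defined`` is False when the observed curve is constant (zero
    total sum of squares); ``r2`` is NaN in that case.
    """

    rmse: float
    r2: float
    r2_defined: bool = True


@dataclass(frozen=True)
class BoxSummary:
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    mean: float
    outliers: tuple[float, ...] = field(default_factory=tuple)

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def score_curve(observed: np.ndarray, predicted: np.ndarray) -> FitMetrics:
    """Score one predicted liking curve against the observed one."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-D of equal length")
    ss_res = float(np.sum((obs - pred) ** 2))
    rmse = float(np.sqrt(ss_res / obs.size))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return FitMetrics(rmse, float("nan"), r2_defined=False)
    return FitMetrics(rmse, 1.0 - ss_res / ss_tot)


def summarize(values) -> BoxSummary:
    """Tukey five-number summary with 1.5 x IQR whiskers.

    Whiskers sit on the most extreme data points inside
    [q1 - 1.5 IQR, q3 + 1.5 IQR]; points beyond them are outliers.
    Invariant to the ordering of ``values``.
    """
    v = np.sort(np.asarray(list(values), dtype=float))
    if v.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_bound, hi_bound = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_bound) & (v <= hi_bound)]
    outliers = tuple(float(x) for x in v[(v < lo_bound) | (v > hi_bound)])
    return BoxSummary(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        mean=float(v.mean()),
        outliers=outliers,
    )


def box_plot(groups: dict[str, np.ndarray], path: str, ylabel: str = "") -> None:
    """Box-whisker plot of metric distributions (1.5 x IQR whiskers, mean
    marked with a cross, outliers as hollow circles)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.4 * len(groups) + 1.5, 3.2))
    ax.boxplot(
        list(groups.values()),
        tick_labels=list(groups.keys()),
        whis=1.5,
        showmeans=True,
        meanprops={"marker": "x", "markeredgecolor": "black"},
        flierprops={"marker": "o", "markerfacecolor": "none"},
    )
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
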