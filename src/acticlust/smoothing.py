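"""Loess-smoothed per-cluster diel activity curves.

Each cluster's members are averaged into a single 1440-minute
minute-of-day curve (raw MET features are folded over the 7 days first), then
smoothed with classical loess: at each minute, a locally weighted linear
regression over the nearest ``ceil(span * n)`` neighbours with tricube
weights, evaluated at that minute. No robustness iterations are applied and
the day is treated as non-circular (no wraparound across midnight).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .features import RAW, FeatureMatrix
from .io_cohort import DAYS_PER_WEEK, MINUTES_PER_DAY

DEFAULT_SPAN = 0.1


@dataclass
class SmoothedCurves:
    """Per-cluster mean diel curves, raw and loess-smoothed, on a shared grid."""

    minute_grid: np.ndarray            # 0..1439
    curves: dict                       # cluster -> smoothed 1440-length curve
    raw_means: dict                    # cluster -> unsmoothed mean curve
    span: float

    def __post_init__(self) -> None:
        if not 0 < self.span <= 1:
            raise ValueError("span must lie in (0, 1]")
        for c, v in self.curves.items():
            if len(v) != len(self.minute_grid):
                raise ValueError(f"cluster {c}: curve length != grid length")


def cluster_mean_curve(features: FeatureMatrix, labels: np.ndarray) -> dict:
    """Mean 1440-length minute-of-day curve for each cluster.

    Raw features (10,080 per row) are averaged over members and then over the
    seven day-blocks; normalized MVPA profiles are simply averaged over
    members.
    """
    labels = np.asarray(labels)
    if len(labels) != features.n:
        raise ValueError("labels do not align with feature rows")
    out = {}
    for c in np.unique(labels):
        members = features.values[labels == c]
        if members.size == 0:
            raise ValueError(f"cluster {c} is empty")
        mean = members.mean(axis=0)
        if features.kind == RAW:
            mean = mean.reshape(DAYS_PER_WEEK, MINUTES_PER_DAY).mean(axis=0)
        out[int(c)] = mean
    return out


def loess_smooth(curve: np.ndarray, span: float = DEFAULT_SPAN, degree: int = 1) -> np.ndarray:
    """Loess (tricube-weighted local linear) smoothing of an evenly spaced curve.

    ``span`` is the fraction of points in each local window; the effective
    window ``ceil(span * n)`` must cover at least 3 points to fit a line with
    a spare degree of freedom.
    """
    if degree != 1:
        raise ValueError("only locally linear (degree=1) loess is supported")
    curve = np.asarray(curve, dtype=float)
    if not np.all(np.isfinite(curve)):
        raise ValueError("curve must be finite")
    n = len(curve)
    window = math.ceil(span * n)
    if window < 3:
        raise ValueError(f"span {span} gives a {window}-point window; need >= 3")
    x = np.arange(n, dtype=float)
    # frac chosen so statsmodels' floor(frac*n) equals the ceil window
    return _sm_lowess(curve, x, frac=(window + 0.5) / n, it=0, return_sorted=False)


def smooth_cluster_curves(
    features: FeatureMatrix, labels: np.ndarray, span: float = DEFAULT_SPAN
) -> SmoothedCurves:
    """Mean curve per cluster, then loess on each; the naming/plotting input."""
    raw_means = cluster_mean_curve(features, labels)
    smoothed = {c: loess_smooth(v, span=span) for c, v in raw_means.items()}
    return SmoothedCurves(
        minute_grid=np.arange(MINUTES_PER_DAY),
        curves=smoothed,
        raw_means=raw_means,
        span=span,
    )


def curves_frame(curves: SmoothedCurves, names: dict | None = None):
    """Long-format DataFrame (minute, cluster[, name], raw_mean, smoothed)."""
    import pandas as pd

    frames = []
    for c in sorted(curves.curves):
        frame = pd.DataFrame(
            {
                "minute": curves.minute_grid,
                "cluster": c,
                "raw_mean": curves.raw_means[c],
                "smoothed": curves.curves[c],
            }
        )
        if names:
            frame.insert(2, "name", names.get(c, str(c)))
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def plot_curves(curves: SmoothedCurves, path, names: dict | None = None, ylabel: str = "mean METs") -> None:
    """Line plot of the smoothed curves (one line per cluster), saved to path."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4.5))
    for c in sorted(curves.curves):
        label = names.get(c, f"cluster {c}") if names else f"cluster {c}"
        ax.plot(curves.minute_grid / 60.0, curves.curves[c], label=label)
    ax.set_xlabel("hour of day")
    ax.set_ylabel(ylabel)
    ax.set_xlim(0, 24)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
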