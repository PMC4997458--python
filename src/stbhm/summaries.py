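"""Decision outputs from posterior draws.

Per-unit relative magnitudes exp(S_i), the anchored geometric-interval
six-class magnitude map, and the three-way local-trend classification driven
by the posterior probability p(b1_i > 0 | data).
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import pandas as pd

from .model import PosteriorDraws

__all__ = [
    "classify_trend",
    "geometric_interval_breaks",
    "classify_magnitude",
    "summarize_units",
    "overall_level_and_trend",
]

TREND_FASTER = "faster"
TREND_STABLE = "stable"
TREND_DECREASING = "decreasing"


def classify_trend(b1_median: float, prob_positive: float) -> str:
    """Three-way local-trend rule at the 0.8 / 0.2 posterior-probability operating point.

    ``faster``: median > 0 and p(b1 > 0 | data) > 0.8; ``decreasing``: median
    < 0 and p < 0.2; everything else (including p exactly 0.8 or 0.2) is
    ``stable``.
    """
    if not (np.isfinite(b1_median) and np.isfinite(prob_positive)):
        raise ValueError("inputs must be finite")
    if not 0.0 <= prob_positive <= 1.0:
        raise ValueError("prob_positive must lie in [0, 1]")
    if b1_median > 0 and prob_positive > 0.8:
        return TREND_FASTER
    if b1_median < 0 and prob_positive < 0.2:
        return TREND_DECREASING
    return TREND_STABLE


def geometric_interval_breaks(
    values: np.ndarray, n_classes: int = 6, anchor: float = 1.0
) -> np.ndarray:
    """Class breaks forming geometric progressions anchored at a neutral value.

    With the default six classes, three fall below the anchor and three above:
    on each side the breaks are a geometric progression between the side's
    extreme and the anchor, and the anchor itself is the middle break. Returns
    the ``n_classes - 1`` internal breaks in increasing order.

    If all values lie on one side of the anchor, a one-sided geometric
    progression between min and max is used instead (fallback).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0 or np.any(values <= 0):
        raise ValueError("values must be positive")
    if n_classes < 2 or n_classes % 2:
        raise ValueError("n_classes must be an even number >= 2")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise ValueError("all values are equal; no classification possible")
    half = n_classes // 2
    if lo < anchor < hi:
        lower = anchor * (lo / anchor) ** (np.arange(half - 1, 0, -1) / half)
        upper = anchor * (hi / anchor) ** (np.arange(1, half) / half)
        return np.concatenate([lower, [anchor], upper])
    ratio = (hi / lo) ** (1.0 / n_classes)
    return lo * ratio ** np.arange(1, n_classes)


def classify_magnitude(values: np.ndarray, breaks: np.ndarray) -> np.ndarray:
    """Assign each magnitude to its class 1..k (left-closed, right-open)."""
    return np.searchsorted(np.asarray(breaks), np.asarray(values), side="right") + 1


def summarize_units(
    draws: PosteriorDraws,
    n_classes: int = 6,
    anchor: float = 1.0,
) -> pd.DataFrame:
    """Per-unit posterior decision summaries, chains pooled after burn-in.

    magnitude = median over draws of exp(S_i) (exp per draw, then median);
    prob_positive = fraction of draws with b1_i strictly > 0. Magnitude
    classes use the anchored geometric-interval breaks over the units'
    magnitudes; trend classes use :func:`classify_trend`.
    """
    S = draws.pooled("S")
    b1 = draws.pooled("b1")
    if S.size == 0:
        raise ValueError("no posterior draws")
    magnitude = np.median(np.exp(S), axis=0)
    b1_median = np.median(b1, axis=0)
    prob_positive = np.mean(b1 > 0, axis=0)
    breaks = geometric_interval_breaks(magnitude, n_classes=n_classes, anchor=anchor)
    magnitude_class = classify_magnitude(magnitude, breaks)
    trend_class = [
        classify_trend(m, p) for m, p in zip(b1_median, prob_positive)
    ]
    return pd.DataFrame(
        {
            "unit_id": np.arange(1, magnitude.size + 1),
            "magnitude": magnitude,
            "magnitude_class": magnitude_class,
            "b1_median": b1_median,
            "prob_positive": prob_positive,
            "trend_class": trend_class,
        }
    )


def _median_ci(x: np.ndarray) -> dict[str, float]:
    lo, med, hi = np.quantile(x, [0.025, 0.5, 0.975])
    return {"median": float(med), "ci_low": float(lo), "ci_high": float(hi)}


def overall_level_and_trend(draws: PosteriorDraws) -> dict[str, dict[str, float]]:
    """Posterior medians and central 95% credible intervals for the overall
    level (alpha, exp(alpha)) and the common trend b0.

    exp is applied per draw before summarizing exp(alpha); because exp is
    monotone the median commutes, but the interval endpoints are genuine
    quantiles of exp(alpha).
    """
    alpha = draws.pooled("alpha")
    b0 = draws.pooled("b0")
    return {
        "alpha": _median_ci(alpha),
        "exp_alpha": _median_ci(np.exp(alpha)),
        "b0": _median_ci(b0),
    }
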