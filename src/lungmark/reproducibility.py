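"""Test-retest agreement statistics for paired feature measurements.

Given a feature measured twice on the same subjects (e.g. baseline and
follow-up scans acquired minutes apart), the module reports:

* Lin's concordance correlation coefficient (CCC) — agreement with the
  identity line, penalizing both correlation loss and mean/scale shifts;
* dynamic range (DR) — one minus the ratio of the mean absolute repeat
  difference to the biological (inter-subject) range, so identical repeats
  give 1 and noisier features score lower;
* Bland-Altman bias and 95% limits of agreement;
* absolute percent difference summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureReproducibility",
    "concordance_correlation",
    "dynamic_range",
    "bland_altman",
    "absolute_percent_difference",
    "evaluate_paired_table",
]


@dataclass(frozen=True)
class FeatureReproducibility:
    feature: str
    ccc: float
    dynamic_range: float
    mean_abs_diff_over_range: float  # raw ratio behind DR, for transparency
    bias: float
    lower_95: float
    upper_95: float
    abs_pct_diff_mean: float
    abs_pct_diff_sd: float
    n: int


def _paired(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("paired values must be finite")
    return x, y


def concordance_correlation(x, y, sample_moments: bool = False) -> float:
    """Lin's concordance correlation coefficient.

    ccc = 2 cov(x, y) / (var(x) + var(y) + (mean x - mean y)^2), with
    population (1/n) moments by default per Lin's original estimator;
    ``sample_moments=True`` switches to 1/(n-1). Returns NaN when both
    vectors are constant (agreement with the 45-degree line undefined).
    """
    x, y = _paired(x, y)
    ddof = 1 if sample_moments else 0
    vx = x.var(ddof=ddof)
    vy = y.var(ddof=ddof)
    dmean = x.mean() - y.mean()
    denom = vx + vy + dmean * dmean
    if denom == 0.0:
        return math.nan
    n = len(x)
    cov = ((x - x.mean()) * (y - y.mean())).sum() / (n - ddof)
    return float(2.0 * cov / denom)


def dynamic_range(x, y) -> float:
    """DR = 1 - mean|x_i - y_i| / (max(x, y) - min(x, y)).

    The denominator is the pooled inter-subject range; identical repeats
    give 1. NaN when the pooled range is zero.
    """
    x, y = _paired(x, y)
    rng = max(x.max(), y.max()) - min(x.min(), y.min())
    if rng == 0.0:
        return math.nan
    return float(1.0 - np.abs(x - y).mean() / rng)


def bland_altman(x, y) -> tuple[float, float, float]:
    """Bland-Altman bias and 95% limits of agreement.

    Returns ``(bias, lower_95, upper_95)`` with bias = mean(x - y) and
    limits bias +/- 1.96 * sd(x - y) (sample sd, n-1 denominator).
    """
    x, y = _paired(x, y)
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def absolute_percent_difference(x, y) -> tuple[float, float]:
    """Mean and sd of the per-subject absolute percent difference.

    Per subject: |x - y| / mean(x, y) * 100. Pairs whose mean is 0 are
    dropped with a warning.
    """
    x, y = _paired(x, y)
    m = (x + y) / 2.0
    keep = m != 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d pair(s) with zero mean from percent-difference summary", n_dropped)
    if not keep.any():
        return math.nan, math.nan
    pct = np.abs(x[keep] - y[keep]) / np.abs(m[keep]) * 100.0
    sd = float(pct.std(ddof=1)) if keep.sum() > 1 else math.nan
    return float(pct.mean()), sd


def evaluate_paired_table(pairs: pd.DataFrame, sample_moments: bool = False) -> pd.DataFrame:
    """Per-feature reproducibility statistics over a paired table.

    ``pairs`` needs columns ``subject_id, feature, test, retest`` (one row
    per subject-feature). Returns one row per feature with CCC, DR,
    Bland-Altman limits and percent-difference summaries.
    """
    required = {"subject_id", "feature", "test", "retest"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"paired table missing columns: {sorted(missing)}")
    if pairs.duplicated(["subject_id", "feature"]).any():
        raise ValueError("paired table has duplicate (subject_id, feature) rows")
    out = []
    for feature, grp in pairs.groupby("feature", sort=True):
        x = grp["test"].to_numpy(float)
        y = grp["retest"].to_numpy(float)
        bias, lo, hi = bland_altman(x, y)
        pct_mean, pct_sd = absolute_percent_difference(x, y)
        dr = dynamic_range(x, y)
        out.append(
            FeatureReproducibility(
                feature=str(feature),
                ccc=concordance_correlation(x, y, sample_moments=sample_moments),
                dynamic_range=dr,
                mean_abs_diff_over_range=(1.0 - dr) if not math.isnan(dr) else math.nan,
                bias=bias,
                lower_95=lo,
                upper_95=hi,
                abs_pct_diff_mean=pct_mean,
                abs_pct_diff_sd=pct_sd,
                n=len(x),
            )
        )
    return pd.DataFrame([vars(r) for r in out])
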