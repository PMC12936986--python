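"""Reliability statistics: intraclass correlation (ICC), Koo categories, MAE.

The ICC point estimate implemented is the absolute-agreement single-rater
form from two-way ANOVA mean squares,

    ICC = (MS_subjects − MS_error) /
          (MS_subjects + (k−1)·MS_error + (k/n)·(MS_raters − MS_error)),

which is the shared point estimate of the two-way random-effects model
(ICC(2,1)) and the two-way mixed-effects absolute-agreement model used for
intra-rater analysis. Reliability categories follow the Koo & Li cut
points: < 0.50 poor, [0.50, 0.75) moderate, [0.75, 0.90] good, > 0.90
excellent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMetricError

ICC_MODELS = ("two_way_mixed_absolute_single", "two_way_random_single")


@dataclass
class RatingTable:
    """Complete n-subject × k-rater matrix for one measurement."""

    values: np.ndarray
    measurement: str = ""
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("rating table must be 2-D (subjects × raters)")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 raters")
        if not np.isfinite(self.values).all():
            raise ValueError("rating table must be complete (no missing cells)")


def koo_category(icc_value: float) -> str:
    """Koo & Li reliability category of an ICC value."""
    if icc_value < 0.50:
        return "poor"
    if icc_value < 0.75:
        return "moderate"
    if icc_value <= 0.90:
        return "good"
    return "excellent"


def anova_mean_squares(table: RatingTable):
    """Two-way ANOVA mean squares (subjects, raters, error) of a rating table."""
    x = table.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return ms_rows, ms_cols, ms_err


def icc(table: RatingTable, model: str = "two_way_random_single"):
    """Absolute-agreement single-rater ICC and its Koo category.

    Both supported models share this point estimate; the distinction (random
    vs mixed rater effects) matters for inference, which is out of scope.
    """
    if model not in ICC_MODELS:
        raise ValueError(f"model must be one of {ICC_MODELS}")
    n, k = table.values.shape
    if np.ptp(table.values) == 0:
        raise UndefinedMetricError("ICC undefined: zero total variance")
    if np.array_equal(table.values, np.tile(table.values[:, :1], (1, k))):
        # perfect agreement: error and rater mean squares are exactly zero
        return 1.0, koo_category(1.0)
    ms_s, ms_r, ms_e = anova_mean_squares(table)
    denom = ms_s + (k - 1) * ms_e + (k / n) * (ms_r - ms_e)
    if abs(denom) < 1e-300:
        raise UndefinedMetricError("ICC undefined: zero total variance")
    value = (ms_s - ms_e) / denom
    return float(value), koo_category(float(value))


def mae(auto, reference):
    """Mean and sample SD (n−1) of the absolute errors |autoᵢ − refᵢ|."""
    a = np.asarray(auto, dtype=float).ravel()
    r = np.asarray(reference, dtype=float).ravel()
    if a.shape != r.shape or a.size == 0:
        raise ValueError("vectors must be non-empty and of equal length")
    err = np.abs(a - r)
    sd = float(err.std(ddof=1)) if err.size > 1 else 0.0
    return float(err.mean()), sd


def rater_mean(table: RatingTable) -> np.ndarray:
    """Per-subject mean across raters — the reference for MAE upstream."""
    return table.values.mean(axis=1)
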