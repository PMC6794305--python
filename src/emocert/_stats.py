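"""Closed-form one-way repeated-measures ANOVA used across modules.

Implemented directly (subjects x levels matrix) so that thousand-fold
calibration simulations stay fast; unit tests cross-check the F and p values
against ``statsmodels`` AnovaRM on the same data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["RMAnovaResult", "rm_anova"]


@dataclass(frozen=True)
class RMAnovaResult:
    f_value: float
    df_num: int
    df_den: int
    p_value: float


def rm_anova(data: np.ndarray) -> RMAnovaResult:
    """One-way repeated-measures F for a (subjects x levels) data matrix.

    Error term is the subject-by-level interaction:
    ``F = MS_levels / MS_error`` with ``df = (k-1), (k-1)(n-1)``.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a (subjects x levels) matrix")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 levels, got {n} x {k}")
    grand = data.mean()
    ss_levels = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_subjects = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_error = ss_total - ss_levels - ss_subjects
    df_num, df_den = k - 1, (k - 1) * (n - 1)
    ms_error = ss_error / df_den
    if ms_error <= 0:
        # degenerate: no within-cell variability left
        f = 0.0 if ss_levels == 0 else np.inf
    else:
        f = (ss_levels / df_num) / ms_error
    p = float(stats.f.sf(f, df_num, df_den)) if np.isfinite(f) else 0.0
    return RMAnovaResult(f_value=float(f), df_num=df_num, df_den=df_den, p_value=p)
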