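"""Modulation statistics coupling psychophysics to ROI t-value trajectories.

Each ROI/hemisphere/emotion carries an ordered t-value trajectory over the
decomposition ladder (original, 8 nb, 32 nb, 64 nb).  Two statistics are
derived:

* **percent change from original** — ``100 * |t(level) - t(original)| /
  |t(original)|`` per altered level; the mean over levels summarizes how
  strongly a ROI is modulated by decomposition.

* **weighted modulation** — couples the ROI's absolute t-change ladder to the
  psychophysical absolute identification-change ladder over the same
  consecutive pairs, normalized to the original-stimulus response:

  ``WM = mean_i(|dt_i| * |dpct_i|) / |t(original)|``

  where ``dt_i`` and ``dpct_i`` run over (original-8, 8-32, 32-64).  The
  statistic is zero when either ladder is flat, invariant to rescaling the
  whole trajectory by a positive constant and to flipping its sign, and
  undefined (flagged, not infinite) when t(original) = 0.  Intermediate
  ladders and the normalizer are exposed so alternative compositions are
  one-line variations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import RMAnovaResult, rm_anova
from .psychometrics import DEFAULT_LADDER

__all__ = [
    "ROITrajectory",
    "ModulationResult",
    "percent_change_from_original",
    "weighted_modulation",
    "modulation_anova",
    "compute_modulation_table",
]


@dataclass(frozen=True)
class ROITrajectory:
    """Ordered ROI t-values over the decomposition ladder."""

    roi: str
    hemisphere: str
    emotion: str
    t_values: tuple[float, float, float, float]
    ladder: tuple = DEFAULT_LADDER

    def __post_init__(self) -> None:
        if len(self.t_values) != len(self.ladder):
            raise ValueError(
                f"{len(self.t_values)} t-values for {len(self.ladder)}-level ladder"
            )


@dataclass
class ModulationResult:
    """Weighted modulation with all exposed intermediates."""

    value: float
    defined: bool
    dt_ladder: np.ndarray  # |t_i - t_{i+1}| over consecutive pairs
    dpct_ladder: np.ndarray  # |pct_i - pct_{i+1}| over the same pairs
    normalizer: float  # |t(original)|
    pct_change: np.ndarray  # percent change from original, per altered level
    mean_abs_t_change: float


def percent_change_from_original(traj: ROITrajectory) -> np.ndarray:
    """Per-level percent change of the ROI response from the original.

    Raises
    ------
    ZeroDivisionError
        When t(original) is zero, normalization is undefined.
    """
    t = np.asarray(traj.t_values, dtype=float)
    if t[0] == 0:
        raise ZeroDivisionError(
            f"t(original) = 0 for {traj.roi}/{traj.hemisphere}/{traj.emotion}"
        )
    return 100.0 * np.abs(t[1:] - t[0]) / abs(t[0])


def weighted_modulation(
    traj: ROITrajectory,
    pct_ladder: np.ndarray | tuple,
) -> ModulationResult:
    """Weighted modulation of one ROI trajectory by a psychometric ladder.

    ``pct_ladder`` holds the percent identification at each ladder level of
    the trajectory's emotion (same ordering).  A zero numerator yields 0; a
    zero ``t(original)`` with a non-zero numerator is flagged undefined
    rather than returned as infinity.
    """
    t = np.asarray(traj.t_values, dtype=float)
    pct = np.asarray(pct_ladder, dtype=float)
    if pct.shape != t.shape:
        raise ValueError(f"psychometric ladder length {pct.size} != trajectory {t.size}")
    dt = np.abs(np.diff(t))
    dpct = np.abs(np.diff(pct))
    numerator = float(np.mean(dt * dpct))
    normalizer = abs(float(t[0]))
    if numerator == 0.0:
        value, defined = 0.0, True
    elif normalizer == 0.0:
        value, defined = float("nan"), False
    else:
        value, defined = numerator / normalizer, True
    pct_change = (
        percent_change_from_original(traj) if t[0] != 0 else np.full(t.size - 1, np.nan)
    )
    return ModulationResult(
        value=value,
        defined=defined,
        dt_ladder=dt,
        dpct_ladder=dpct,
        normalizer=normalizer,
        pct_change=pct_change,
        mean_abs_t_change=float(dt.mean()),
    )


def modulation_anova(
    trajectories: list[ROITrajectory],
) -> tuple[RMAnovaResult, pd.DataFrame]:
    """Repeated-measures F across ladder levels over subject trajectories.

    ``trajectories`` holds one ROITrajectory per subject for a single
    ROI/hemisphere/emotion; follow-up paired t-tests compare each altered
    level against the original.
    """
    if len(trajectories) < 2:
        raise ValueError("need >= 2 subjects for a repeated-measures ANOVA")
    ladder = trajectories[0].ladder
    for tr in trajectories:
        if tr.ladder != ladder:
            raise ValueError("all trajectories must share one ladder")
    data = np.array([tr.t_values for tr in trajectories], dtype=float)
    res = rm_anova(data)
    from scipy import stats as _st

    rows = []
    for j, level in enumerate(ladder[1:], start=1):
        t, p = _st.ttest_rel(data[:, j], data[:, 0])
        rows.append({"level": level, "t": float(t), "df": data.shape[0] - 1, "p": float(p)})
    return res, pd.DataFrame(rows)


def compute_modulation_table(
    trajectories: list[ROITrajectory],
    psych_table: pd.DataFrame,
) -> pd.DataFrame:
    """Tidy per-ROI modulation table from trajectories and a psychometric table.

    ``psych_table`` is the output of
    :func:`emocert.psychometrics.percent_identification`.  Returns one row per
    (roi, hemisphere, emotion, level) with the percent change plus the ROI's
    weighted modulation (repeated across its levels).
    """
    rows = []
    for traj in trajectories:
        pct = [float(psych_table.loc[(traj.emotion, lvl), "pct"]) for lvl in traj.ladder]
        res = weighted_modulation(traj, pct)
        for j, level in enumerate(traj.ladder[1:]):
            rows.append(
                {
                    "roi": traj.roi,
                    "hemisphere": traj.hemisphere,
                    "emotion": traj.emotion,
                    "level": level,
                    "pct_change": float(res.pct_change[j]),
                    "weighted_modulation": res.value,
                    "defined": res.defined,
                }
            )
    return pd.DataFrame(rows)
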