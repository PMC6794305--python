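"""2IFC happy/sad psychometrics: identification curves and certainty classes.

Every altered excerpt is scored against the label of its original unaltered
source, so "percent identification" is the percent of responses matching the
original emotion.  Categories fall into three certainty classes: *certain*
(original excerpts), *uncertain* (< 80% identification) and *chance* (< 50%);
altered stimuli at >= 80% never occur in the studied regime and are flagged
as ``certain_equivalent`` rather than silently folded into a paper class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import RMAnovaResult, rm_anova

__all__ = [
    "CERTAIN",
    "UNCERTAIN",
    "CHANCE",
    "CERTAIN_EQUIVALENT",
    "DEFAULT_LADDER",
    "MissingCellError",
    "percent_identification",
    "classify_certainty",
    "category_change",
    "anova_by_decomposition",
    "AnovaByDecomposition",
    "read_responses",
]

CERTAIN = "certain"
UNCERTAIN = "uncertain"
CHANCE = "chance"
CERTAIN_EQUIVALENT = "certain_equivalent"

#: decomposition ladder used for modulation statistics
DEFAULT_LADDER = ("original", 8, 32, 64)

_RESPONSE_COLUMNS = ["subject", "stim_id", "emotion", "nb", "domain", "response"]


class MissingCellError(KeyError):
    """Raised when a required (emotion, nb) cell has no responses."""


def read_responses(path) -> pd.DataFrame:
    """Read a TSV response table (subject, stim_id, emotion, nb, domain, response)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"response table missing columns: {sorted(missing)}")
    # the nb column mixes "original" with band counts; keep counts as ints
    df["nb"] = [v if v == "original" else int(v) for v in df["nb"]]
    return df


def classify_certainty(pct: float, is_original: bool) -> str:
    """Assign the certainty class of one (emotion, nb) category.

    Original excerpts are *certain* by definition; altered categories are
    *chance* below 50% identification, *uncertain* in [50, 80), and flagged
    ``certain_equivalent`` at >= 80 (outside the studied regime).
    """
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"percent identification out of range: {pct}")
    if is_original:
        return CERTAIN
    if pct < 50.0:
        return CHANCE
    if pct < 80.0:
        return UNCERTAIN
    return CERTAIN_EQUIVALENT


def percent_identification(
    responses: pd.DataFrame,
    sd_across: str = "subjects",
) -> pd.DataFrame:
    """Per-category percent identification with group mean and SD.

    Responses are first averaged within subject per (emotion, nb) cell, then
    aggregated to a group mean +/- SD across subjects (``sd_across="stimuli"``
    switches the dispersion unit to stimuli).  Returns a DataFrame indexed by
    (emotion, nb) with columns ``pct``, ``sd``, ``n_trials``, ``n_units`` and
    ``certainty``.

    Raises
    ------
    MissingCellError
        If any (emotion, nb) combination present in the labels has no rows
        (flagged explicitly, never reported as a silent zero).
    """
    if responses.empty:
        raise MissingCellError("empty response table")
    df = responses.copy()
    df["correct"] = (df["response"] == df["emotion"]).astype(float)
    unit = "subject" if sd_across == "subjects" else "stim_id"
    per_unit = (
        df.groupby(["emotion", "nb", unit], sort=False)["correct"].mean().mul(100.0)
    )
    rows = []
    for (emotion, nb), grp in per_unit.groupby(level=["emotion", "nb"], sort=False):
        n_trials = int(((df["emotion"] == emotion) & (df["nb"] == nb)).sum())
        if n_trials == 0:
            raise MissingCellError(f"no responses in cell ({emotion}, {nb})")
        pct = float(grp.mean())
        rows.append(
            {
                "emotion": emotion,
                "nb": nb,
                "pct": pct,
                "sd": float(grp.std(ddof=1)) if len(grp) > 1 else 0.0,
                "n_trials": n_trials,
                "n_units": int(len(grp)),
                "certainty": classify_certainty(pct, is_original=(nb == "original")),
            }
        )
    return pd.DataFrame(rows).set_index(["emotion", "nb"])


def category_change(
    table: pd.DataFrame,
    ladder: tuple = DEFAULT_LADDER,
) -> pd.Series:
    """Mean absolute identification change over consecutive ladder levels.

    The mean of |pct(original) - pct(8nb)|, |pct(8nb) - pct(32nb)| and
    |pct(32nb) - pct(64nb)| per emotion — the psychophysical factor of the
    weighted-modulation statistic.
    """
    out = {}
    for emotion in table.index.get_level_values("emotion").unique():
        pcts = []
        for level in ladder:
            try:
                pcts.append(float(table.loc[(emotion, level), "pct"]))
            except KeyError:
                raise MissingCellError(
                    f"ladder level {level!r} missing for emotion {emotion!r}"
                ) from None
        out[emotion] = float(np.mean(np.abs(np.diff(pcts))))
    return pd.Series(out, name="mean_abs_change")


@dataclass
class AnovaByDecomposition:
    """Per-emotion repeated-measures F plus paired follow-ups vs original."""

    anova: dict[str, RMAnovaResult]
    followups: pd.DataFrame  # emotion, level, t, df, p


def anova_by_decomposition(
    responses: pd.DataFrame,
    levels: tuple | None = None,
    bonferroni: bool = False,
) -> AnovaByDecomposition:
    """One-way repeated-measures ANOVA across nb levels, per emotion.

    Per-subject cell means (percent correct) are the repeated measures;
    follow-up paired t-tests compare each altered level against the original,
    Bonferroni-corrected when ``bonferroni`` is set.
    """
    df = responses.copy()
    df["correct"] = (df["response"] == df["emotion"]).astype(float) * 100.0
    anova: dict[str, RMAnovaResult] = {}
    follow_rows = []
    for emotion, grp in df.groupby("emotion", sort=False):
        pivot = grp.pivot_table(index="subject", columns="nb", values="correct", aggfunc="mean")
        use = [l for l in (levels or pivot.columns)]
        pivot = pivot[use].dropna()
        if len(pivot) < 2:
            raise ValueError(f"need >= 2 subjects with complete data for {emotion!r}")
        anova[emotion] = rm_anova(pivot.to_numpy())
        if "original" in pivot.columns:
            altered = [c for c in pivot.columns if c != "original"]
            n_comp = max(len(altered), 1)
            for level in altered:
                t, p = stats.ttest_rel(pivot[level], pivot["original"])
                if bonferroni:
                    p = min(1.0, p * n_comp)
                follow_rows.append(
                    {"emotion": emotion, "level": level, "t": float(t),
                     "df": len(pivot) - 1, "p": float(p)}
                )
    return AnovaByDecomposition(anova=anova, followups=pd.DataFrame(follow_rows))
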