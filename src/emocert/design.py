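"""Sparse-sampling experimental design: protocols, schedules and catalogs.

Sparse sampling acquires a single fMRI volume per block, separated from the
3-s auditory stimulus by a short gap and followed by silence, so scanner noise
never overlaps the music.  The finalized protocol is 74 blocks per run
(40 stimulus + 34 silent, 45.95% silent) at TR = 15 s, i.e. 18 min 30 s.
Stimulus blocks come in 8 sets of 5 like-category presentations separated by
silent periods of 3-4 blocks; differing stimulus sets are at least two minutes
apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SparseProtocol",
    "RunSchedule",
    "CohortPlan",
    "StimulusCatalog",
    "ProtocolError",
    "SchedulingError",
    "build_protocol",
    "schedule_run",
    "cohort_totals",
    "enumerate_catalog",
    "gap_delay_grid",
    "BUTTON_MAPS",
]

#: run-1 button assignment and its run-2 counterbalanced reverse
BUTTON_MAPS = {
    1: {"left": "sad", "right": "happy"},
    2: {"left": "happy", "right": "sad"},
}


class ProtocolError(ValueError):
    """Raised when block timing cannot fit the repetition time."""


class SchedulingError(ValueError):
    """Raised when a catalog cannot fill a run schedule."""


@dataclass(frozen=True)
class SparseProtocol:
    """Timing skeleton of one sparse-sampling run."""

    tr: float = 15.0
    ta: float = 1.0
    stim_dur: float = 3.0
    gap_delay: float = 0.1
    post_silence: float = 10.0
    n_stim_blocks: int = 40
    n_silent_blocks: int = 34
    silence_truncated: bool = False

    @property
    def n_blocks(self) -> int:
        return self.n_stim_blocks + self.n_silent_blocks

    @property
    def silent_fraction(self) -> float:
        """Fraction of silent blocks (0.4595 for the final protocol)."""
        return self.n_silent_blocks / self.n_blocks

    @property
    def run_time(self) -> float:
        """Total run duration in seconds (n_blocks x TR)."""
        return self.n_blocks * self.tr

    @property
    def fill_silence(self) -> float:
        """Actual post-acquisition silence scheduled to close each block to TR."""
        return self.tr - self.stim_dur - self.gap_delay - self.ta


def build_protocol(
    tr: float = 15.0,
    ta: float = 1.0,
    stim_dur: float = 3.0,
    gap_delay: float = 0.1,
    post_silence: float = 10.0,
    n_stim_blocks: int = 40,
    n_silent_blocks: int = 34,
) -> SparseProtocol:
    """Validate and assemble a sparse-sampling protocol.

    The hard constraint is that stimulus + gap + acquisition fit inside one
    TR.  The nominal post-stimulus silence is approximate ("~10.00 seconds");
    when it overflows the block remainder by more than 0.5 s the schedule
    truncates it to close each block exactly at TR and the protocol is flagged
    ``silence_truncated`` (this occurs for some gap-delay optimization trials,
    never for the final protocol).
    """
    for name, v in [("tr", tr), ("ta", ta), ("stim_dur", stim_dur), ("post_silence", post_silence)]:
        if v <= 0:
            raise ProtocolError(f"{name} must be positive, got {v}")
    if gap_delay < 0:
        raise ProtocolError(f"gap_delay must be >= 0, got {gap_delay}")
    if n_stim_blocks < 0 or n_silent_blocks <= 0:
        raise ProtocolError("block counts must be non-negative (silent > 0)")
    if stim_dur + gap_delay + ta > tr:
        raise ProtocolError(
            f"stimulus+gap+acquisition = {stim_dur + gap_delay + ta:.2f} s exceeds TR = {tr} s"
        )
    truncated = stim_dur + gap_delay + ta + post_silence > tr + 0.5
    return SparseProtocol(
        tr=tr,
        ta=ta,
        stim_dur=stim_dur,
        gap_delay=gap_delay,
        post_silence=post_silence,
        n_stim_blocks=n_stim_blocks,
        n_silent_blocks=n_silent_blocks,
        silence_truncated=truncated,
    )


@dataclass(frozen=True)
class CohortPlan:
    """Per-cohort bookkeeping for the fMRI experiment."""

    n_subjects: int
    runs_per_subject: int = 2
    stim_per_run: int = 40
    silent_per_run: int = 34


def cohort_totals(plan: CohortPlan) -> dict:
    """Derived presentation counts for a whole cohort.

    For the 16-subject, 2-run cohort: 1280 stimulus presentations,
    68 silent blocks per individual and 1088 silent periods.
    """
    if plan.n_subjects <= 0 or plan.runs_per_subject <= 0:
        raise ValueError("cohort counts must be positive")
    return {
        "stimulus_presentations": plan.n_subjects * plan.runs_per_subject * plan.stim_per_run,
        "silent_periods": plan.n_subjects * plan.runs_per_subject * plan.silent_per_run,
        "silent_blocks_per_individual": plan.runs_per_subject * plan.silent_per_run,
        "stimulus_per_individual": plan.runs_per_subject * plan.stim_per_run,
    }


@dataclass
class StimulusCatalog:
    """Enumerated original + decomposed/chimeric stimuli."""

    entries: pd.DataFrame  # columns: stim_id, emotion, nb, domain

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def categories(self) -> pd.DataFrame:
        return self.entries[["emotion", "nb"]].drop_duplicates()


def enumerate_catalog(
    n_originals: int,
    nb_levels: int = 6,
    alterations_per_original_per_level: int = 1,
    nb_values: tuple[int, ...] = (2, 4, 8, 16, 32, 64),
    domains: tuple[str, ...] = ("FIS", "ENV"),
) -> StimulusCatalog:
    """Enumerate a stimulus catalog of originals plus per-level alterations.

    Size is ``n_originals * (1 + nb_levels * alterations_per_original_per_level)``:
    the psychophysics set (32 originals, 6 levels, 1 alteration each) yields
    224 stimuli; the fMRI set (10 originals, 3 levels) yields 40.
    Emotion labels alternate happy/sad across originals; alteration domain
    tags cycle through ``domains``.
    """
    if n_originals <= 0:
        raise ValueError("n_originals must be positive")
    if nb_levels > len(nb_values):
        raise ValueError(f"nb_levels={nb_levels} exceeds available nb values {nb_values}")
    rows = []
    for i in range(n_originals):
        emotion = "happy" if i % 2 == 0 else "sad"
        rows.append({"stim_id": f"orig{i:03d}", "emotion": emotion, "nb": "original", "domain": "original"})
        for lv in range(nb_levels):
            nb = nb_values[lv]
            for a in range(alterations_per_original_per_level):
                rows.append(
                    {
                        "stim_id": f"orig{i:03d}_nb{nb}_a{a}",
                        "emotion": emotion,
                        "nb": nb,
                        "domain": domains[(i + a) % len(domains)],
                    }
                )
    return StimulusCatalog(entries=pd.DataFrame(rows))


@dataclass
class RunSchedule:
    """Ordered block events of one run with BIDS-style export."""

    protocol: SparseProtocol
    events: pd.DataFrame = field(repr=False)
    button_map: dict = field(default_factory=lambda: dict(BUTTON_MAPS[1]))
    run: int = 1
    seed: int = 0

    def to_events_tsv(self, path) -> None:
        """Write a BIDS events file: onset, duration, trial_type, stim_file."""
        out = self.events.rename(columns={"kind": "trial_type", "stim_id": "stim_file"})
        out = out[["onset", "duration", "trial_type", "stim_file"]]
        out.to_csv(path, sep="\t", index=False, na_rep="n/a")

    def validate(self) -> None:
        """Check count conservation, onset monotonicity and category spacing."""
        ev = self.events
        p = self.protocol
        if len(ev) != p.n_blocks:
            raise SchedulingError(f"{len(ev)} events != {p.n_blocks} blocks")
        if (ev["kind"] == "stimulus").sum() != p.n_stim_blocks:
            raise SchedulingError("stimulus block count mismatch")
        if not np.all(np.diff(ev["onset"].to_numpy()) > 0):
            raise SchedulingError("onsets not strictly increasing")
        # like-category blocks are contiguous within one aggregation set or
        # >= 120 s apart across sets
        stim = ev[ev["kind"] == "stimulus"]
        for _, grp in stim.groupby("category"):
            onsets = grp["onset"].to_numpy()
            sets = grp["set_index"].to_numpy()
            for i in range(1, len(onsets)):
                if sets[i] != sets[i - 1] and onsets[i] - onsets[i - 1] < 120.0:
                    raise SchedulingError(
                        f"same-category sets closer than 2 min at onset {onsets[i]}"
                    )


def _silent_gap_sizes(n_gaps: int, total: int, rng: np.random.Generator) -> list[int]:
    """Partition ``total`` silent blocks into gaps of size 3 or 4."""
    n_fours = total - 3 * n_gaps
    if not 0 <= n_fours <= n_gaps:
        raise SchedulingError(
            f"cannot split {total} silent blocks into {n_gaps} gaps of 3-4"
        )
    sizes = np.full(n_gaps, 3, dtype=int)
    sizes[rng.choice(n_gaps, size=n_fours, replace=False)] = 4
    return sizes.tolist()


def schedule_run(
    protocol: SparseProtocol,
    catalog: StimulusCatalog,
    seed: int = 0,
    run: int = 1,
    n_sets: int = 8,
) -> RunSchedule:
    """Deterministically schedule one run from a protocol and catalog.

    The 40 stimulus blocks form ``n_sets`` sets of 5 like-category
    presentations (the paper's unit of analysis is the aggregation of alike
    stimuli); category-to-set order and within-set exemplar order are drawn
    from ``seed``.  Silent blocks are placed as one leading gap plus one gap
    after every set, each 3 or 4 blocks, summing to the protocol's silent
    count.
    """
    p = protocol
    per_set, rem = divmod(p.n_stim_blocks, n_sets)
    if rem:
        raise SchedulingError(f"{p.n_stim_blocks} stimulus blocks not divisible into {n_sets} sets")
    cats = catalog.categories
    if len(cats) < n_sets:
        raise SchedulingError(f"catalog spans {len(cats)} categories; need >= {n_sets}")
    rng = np.random.default_rng(seed)
    # one category per set; enough exemplars per category required
    cat_order = cats.sample(n=n_sets, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    gap_sizes = _silent_gap_sizes(n_sets + 1, p.n_silent_blocks, rng)

    rows: list[dict] = []
    block = 0

    def add_silent(n: int) -> None:
        nonlocal block
        for _ in range(n):
            rows.append(
                {
                    "block": block,
                    "kind": "silent",
                    "stim_id": None,
                    "category": None,
                    "set_index": -1,
                    "onset": block * p.tr,
                    "stim_onset": np.nan,
                    "acq_onset": block * p.tr,  # volume acquired at block start in silence
                    "duration": p.tr,
                }
            )
            block += 1

    add_silent(gap_sizes[0])
    for s in range(n_sets):
        emotion, nb = cat_order.loc[s, "emotion"], cat_order.loc[s, "nb"]
        pool = catalog.entries[
            (catalog.entries["emotion"] == emotion) & (catalog.entries["nb"] == nb)
        ]["stim_id"].to_numpy()
        if len(pool) == 0:
            raise SchedulingError(f"no stimuli for category ({emotion}, {nb})")
        picks = rng.choice(pool, size=per_set, replace=len(pool) < per_set)
        for stim_id in picks:
            onset = block * p.tr
            rows.append(
                {
                    "block": block,
                    "kind": "stimulus",
                    "stim_id": stim_id,
                    "category": f"{emotion}_{nb}",
                    "set_index": s,
                    "onset": onset,
                    "stim_onset": onset,
                    "acq_onset": onset + p.stim_dur + p.gap_delay,
                    "duration": p.tr,
                }
            )
            block += 1
        add_silent(gap_sizes[s + 1])

    events = pd.DataFrame(rows)
    sched = RunSchedule(
        protocol=p,
        events=events,
        button_map=dict(BUTTON_MAPS[1 if run % 2 == 1 else 2]),
        run=run,
        seed=seed,
    )
    sched.validate()
    return sched


def gap_delay_grid(
    gap_delays: tuple[float, ...] = (1.0, 1.25, 1.5, 1.75, 2.0, 2.5, 3.0, 3.5),
    trs: tuple[float, ...] = (10.0, 11.0, 12.0, 13.0),
    **kwargs,
) -> list[SparseProtocol]:
    """Parameter grid of optimization-phase protocols (gap delay x TR sweep).

    The gap delay was swept 1-3.5 s (0.25/0.5 s steps) at TR = 13 s, and TR
    itself was varied 10-13 s; HRF-robustness evaluation of these trials on
    real BOLD data is out of scope — this only enumerates the candidates.
    """
    grid = []
    for tr in trs:
        for gd in gap_delays:
            grid.append(build_protocol(tr=tr, gap_delay=gd, post_silence=8.0, **kwargs))
    return grid
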