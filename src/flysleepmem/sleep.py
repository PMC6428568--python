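"""Sleep scoring from per-minute activity counts.

Fly sleep is scored with the standard DAM (Drosophila Activity Monitor)
convention: any period of complete inactivity (zero beam-break counts)
lasting at least 5 consecutive minutes is sleep; shorter quiet runs are
wake.  Scored bouts are summarized as 30-min binned sleep profiles and as
total sleep within an analysis window (e.g. hours 7-10 after training
onset), compared between groups with a Student t-test.

Bouts that straddle a bin edge or the analysis window are attributed by
overlap: each bin or window receives exactly the minutes of the bout that
fall inside it.  A zero-run touching the start or end of the record counts
as sleep if its observed length reaches the threshold (no censoring
correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from flysleepmem._common import GroupComparison, TimeWindow, group_ttest
from flysleepmem.exceptions import ValidationError

__all__ = [
    "ActivityTrace",
    "SleepBout",
    "SleepProfile",
    "TimeWindow",
    "score_sleep",
    "sleep_profile",
    "total_sleep_in_window",
    "compare_group_sleep",
    "light_phase",
]

MIN_BOUT_MIN_DEFAULT = 5


@dataclass
class ActivityTrace:
    """Per-minute beam-break counts of one fly, anchored to training onset.

    ``counts[i]`` is the activity in minute ``t0_min + i``.
    """

    fly_id: str
    t0_min: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size < 1:
            raise ValidationError("counts must be a non-empty 1-D sequence")
        if not np.issubdtype(counts.dtype, np.integer):
            as_int = counts.astype(np.int64)
            if not np.array_equal(as_int, counts):
                raise ValidationError("counts must be integers")
            counts = as_int
        if counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        self.counts = counts

    @property
    def duration_min(self) -> int:
        return int(self.counts.size)

    @property
    def end_min(self) -> int:
        return self.t0_min + self.duration_min


@dataclass(frozen=True)
class SleepBout:
    """One sleep bout, half-open [start_min, end_min) from training onset."""

    start_min: int
    end_min: int
    censored: bool = False  # touches the start or end of the record

    def __post_init__(self) -> None:
        if self.end_min <= self.start_min:
            raise ValidationError("bout must have positive length")

    @property
    def length_min(self) -> int:
        return self.end_min - self.start_min

    def overlap_min(self, start_min: float, end_min: float) -> float:
        """Minutes of this bout inside [start_min, end_min)."""
        return max(0.0, min(self.end_min, end_min) - max(self.start_min, start_min))


@dataclass
class SleepProfile:
    """Minutes asleep per uniform time bin (half-open bins)."""

    bin_edges_min: np.ndarray  # length n_bins + 1
    minutes_asleep: np.ndarray  # length n_bins

    @property
    def bin_min(self) -> float:
        return float(self.bin_edges_min[1] - self.bin_edges_min[0])

    @property
    def bin_centers_hr(self) -> np.ndarray:
        mids = (self.bin_edges_min[:-1] + self.bin_edges_min[1:]) / 2.0
        return mids / 60.0


def score_sleep(
    trace: ActivityTrace, min_bout_min: int = MIN_BOUT_MIN_DEFAULT
) -> list[SleepBout]:
    """Score sleep bouts: maximal zero-count runs of length >= ``min_bout_min``.

    Deterministic and idempotent; an empty list is a valid result.
    """
    if min_bout_min < 1:
        raise ValidationError("min_bout_min must be >= 1")
    quiet = (trace.counts == 0).astype(np.int8)
    # run boundaries via the discrete derivative of the padded quiet mask
    d = np.diff(np.concatenate([[0], quiet, [0]]))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    bouts = []
    for s, e in zip(starts, ends):
        if e - s >= min_bout_min:
            censored = s == 0 or e == trace.duration_min
            bouts.append(
                SleepBout(trace.t0_min + int(s), trace.t0_min + int(e), censored)
            )
    return bouts


def sleep_profile(
    bouts: list[SleepBout], window: TimeWindow, bin_min: float = 30.0
) -> SleepProfile:
    """Bin sleep into uniform ``bin_min``-minute bins over ``window``.

    Bouts straddling a bin edge are split by overlap, so the profile sum
    equals total scored sleep clipped to the window.
    """
    span = window.end_min - window.start_min
    n_bins = span / bin_min
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValidationError(
            f"window of {span} min is not divisible into {bin_min}-min bins"
        )
    n_bins = int(round(n_bins))
    edges = window.start_min + bin_min * np.arange(n_bins + 1)
    minutes = np.zeros(n_bins)
    for bout in bouts:
        lo = np.maximum(edges[:-1], bout.start_min)
        hi = np.minimum(edges[1:], bout.end_min)
        minutes += np.maximum(0.0, hi - lo)
    return SleepProfile(bin_edges_min=edges, minutes_asleep=minutes)


def total_sleep_in_window(bouts: list[SleepBout], window: TimeWindow) -> float:
    """Total minutes of scored sleep overlapping ``window`` (overlap-clipped)."""
    return float(sum(b.overlap_min(window.start_min, window.end_min) for b in bouts))


def compare_group_sleep(group_a, group_b) -> GroupComparison:
    """Equal-variance Student t-test on per-fly windowed sleep totals."""
    return group_ttest(group_a, group_b)


def light_phase(
    t_min: float, lights_on_min: float = 0.0, day_min: float = 720.0,
    period_min: float = 1440.0,
) -> str:
    """Annotate a timepoint as ``"day"`` or ``"night"`` under a light cycle.

    Default is 12:12 with lights-on at training onset; reporting only, no
    computation depends on it.
    """
    phase = (t_min - lights_on_min) % period_min
    return "day" if phase < day_min else "night"
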