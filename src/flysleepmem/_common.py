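"""Shared small types: analysis time windows and two-sample comparisons."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from flysleepmem.exceptions import ValidationError, ZeroVarianceError


@dataclass(frozen=True)
class TimeWindow:
    """Half-open analysis window [start_hr, end_hr) in hours from training onset."""

    start_hr: float
    end_hr: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_hr < self.end_hr):
            raise ValidationError(
                f"need 0 <= start_hr < end_hr, got [{self.start_hr}, {self.end_hr})"
            )

    @property
    def start_min(self) -> float:
        return self.start_hr * 60.0

    @property
    def end_min(self) -> float:
        return self.end_hr * 60.0

    @property
    def duration_hr(self) -> float:
        return self.end_hr - self.start_hr

    @classmethod
    def parse(cls, text: str) -> "TimeWindow":
        """Parse ``"7:10"`` or ``"7-10"`` into hours."""
        for sep in (":", "-"):
            if sep in text:
                a, b = text.split(sep, 1)
                return cls(float(a), float(b))
        raise ValidationError(f"cannot parse time window {text!r}; use start:end hours")


@dataclass(frozen=True)
class GroupComparison:
    """Equal-variance two-sample Student t-test with per-group mean +/- SEM."""

    t_statistic: float
    p_value: float
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int

    def to_dict(self) -> dict:
        return {
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "group_a": {"mean": self.mean_a, "sem": self.sem_a, "n": self.n_a},
            "group_b": {"mean": self.mean_b, "sem": self.sem_b, "n": self.n_b},
            "test": "student_t_equal_var",
        }


def group_ttest(group_a, group_b) -> GroupComparison:
    """Two-sample Student t-test (equal variance) on per-fly / per-well scalars.

    Raises :class:`ZeroVarianceError` when neither group has any within-group
    variance, in which case no t-statistic exists.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("non-finite values in comparison groups")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ZeroVarianceError("zero variance in both groups; t-test undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        t_statistic=float(t),
        p_value=float(p),
        mean_a=float(a.mean()),
        sem_a=float(stats.sem(a)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sem_b=float(stats.sem(b)),
        n_b=int(b.size),
    )
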