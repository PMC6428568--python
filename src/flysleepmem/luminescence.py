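"""Activity-reporter luminescence normalized against genetic controls.

An activity-dependent luciferase reporter read in a 96-well plate every
15 min over 16 h proxies neuronal activity in freely behaving flies.
Relative luminescence is each well's reading divided by the center (mean by
default) of the genetic-control wells at the same timepoint; group
differences are assessed on windowed totals with a Student t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from flysleepmem._common import GroupComparison, TimeWindow, group_ttest
from flysleepmem.exceptions import ValidationError

logger = logging.getLogger(__name__)

GROUPS = ("experienced", "naive", "control")

#: Nominal sampling interval of the plate reader, hours.
SAMPLING_INTERVAL_HR = 0.25


@dataclass
class LuminescencePlate:
    """Per-well reporter readings on a shared uniform timepoint grid.

    ``readings`` is a DataFrame indexed by well_id with one column per
    timepoint; ``groups`` maps well_id to experienced / naive / control;
    ``timepoints_hr`` are hours from training onset at 15-min spacing.
    """

    readings: pd.DataFrame
    groups: pd.Series
    timepoints_hr: np.ndarray

    def __post_init__(self) -> None:
        self.timepoints_hr = np.asarray(self.timepoints_hr, dtype=float)
        if self.readings.shape[1] != self.timepoints_hr.size:
            raise ValidationError("readings columns must match timepoints")
        if not self.readings.index.equals(self.groups.index):
            raise ValidationError("groups index must match readings wells")
        bad = set(self.groups) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group labels {sorted(bad)}")
        if not (self.groups == "control").any():
            raise ValidationError("plate needs at least one control well")
        if self.timepoints_hr.size >= 2:
            steps = np.diff(self.timepoints_hr)
            if np.any(np.abs(steps - steps[0]) > SAMPLING_INTERVAL_HR / 2):
                raise ValidationError("timepoint grid is not uniform")
        vals = self.readings.to_numpy(float)
        finite = vals[np.isfinite(vals)]
        if finite.size and finite.min() < 0:
            raise ValidationError("readings must be >= 0")

    def wells(self, group: str) -> list:
        return list(self.groups.index[self.groups == group])


@dataclass
class RelativeLuminescenceSeries:
    """Per-well relative (control-normalized) luminescence over time."""

    values: pd.DataFrame  # wells x timepoints, dimensionless
    groups: pd.Series
    timepoints_hr: np.ndarray
    control_center: np.ndarray  # per-timepoint control center used


def relative_luminescence(
    plate: LuminescencePlate, center: Literal["mean", "median"] = "mean"
) -> RelativeLuminescenceSeries:
    """Divide every well by the control-well center at each timepoint.

    Control wells are normalized to themselves too (values near 1) as a QC
    readout.  A control center that is zero or non-finite at any timepoint
    is an error naming that timepoint.
    """
    ctrl = plate.readings.loc[plate.groups == "control"].to_numpy(float)
    fn = np.mean if center == "mean" else np.median
    if center not in ("mean", "median"):
        raise ValidationError(f"center must be 'mean' or 'median', got {center!r}")
    ctrl_center = fn(ctrl, axis=0)
    bad = ~np.isfinite(ctrl_center) | (ctrl_center <= 0)
    if bad.any():
        t_bad = plate.timepoints_hr[bad][0]
        raise ValidationError(
            f"control center is zero or missing at timepoint {t_bad:g} hr"
        )
    values = plate.readings / ctrl_center
    return RelativeLuminescenceSeries(
        values=values,
        groups=plate.groups,
        timepoints_hr=plate.timepoints_hr,
        control_center=ctrl_center,
    )


def total_relative_luminescence(
    series: RelativeLuminescenceSeries, window: TimeWindow
) -> pd.Series:
    """Per-well sum of relative values at timepoints in [start_hr, end_hr).

    Wells with any missing reading inside the window are excluded (and
    logged), never imputed.
    """
    t = series.timepoints_hr
    in_win = (t >= window.start_hr) & (t < window.end_hr)
    if not in_win.any():
        raise ValidationError(
            f"window [{window.start_hr}, {window.end_hr}) hr contains no timepoints"
        )
    windowed = series.values.loc[:, in_win]
    complete = ~windowed.isna().any(axis=1)
    dropped = list(windowed.index[~complete])
    if dropped:
        logger.warning(
            "excluding %d wells with missing readings in window: %s",
            len(dropped), dropped,
        )
    return windowed.loc[complete].sum(axis=1)


def compare_luminescence(group_a, group_b) -> GroupComparison:
    """Equal-variance Student t-test on per-well windowed totals."""
    return group_ttest(group_a, group_b)


# ---------------------------------------------------------------------------
# CSV I/O


def read_plate_long_csv(path) -> LuminescencePlate:
    """Long format: columns well_id, group, timepoint_hr, reading."""
    df = pd.read_csv(path, dtype={"well_id": str, "group": str})
    need = {"well_id", "group", "timepoint_hr", "reading"}
    if not need.issubset(df.columns):
        raise ValidationError(f"long plate CSV needs columns {sorted(need)}")
    wide = df.pivot(index="well_id", columns="timepoint_hr", values="reading")
    wide = wide.sort_index(axis=1)
    groups = df.drop_duplicates("well_id").set_index("well_id")["group"]
    groups = groups.reindex(wide.index)
    timepoints = wide.columns.to_numpy(float)
    wide.columns = range(wide.shape[1])
    return LuminescencePlate(readings=wide, groups=groups, timepoints_hr=timepoints)


def read_plate_wide_csv(path, group_map_path) -> LuminescencePlate:
    """Wide layout: rows = wells, columns = timepoint hours; separate group map
    CSV with columns well_id, group."""
    wide = pd.read_csv(path, index_col=0)
    wide.index = wide.index.astype(str)
    timepoints = np.array([float(c) for c in wide.columns])
    gm = pd.read_csv(group_map_path, dtype=str).set_index("well_id")["group"]
    groups = gm.reindex(wide.index)
    if groups.isna().any():
        missing = list(groups.index[groups.isna()])
        raise ValidationError(f"wells missing from group map: {missing}")
    wide.columns = range(wide.shape[1])
    return LuminescencePlate(readings=wide, groups=groups, timepoints_hr=timepoints)


def write_plate_long_csv(plate: LuminescencePlate, path) -> None:
    rows = []
    for well in plate.readings.index:
        for j, t in enumerate(plate.timepoints_hr):
            rows.append((well, plate.groups[well], t, plate.readings.iat[
                plate.readings.index.get_loc(well), j]))
    pd.DataFrame(rows, columns=["well_id", "group", "timepoint_hr", "reading"]).to_csv(
        path, index=False
    )


def write_relative_series_csv(series: RelativeLuminescenceSeries, path) -> None:
    out = series.values.copy()
    out.columns = [f"{t:g}" for t in series.timepoints_hr]
    out.insert(0, "group", series.groups)
    out.to_csv(path, index_label="well_id")
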