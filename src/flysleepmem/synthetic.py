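"""Synthetic-data generators with retained ground truth.

Every downstream stage of the pipeline can be exercised, with known truth,
on data produced here:

- courtship populations: per-fly CIs drawn from a beta distribution scaled
  to [0, 100], with a trained-group suppression effect of known size;
- activity traces: alternating wake/sleep bouts with geometric
  (minute-resolution, memoryless) dwell times; sleep minutes have zero
  counts, wake minutes positive Poisson counts;
- luminescence plates: wells following a slowly ramping baseline with
  multiplicative log-normal noise, the experienced group elevated inside a
  time window;
- calcium movies: voxels inside labelled ROI masks respond to the LED drive
  as baseline * (1 + amplitude * V(t)) plus Gaussian noise, clipped at 0.

The distributional forms are modelling choices of this package (the real
assays publish no distributions); they are documented in the methods note
and chosen for the support and noise structure of each measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from flysleepmem._common import TimeWindow
from flysleepmem.calcium import CalciumMovie, StimulusProtocol
from flysleepmem.courtship import CourtshipTable
from flysleepmem.exceptions import ValidationError
from flysleepmem.luminescence import LuminescencePlate
from flysleepmem.sleep import ActivityTrace, SleepBout

__all__ = [
    "CourtshipSimSpec",
    "SleepSimSpec",
    "RoiSpec",
    "CalciumSimSpec",
    "generate_courtship_population",
    "generate_activity_trace",
    "apply_sleep_deprivation",
    "generate_luminescence_plate",
    "generate_calcium_movie",
    "default_baseline_curve",
]


# ---------------------------------------------------------------------------
# Courtship


@dataclass(frozen=True)
class CourtshipSimSpec:
    """Parameters of a simulated courtship-conditioning experiment.

    The trained-group expected CI is ``naive_mean_ci * (1 - true_si/100)``;
    ``dispersion`` is the beta concentration (a + b), larger = tighter.
    """

    n_trained: int
    n_naive: int
    naive_mean_ci: float = 60.0
    true_si: float = 40.0
    dispersion: float = 12.0
    seed: int = 0
    genotype: str = "wt"

    def __post_init__(self) -> None:
        if self.n_trained < 1 or self.n_naive < 1:
            raise ValidationError("group sizes must be >= 1")
        if not (0 < self.naive_mean_ci < 100):
            raise ValidationError("naive_mean_ci must lie in (0, 100)")
        if not (0 <= self.true_si < 100):
            raise ValidationError("true_si must lie in [0, 100)")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")

    @property
    def trained_mean_ci(self) -> float:
        return self.naive_mean_ci * (1.0 - self.true_si / 100.0)


def _beta_cis(mean_ci: float, dispersion: float, n: int,
              rng: np.random.Generator) -> np.ndarray:
    if not (0 < mean_ci < 100):
        raise ValidationError(f"group mean CI {mean_ci:g} outside (0, 100)")
    mu = mean_ci / 100.0
    a, b = mu * dispersion, (1 - mu) * dispersion
    return 100.0 * rng.beta(a, b, size=n)


def generate_courtship_population(spec: CourtshipSimSpec) -> CourtshipTable:
    """Draw a trained/naive CI table with the specified suppression effect."""
    rng = np.random.default_rng(spec.seed)
    trained = _beta_cis(spec.trained_mean_ci, spec.dispersion, spec.n_trained, rng)
    naive = _beta_cis(spec.naive_mean_ci, spec.dispersion, spec.n_naive, rng)
    return CourtshipTable.from_arrays(
        trained, naive, genotype=spec.genotype,
        fly_prefix=f"{spec.genotype}_s{spec.seed}",
    )


# ---------------------------------------------------------------------------
# Sleep


@dataclass(frozen=True)
class SleepSimSpec:
    """Two-state wake/sleep activity model at minute resolution.

    Dwell times in each state are geometric with the given means (support
    >= 1 min).  Wake minutes draw beam-break counts from a zero-truncated
    Poisson — a fly awake for a whole minute essentially always breaks the
    beam, and this keeps the generated sleep bouts exactly recoverable from
    the counts; ``truncate_wake_zeros=False`` restores a plain Poisson.
    """

    duration_min: int
    wake_activity_rate: float = 2.0
    mean_wake_min: float = 20.0
    mean_sleep_min: float = 15.0
    start_awake: bool = True
    truncate_wake_zeros: bool = True
    t0_min: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_min < 1:
            raise ValidationError("duration_min must be >= 1")
        if self.wake_activity_rate <= 0:
            raise ValidationError("wake_activity_rate must be positive")
        if self.mean_wake_min < 1 or self.mean_sleep_min < 1:
            raise ValidationError("mean dwell times must be >= 1 min")


def _zero_truncated_poisson(lam: float, size: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Poisson(lam) conditioned on being >= 1, by inverse CDF on U(e^-lam, 1)."""
    from scipy import stats as sps

    u = rng.uniform(np.exp(-lam), 1.0, size=size)
    return sps.poisson.ppf(u, lam).astype(np.int64)


def generate_activity_trace(
    spec: SleepSimSpec, fly_id: str = "fly0"
) -> tuple[ActivityTrace, list[SleepBout]]:
    """Simulate one fly's per-minute counts plus its ground-truth sleep bouts.

    Returns every generated sleep bout (including those shorter than the
    5-min scoring threshold), clipped to the trace extent.
    """
    rng = np.random.default_rng(spec.seed)
    counts = np.zeros(spec.duration_min, dtype=np.int64)
    truth: list[SleepBout] = []
    t = 0
    awake = spec.start_awake
    while t < spec.duration_min:
        mean = spec.mean_wake_min if awake else spec.mean_sleep_min
        dwell = int(rng.geometric(1.0 / mean))
        end = min(t + dwell, spec.duration_min)
        if awake:
            n = end - t
            if spec.truncate_wake_zeros:
                counts[t:end] = _zero_truncated_poisson(
                    spec.wake_activity_rate, n, rng
                )
            else:
                counts[t:end] = rng.poisson(spec.wake_activity_rate, size=n)
        else:
            truth.append(SleepBout(spec.t0_min + t, spec.t0_min + end,
                                   censored=(t == 0 or end == spec.duration_min)))
        t = end
        awake = not awake
    trace = ActivityTrace(fly_id=fly_id, t0_min=spec.t0_min, counts=counts)
    return trace, truth


def apply_sleep_deprivation(
    trace: ActivityTrace, window: TimeWindow, max_quiet_min: int = 3
) -> ActivityTrace:
    """Emulate mechanical sleep deprivation inside a time window.

    Inside the window, whenever a run of zero-count minutes (counted from
    its true start, also before the window) reaches ``max_quiet_min``, a
    single count is inserted; the last minute of the window is always
    perturbed if quiet.  With ``max_quiet_min < 5`` no 5-min inactivity run
    can overlap the window, so scored sleep inside it is zero.  Minutes
    outside the window are untouched.
    """
    if not (1 <= max_quiet_min < 5):
        raise ValidationError("max_quiet_min must be in [1, 5)")
    w_start = int(round(window.start_min)) - trace.t0_min
    w_end = int(round(window.end_min)) - trace.t0_min
    if w_start < 0 or w_end > trace.duration_min:
        raise ValidationError("deprivation window outside the trace extent")
    counts = trace.counts.copy()
    run = 0
    for i in range(w_end):
        if counts[i] == 0:
            run += 1
            in_window = i >= w_start
            if in_window and (run >= max_quiet_min or i == w_end - 1):
                counts[i] = 1
                run = 0
        else:
            run = 0
    return ActivityTrace(fly_id=trace.fly_id, t0_min=trace.t0_min, counts=counts)


# ---------------------------------------------------------------------------
# Luminescence


def default_baseline_curve(t_hr: np.ndarray) -> np.ndarray:
    """Slowly ramping reporter baseline: 1000 counts rising 3%/h."""
    return 1000.0 * (1.0 + 0.03 * np.asarray(t_hr, dtype=float))


def generate_luminescence_plate(
    n_exp: int,
    n_naive: int,
    n_control: int,
    baseline_curve: Callable[[np.ndarray], np.ndarray] = default_baseline_curve,
    exp_elevation: float = 0.5,
    elevation_window: TimeWindow = TimeWindow(7.0, 10.0),
    noise_cv: float = 0.1,
    seed: int = 0,
    n_timepoints: int = 64,
    t_start_hr: float = 0.0,
    interval_hr: float = 0.25,
) -> LuminescencePlate:
    """Simulate a reporter plate read every 15 min (64 timepoints = 16 h).

    Control and naive wells follow ``baseline_curve`` with multiplicative
    mean-one log-normal noise of the stated CV; experienced wells are
    multiplied by ``1 + exp_elevation`` only at timepoints inside
    ``elevation_window``.  ``noise_cv = 0`` gives a deterministic plate.
    """
    if n_control < 1:
        raise ValidationError("plate needs at least one control well")
    if n_exp < 1 or n_naive < 1:
        raise ValidationError("group sizes must be >= 1")
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    t = t_start_hr + interval_hr * np.arange(n_timepoints)
    base = np.asarray(baseline_curve(t), dtype=float)
    if base.shape != t.shape or np.any(base <= 0):
        raise ValidationError("baseline_curve must return positive values per timepoint")
    elev = np.where(
        (t >= elevation_window.start_hr) & (t < elevation_window.end_hr),
        1.0 + exp_elevation, 1.0,
    )

    def noise(n_wells: int) -> np.ndarray:
        if noise_cv == 0:
            return np.ones((n_wells, t.size))
        sigma = np.sqrt(np.log1p(noise_cv**2))
        return rng.lognormal(-sigma**2 / 2.0, sigma, size=(n_wells, t.size))

    rows, groups, wells = [], [], []
    for group, n, mult in (
        ("experienced", n_exp, elev),
        ("naive", n_naive, np.ones_like(t)),
        ("control", n_control, np.ones_like(t)),
    ):
        block = base * mult * noise(n)
        for i in range(n):
            wells.append(f"{group[:3]}{i:02d}")
            groups.append(group)
            rows.append(block[i])
    readings = pd.DataFrame(np.vstack(rows), index=wells)
    return LuminescencePlate(
        readings=readings,
        groups=pd.Series(groups, index=wells),
        timepoints_hr=t,
    )


# ---------------------------------------------------------------------------
# Calcium


@dataclass(frozen=True)
class RoiSpec:
    """A labelled responsive voxel set: response = amplitude * V(t) as a
    fraction of baseline; negative amplitude = inhibited."""

    label: str
    mask: np.ndarray  # boolean (z, y, x)
    amplitude: float


@dataclass(frozen=True)
class CalciumSimSpec:
    """Stimulus-locked volumetric movie model.

    Voxel (t, v) inside a responsive mask has expected intensity
    ``baseline * (1 + amplitude * V(t))``; all voxels get iid Gaussian noise
    of sd ``noise_sd`` and are clipped at zero.
    """

    volume_shape: tuple[int, int, int] = (4, 8, 8)
    n_volumes: int = 120
    volume_rate_hz: float = 1.0
    baseline_intensity: float = 100.0
    roi_masks: tuple[RoiSpec, ...] = ()
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes < 2 or self.volume_rate_hz <= 0:
            raise ValidationError("need >= 2 volumes and a positive rate")
        if self.baseline_intensity <= 0 or self.noise_sd < 0:
            raise ValidationError("baseline must be > 0 and noise_sd >= 0")
        for roi in self.roi_masks:
            if np.asarray(roi.mask).shape != tuple(self.volume_shape):
                raise ValidationError(
                    f"mask {roi.label!r} does not match volume shape"
                )


def generate_calcium_movie(
    spec: CalciumSimSpec, protocol: StimulusProtocol
) -> tuple[CalciumMovie, dict]:
    """Simulate a movie under the pulse protocol; returns ground truth too.

    Ground truth holds the drive model V(t) and, per ROI, its mask and
    amplitude, so mapping and connectivity outputs can be checked without
    re-deriving them.
    """
    if protocol.duration_s > spec.n_volumes / spec.volume_rate_hz:
        raise ValidationError("protocol longer than the movie")
    rng = np.random.default_rng(spec.seed)
    v = protocol.drive(spec.n_volumes, spec.volume_rate_hz)
    amp = np.zeros(spec.volume_shape)
    for roi in spec.roi_masks:
        amp[np.asarray(roi.mask, dtype=bool)] = roi.amplitude
    clean = spec.baseline_intensity * (
        1.0 + amp[None, ...] * v[:, None, None, None]
    )
    if spec.noise_sd > 0:
        clean = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
    data = np.clip(clean, 0.0, None)
    movie = CalciumMovie(
        data=data,
        volume_rate_hz=spec.volume_rate_hz,
        meta={"z_step_um": 3.0, "frames_per_volume": spec.volume_shape[0]},
    )
    truth = {
        "drive": v,
        "rois": [
            {"label": r.label, "mask": np.asarray(r.mask, dtype=bool),
             "amplitude": r.amplitude}
            for r in spec.roi_masks
        ],
        "baseline": spec.baseline_intensity,
        "noise_sd": spec.noise_sd,
    }
    return movie, truth
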