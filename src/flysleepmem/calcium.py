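"""Optogenetic calcium-imaging analysis for explant-brain recordings.

A volumetric two-photon movie (~1 Hz volume rate) records a GCaMP signal
while a target neuron class expressing a red-shifted channelrhodopsin is
driven with a pulse train — by default six pulses of 8 s (100% duty cycle)
separated by 30 s off periods.  The analysis chain is:

1. ROI trace: per-volume mean intensity over a voxel mask, f(t).
2. dF/F = (f(t) - F0)/F0 with F0 the mean of the first 10 s of the session
   (before the first pulse).
3. Epoch alignment: the dF/F trace is cut into one epoch per pulse, from
   10 s before LED onset through pulse offset, and averaged across epochs.
4. Connectivity call: per fly, the mean dF/F of the 10 s pre-stimulation
   baseline and the mean dF/F during stimulation are compared across flies
   (Wilcoxon rank sum by default); p < 0.05 declares connectivity, with the
   direction (excitatory / inhibitory) given by the sign of the median
   stimulation-minus-baseline difference.
5. Voxel-wise R2 map: each voxel trace is z-scored, linearly fit to the
   LED drive model V(t), and the squared Pearson correlation between trace
   and fit is stored; the map is projected to a 16-bit stack for display.

R2 is symmetric in sign, so inhibited voxels map as strongly as excited
ones.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from flysleepmem.exceptions import ValidationError, ZeroVarianceError

logger = logging.getLogger(__name__)

__all__ = [
    "CalciumMovie",
    "StimulusProtocol",
    "RoiTrace",
    "DffTrace",
    "EpochSet",
    "ConnectivityCall",
    "R2Volume",
    "extract_roi_trace",
    "dff",
    "align_epochs",
    "connectivity_test",
    "zscore",
    "voxel_r2_map",
    "r2_to_uint16_stack",
]


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class CalciumMovie:
    """Time-ordered intensity volumes, axis order (time, z, y, x)."""

    data: np.ndarray
    volume_rate_hz: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValidationError("movie data must be 4-D (time, z, y, x)")
        if self.data.shape[0] < 2:
            raise ValidationError("movie needs at least 2 timepoints")
        if self.volume_rate_hz <= 0:
            raise ValidationError("volume_rate_hz must be positive")

    @property
    def n_volumes(self) -> int:
        return int(self.data.shape[0])

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[1:])

    @property
    def duration_s(self) -> float:
        return self.n_volumes / self.volume_rate_hz


@dataclass(frozen=True)
class StimulusProtocol:
    """LED pulse train: ``n_pulses`` pulses of ``pulse_dur_s`` at 100% duty,
    with ``ipi_s`` between each pulse's offset and the next onset, after
    ``pre_s`` of darkness.

    The drive model V(t) samples the train at the volume rate: 1 during a
    pulse, 0 otherwise (the LED drive voltage rescaled to [0, 1]).
    """

    pre_s: float = 10.0
    n_pulses: int = 6
    pulse_dur_s: float = 8.0
    ipi_s: float = 30.0

    def __post_init__(self) -> None:
        if self.pre_s < 0 or self.n_pulses < 1 or self.pulse_dur_s <= 0:
            raise ValidationError("invalid stimulus protocol")
        if self.n_pulses > 1 and self.ipi_s <= 0:
            raise ValidationError("pulses would overlap: ipi_s must be > 0")

    @property
    def onsets_s(self) -> np.ndarray:
        return self.pre_s + np.arange(self.n_pulses) * (self.pulse_dur_s + self.ipi_s)

    @property
    def offsets_s(self) -> np.ndarray:
        return self.onsets_s + self.pulse_dur_s

    @property
    def duration_s(self) -> float:
        return float(self.offsets_s[-1])

    def drive(self, n_samples: int, rate_hz: float) -> np.ndarray:
        """V(t) sampled at ``rate_hz`` for ``n_samples`` volumes (sample i at
        time i / rate)."""
        t = np.arange(n_samples) / rate_hz
        v = np.zeros(n_samples)
        for on, off in zip(self.onsets_s, self.offsets_s):
            v[(t >= on) & (t < off)] = 1.0
        return v

    def to_json(self, path, rate_hz: float | None = None) -> None:
        payload = {
            "schema_version": 1,
            "pre_s": self.pre_s,
            "n_pulses": self.n_pulses,
            "pulse_dur_s": self.pulse_dur_s,
            "ipi_s": self.ipi_s,
        }
        if rate_hz is not None:
            payload["rate_hz"] = rate_hz
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StimulusProtocol":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            pre_s=d["pre_s"],
            n_pulses=d["n_pulses"],
            pulse_dur_s=d["pulse_dur_s"],
            ipi_s=d["ipi_s"],
        )


@dataclass
class RoiTrace:
    """Mean-intensity time series f(t) over an ROI."""

    f: np.ndarray
    roi_label: str = "roi"
    fly_id: str = ""

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.ndim != 1 or self.f.size < 2:
            raise ValidationError("trace must be 1-D with >= 2 samples")


@dataclass
class DffTrace:
    """Fractional fluorescence change (f - F0)/F0 and its baseline F0."""

    dff: np.ndarray
    f0: float
    rate_hz: float


@dataclass
class EpochSet:
    """Pulse-aligned dF/F epochs (rows) and their across-epoch mean trace.

    Columns 0..pre_samples-1 precede LED onset; the remaining
    ``stim_samples`` columns span the pulse.
    """

    epochs: np.ndarray  # n_pulses x (pre_samples + stim_samples)
    pre_samples: int
    stim_samples: int
    rate_hz: float

    @property
    def mean_trace(self) -> np.ndarray:
        return self.epochs.mean(axis=0)

    def baseline_mean(self) -> float:
        """Mean of the epoch-averaged trace over the pre-stimulation window."""
        return float(self.mean_trace[: self.pre_samples].mean())

    def stim_mean(self) -> float:
        """Mean of the epoch-averaged trace during stimulation."""
        return float(self.mean_trace[self.pre_samples :].mean())


@dataclass
class ConnectivityCall:
    """Outcome of the across-fly baseline-vs-stimulation comparison."""

    per_fly: list[tuple[float, float]]  # (baseline_mean, stim_mean)
    p_value: float
    direction: Literal["excitatory", "inhibitory", "none"]
    test: str
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "per_fly": [
                {"baseline_mean": b, "stim_mean": s} for b, s in self.per_fly
            ],
            "p_value": self.p_value,
            "direction": self.direction,
            "test": self.test,
            "alpha": self.alpha,
        }


@dataclass
class R2Volume:
    """Voxel-wise correlation of determination, shape (z, y, x), in [0, 1]."""

    r2: np.ndarray
    n_invalid: int = 0  # voxels zeroed by the NaN policy or zero variance

    def __post_init__(self) -> None:
        if self.r2.ndim != 3:
            raise ValidationError("r2 volume must be 3-D (z, y, x)")


# ---------------------------------------------------------------------------
# Operations


def _as_mask(mask, volume_shape) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype != bool:
        mask = mask.astype(bool)
    if mask.shape != tuple(volume_shape):
        raise ValidationError(
            f"mask shape {mask.shape} does not match volume {tuple(volume_shape)}"
        )
    return mask


def extract_roi_trace(
    movie: CalciumMovie, mask, roi_label: str = "roi", fly_id: str = ""
) -> RoiTrace:
    """Per-volume mean intensity over the mask voxels."""
    mask = _as_mask(mask, movie.volume_shape)
    if not mask.any():
        raise ValidationError("ROI mask is empty")
    f = movie.data[:, mask].mean(axis=1)
    return RoiTrace(f=f, roi_label=roi_label, fly_id=fly_id)


def dff(
    trace: RoiTrace | np.ndarray,
    rate_hz: float,
    f0_window_s: float = 10.0,
    first_pulse_onset_s: float | None = None,
) -> DffTrace:
    """dF/F = (f(t) - F0)/F0, F0 = mean of the first ``f0_window_s`` seconds.

    The baseline window must contain at least one sample and, when the first
    pulse onset is given, end at or before it.  F0 must be positive.
    """
    f = trace.f if isinstance(trace, RoiTrace) else np.asarray(trace, dtype=float)
    if rate_hz <= 0:
        raise ValidationError("rate_hz must be positive")
    n0 = int(round(f0_window_s * rate_hz))
    if n0 < 1:
        raise ValidationError("F0 window contains no samples")
    if n0 > f.size:
        raise ValidationError("F0 window longer than the trace")
    if first_pulse_onset_s is not None and f0_window_s > first_pulse_onset_s:
        raise ValidationError("F0 window extends into the stimulation period")
    f0 = float(f[:n0].mean())
    if f0 <= 0:
        raise ValidationError(f"F0 must be positive, got {f0}")
    return DffTrace(dff=(f - f0) / f0, f0=f0, rate_hz=rate_hz)


def _onset_index(t_s: float, rate_hz: float) -> int:
    """First sample at or after a nominal time (sample i at time i/rate)."""
    return int(math.ceil(t_s * rate_hz - 1e-9))


def align_epochs(
    dff_trace: DffTrace, protocol: StimulusProtocol, pre_s: float = 10.0
) -> EpochSet:
    """Cut one epoch per pulse: ``pre_s`` before LED onset through pulse offset.

    Nominal onset times map to the first sample at or after the onset; all
    epochs must lie inside the trace.
    """
    rate = dff_trace.rate_hz
    x = dff_trace.dff
    pre_n = int(round(pre_s * rate))
    stim_n = int(round(protocol.pulse_dur_s * rate))
    if stim_n < 1:
        raise ValidationError("pulse shorter than one sample")
    rows = []
    for onset in protocol.onsets_s:
        i0 = _onset_index(onset, rate)
        lo, hi = i0 - pre_n, i0 + stim_n
        if lo < 0 or hi > x.size:
            raise ValidationError(
                f"epoch [{lo}, {hi}) around onset {onset:g} s is outside the trace"
            )
        rows.append(x[lo:hi])
    return EpochSet(
        epochs=np.vstack(rows), pre_samples=pre_n, stim_samples=stim_n, rate_hz=rate
    )


def connectivity_test(
    per_fly_epochs: Sequence[EpochSet],
    test: Literal["wilcoxon_rank_sum", "student_t", "wilcoxon_signed_rank"]
    = "wilcoxon_rank_sum",
    alpha: float = 0.05,
) -> ConnectivityCall:
    """Across-fly test of stimulated vs baseline dF/F.

    Per fly, the baseline mean (10 s pre-stimulation) and stimulation mean of
    the epoch-averaged dF/F trace form one (baseline, stim) pair.  The two
    across-fly samples are compared with the selected test; p < ``alpha``
    declares connectivity, with direction from the sign of the median paired
    difference.  The rank-sum and t options treat the samples as independent,
    as in common practice; the paired signed-rank alternative is available.
    """
    if len(per_fly_epochs) < 3:
        raise ValidationError("connectivity test needs >= 3 flies")
    pairs = [(es.baseline_mean(), es.stim_mean()) for es in per_fly_epochs]
    base = np.array([b for b, _ in pairs])
    stim = np.array([s for _, s in pairs])
    diffs = stim - base
    if np.all(diffs == 0):
        return ConnectivityCall(pairs, 1.0, "none", test, alpha)
    if test == "wilcoxon_rank_sum":
        res = stats.mannwhitneyu(stim, base, alternative="two-sided", method="exact")
        p = float(res.pvalue)
    elif test == "student_t":
        p = float(stats.ttest_ind(stim, base, equal_var=True).pvalue)
    elif test == "wilcoxon_signed_rank":
        p = float(stats.wilcoxon(stim, base, alternative="two-sided").pvalue)
    else:
        raise ValidationError(f"unknown test {test!r}")
    if p < alpha:
        direction = "excitatory" if float(np.median(diffs)) > 0 else "inhibitory"
    else:
        direction = "none"
    return ConnectivityCall(pairs, p, direction, test, alpha)


def zscore(trace: np.ndarray) -> np.ndarray:
    """Z(t) = (f(t) - mu)/sigma with the population (divide-by-T) sd.

    The sd convention cancels in the downstream correlation ratio, so R2 is
    identical under either convention.
    """
    x = np.asarray(trace, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ZeroVarianceError("cannot z-score a constant trace")
    return (x - x.mean()) / sd


def voxel_r2_map(movie: CalciumMovie, protocol: StimulusProtocol) -> R2Volume:
    """Voxel-wise correlation of determination against the LED drive V(t).

    Each voxel trace is z-scored and fit (slope + intercept) to V(t); the
    predicted response Zp(t) is the fitted line, and r = cov(Z, Zp)/(sZ*sZp).
    Because Zp is affine in V(t), r equals the Pearson correlation between
    the raw voxel trace and V(t) up to sign, and R2 = r^2 is its square.
    Zero-variance voxels and voxels with any non-finite sample get R2 = 0.
    """
    T = movie.n_volumes
    v = protocol.drive(T, movie.volume_rate_hz)
    if np.ptp(v) == 0:
        raise ValidationError(
            "V(t) is constant over the movie; no pulse falls inside the recording"
        )
    X = movie.data.reshape(T, -1)
    finite = np.all(np.isfinite(X), axis=0)
    Xc = np.where(finite, X, 0.0) - np.where(finite, X, 0.0).mean(axis=0)
    vc = v - v.mean()
    cov = vc @ Xc / T
    sx = Xc.std(axis=0, ddof=0)
    sv = vc.std(ddof=0)
    valid = finite & (sx > 0)
    r2 = np.zeros(X.shape[1])
    r2[valid] = (cov[valid] / (sx[valid] * sv)) ** 2
    # squared correlations can exceed 1 by rounding only
    np.clip(r2, 0.0, 1.0, out=r2)
    n_invalid = int(np.count_nonzero(~valid))
    if n_invalid:
        logger.info("voxel_r2_map: %d voxels invalid (non-finite or constant)",
                    n_invalid)
    return R2Volume(r2=r2.reshape(movie.volume_shape), n_invalid=n_invalid)


def r2_to_uint16_stack(r2: R2Volume | np.ndarray) -> np.ndarray:
    """Project an R2 volume to a 16-bit stack: [0, 1] -> [0, 65535] linearly,
    rounded half-up."""
    arr = r2.r2 if isinstance(r2, R2Volume) else np.asarray(r2, dtype=float)
    if not np.all(np.isfinite(arr)) or arr.min() < 0 or arr.max() > 1:
        raise ValidationError("R2 values must be finite and within [0, 1]")
    return np.floor(arr * 65535.0 + 0.5).astype(np.uint16)
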