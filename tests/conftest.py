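import numpy as np
import pytest

from flysleepmem.calcium import StimulusProtocol
from flysleepmem.synthetic import CalciumSimSpec, RoiSpec


@pytest.fixture
def six_pulse_protocol() -> StimulusProtocol:
    """The default stimulation protocol: six 8-s pulses, 30-s inter-pulse
    interval, 10 s of darkness first."""
    return StimulusProtocol(pre_s=10.0, n_pulses=6, pulse_dur_s=8.0, ipi_s=30.0)


@pytest.fixture
def small_roi_mask() -> np.ndarray:
    mask = np.zeros((4, 8, 8), dtype=bool)
    mask[1:3, 2:6, 2:6] = True
    return mask


@pytest.fixture
def responsive_movie_spec(small_roi_mask) -> CalciumSimSpec:
    return CalciumSimSpec(
        volume_shape=(4, 8, 8),
        n_volumes=220,
        roi_masks=(RoiSpec("gamma5", small_roi_mask, amplitude=0.5),),
        noise_sd=2.0,
        seed=7,
    )
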