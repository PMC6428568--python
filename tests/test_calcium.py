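"""dF/F, epoch alignment, connectivity calls and the voxel R2 map."""

import numpy as np
import pytest
from scipy import stats

from flysleepmem.calcium import (
    CalciumMovie,
    EpochSet,
    RoiTrace,
    StimulusProtocol,
    align_epochs,
    connectivity_test,
    dff,
    extract_roi_trace,
    r2_to_uint16_stack,
    voxel_r2_map,
    zscore,
)
from flysleepmem.exceptions import ValidationError, ZeroVarianceError
from flysleepmem.synthetic import CalciumSimSpec, RoiSpec, generate_calcium_movie


def movie_from(data, rate=1.0):
    return CalciumMovie(data=np.asarray(data, dtype=float), volume_rate_hz=rate)


# ---------------------------------------------------------------------------
# Protocol / drive model


def test_drive_model_samples_pulse_train(six_pulse_protocol):
    v = six_pulse_protocol.drive(220, 1.0)
    # first pulse: samples 10..17 inclusive (8 s at 1 Hz, onset at 10 s)
    assert v[:10].sum() == 0
    assert v[10:18].sum() == 8
    assert v[18:40].sum() == 0
    assert v.sum() == 6 * 8
    onsets = six_pulse_protocol.onsets_s
    assert np.allclose(np.diff(onsets), 38.0)  # 8 s pulse + 30 s gap


def test_protocol_json_roundtrip(tmp_path, six_pulse_protocol):
    path = tmp_path / "protocol.json"
    six_pulse_protocol.to_json(path, rate_hz=1.0)
    assert StimulusProtocol.from_json(path) == six_pulse_protocol


# ---------------------------------------------------------------------------
# ROI extraction


def test_uniform_movie_gives_constant_trace():
    data = np.full((5, 2, 3, 3), 7.0)
    mask = np.ones((2, 3, 3), bool)
    assert np.allclose(extract_roi_trace(movie_from(data), mask).f, 7.0)


def test_single_voxel_mask_is_identity():
    rng = np.random.default_rng(0)
    data = rng.uniform(1, 10, (6, 2, 2, 2))
    mask = np.zeros((2, 2, 2), bool)
    mask[1, 0, 1] = True
    assert np.allclose(extract_roi_trace(movie_from(data), mask).f,
                       data[:, 1, 0, 1])


def test_union_of_equal_masks_averages_traces():
    rng = np.random.default_rng(1)
    data = rng.uniform(1, 10, (6, 2, 4, 4))
    m1 = np.zeros((2, 4, 4), bool)
    m2 = np.zeros((2, 4, 4), bool)
    m1[0, :2, :2] = True  # 4 voxels
    m2[1, 2:, 2:] = True  # 4 voxels
    movie = movie_from(data)
    t1 = extract_roi_trace(movie, m1).f
    t2 = extract_roi_trace(movie, m2).f
    tu = extract_roi_trace(movie, m1 | m2).f
    assert np.allclose(tu, (t1 + t2) / 2)


def test_empty_mask_rejected():
    with pytest.raises(ValidationError):
        extract_roi_trace(movie_from(np.ones((3, 2, 2, 2))),
                          np.zeros((2, 2, 2), bool))


# ---------------------------------------------------------------------------
# dF/F


def test_dff_constant_trace_is_zero():
    d = dff(np.full(30, 50.0), rate_hz=1.0)
    assert np.allclose(d.dff, 0.0)
    assert d.f0 == 50.0


def test_dff_doubled_fluorescence_is_one():
    f = np.full(40, 100.0)
    f[20:30] = 200.0
    d = dff(f, rate_hz=1.0, f0_window_s=10)
    assert np.allclose(d.dff[20:30], 1.0)
    assert np.allclose(d.dff[:20], 0.0)


def test_dff_gain_invariant_offset_sensitive():
    rng = np.random.default_rng(2)
    f = rng.uniform(50, 150, 60)
    d1 = dff(f, 1.0).dff
    d2 = dff(3.0 * f, 1.0).dff
    d3 = dff(f + 10.0, 1.0).dff
    assert np.allclose(d1, d2)
    assert not np.allclose(d1, d3)


def test_dff_guards():
    with pytest.raises(ValidationError):
        dff(np.zeros(30), rate_hz=1.0)  # F0 = 0
    with pytest.raises(ValidationError):
        dff(np.ones(5), rate_hz=1.0, f0_window_s=10)  # window > trace
    with pytest.raises(ValidationError):
        dff(np.ones(30), rate_hz=1.0, f0_window_s=15, first_pulse_onset_s=10)


# ---------------------------------------------------------------------------
# Epoch alignment


def test_identical_epochs_average_to_any_single_epoch(six_pulse_protocol):
    rate = 1.0
    v = six_pulse_protocol.drive(220, rate)
    d = dff(100.0 * (1 + 0.4 * v), rate)
    es = align_epochs(d, six_pulse_protocol, pre_s=10)
    assert es.epochs.shape == (6, 18)
    for row in es.epochs:
        assert np.allclose(row, es.mean_trace)
    assert es.stim_mean() == pytest.approx(0.4)
    assert es.baseline_mean() == pytest.approx(0.0)


def test_single_pulse_protocol_is_valid():
    proto = StimulusProtocol(pre_s=10, n_pulses=1, pulse_dur_s=8, ipi_s=30)
    d = dff(np.full(30, 10.0), 1.0)
    es = align_epochs(d, proto)
    assert es.epochs.shape == (1, 18)


def test_epoch_out_of_range_errors():
    proto = StimulusProtocol(pre_s=10, n_pulses=6, pulse_dur_s=8, ipi_s=30)
    d = dff(np.full(60, 10.0), 1.0)  # much shorter than the protocol
    with pytest.raises(ValidationError):
        align_epochs(d, proto)


def test_epoch_averaging_attenuates_noise_by_sqrt6(six_pulse_protocol):
    """Across-epoch averaging shrinks iid noise sd by sqrt(6)."""
    rng = np.random.default_rng(3)
    sigma = 0.2
    resid = []
    for _ in range(300):
        noise = rng.normal(0, sigma, 220)
        d = dff(np.full(220, 100.0), 1.0)
        d.dff = d.dff + noise
        es = align_epochs(d, six_pulse_protocol)
        resid.append(es.mean_trace)
    sd = np.concatenate(resid).std()
    assert sd == pytest.approx(sigma / np.sqrt(6), rel=0.05)


# ---------------------------------------------------------------------------
# Connectivity


def _epochs_from_offsets(offsets, pre_n=10, stim_n=8):
    """One EpochSet per fly with a flat baseline 0 and stim level = offset."""
    sets = []
    for off in offsets:
        row = np.concatenate([np.zeros(pre_n), np.full(stim_n, off)])
        sets.append(EpochSet(epochs=np.tile(row, (6, 1)), pre_samples=pre_n,
                             stim_samples=stim_n, rate_hz=1.0))
    return sets


def test_no_change_gives_direction_none():
    call = connectivity_test(_epochs_from_offsets([0.0, 0.0, 0.0, 0.0]))
    assert call.direction == "none"
    assert call.p_value == 1.0


def test_complete_separation_n7_gives_minimal_ranksum_p():
    offsets = [0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1]
    call = connectivity_test(_epochs_from_offsets(offsets))
    # exact two-sided rank-sum tail for complete separation at 7 vs 7
    from math import comb

    assert call.p_value == pytest.approx(2 / comb(14, 7))
    assert call.direction == "excitatory"


def test_negation_flips_direction_with_identical_p():
    offsets = [0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1]
    pos = connectivity_test(_epochs_from_offsets(offsets))
    neg = connectivity_test(_epochs_from_offsets([-o for o in offsets]))
    assert neg.direction == "inhibitory"
    assert neg.p_value == pos.p_value


def test_alternative_tests_available():
    offsets = [0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1]
    for name in ("student_t", "wilcoxon_signed_rank"):
        call = connectivity_test(_epochs_from_offsets(offsets), test=name)
        assert call.direction == "excitatory"
        assert call.test == name
    with pytest.raises(ValidationError):
        connectivity_test(_epochs_from_offsets([1.0, 2.0]))  # < 3 flies


def test_inhibitory_roi_detected_through_full_chain(six_pulse_protocol):
    """Sign propagates from a negative-amplitude ROI to the call."""
    mask = np.zeros((2, 4, 4), bool)
    mask[:, 1:3, 1:3] = True
    sets = []
    for seed in range(5):
        spec = CalciumSimSpec(volume_shape=(2, 4, 4), n_volumes=220,
                              roi_masks=(RoiSpec("r", mask, -0.4),),
                              noise_sd=0.5, seed=seed)
        movie, _ = generate_calcium_movie(spec, six_pulse_protocol)
        d = dff(extract_roi_trace(movie, mask), movie.volume_rate_hz)
        sets.append(align_epochs(d, six_pulse_protocol))
    call = connectivity_test(sets)
    assert call.direction == "inhibitory"


# ---------------------------------------------------------------------------
# z-score and R2 map


def test_zscore_affine_invariance_and_closed_form():
    rng = np.random.default_rng(4)
    f = rng.uniform(0, 10, 50)
    assert np.allclose(zscore(f), zscore(3.0 * f + 7.0))
    assert np.allclose(zscore(np.array([0.0, 2.0])), [-1.0, 1.0])
    z = zscore(f)
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std(ddof=0) == pytest.approx(1.0)
    with pytest.raises(ZeroVarianceError):
        zscore(np.full(10, 3.3))


def test_r2_is_one_for_traces_proportional_to_drive(six_pulse_protocol):
    v = six_pulse_protocol.drive(220, 1.0)
    data = np.empty((220, 1, 2, 2))
    data[:, 0, 0, 0] = 100 + 50 * v
    data[:, 0, 0, 1] = 100 - 50 * v  # inhibition maps identically
    data[:, 0, 1, 0] = 7.0  # constant voxel -> 0 by convention
    data[:, 0, 1, 1] = 100 + 0.5 * v
    r2 = voxel_r2_map(movie_from(data), six_pulse_protocol).r2
    assert r2[0, 0, 0] == pytest.approx(1.0, abs=1e-12)
    assert r2[0, 0, 1] == pytest.approx(1.0, abs=1e-12)
    assert r2[0, 1, 0] == 0.0
    assert r2[0, 1, 1] == pytest.approx(1.0, abs=1e-12)


def test_r2_affine_invariance(six_pulse_protocol):
    rng = np.random.default_rng(5)
    data = rng.uniform(50, 150, (220, 2, 3, 3))
    r2a = voxel_r2_map(movie_from(data), six_pulse_protocol).r2
    r2b = voxel_r2_map(movie_from(2.5 * data + 40), six_pulse_protocol).r2
    assert np.allclose(r2a, r2b)


def test_r2_matches_bruteforce_pearson(six_pulse_protocol):
    """Vectorized map equals scipy.stats.pearsonr voxel by voxel."""
    rng = np.random.default_rng(6)
    mask = np.zeros((4, 8, 8), bool)
    mask[1:3, 2:5, 2:5] = True
    spec = CalciumSimSpec(volume_shape=(4, 8, 8), n_volumes=60,
                          roi_masks=(RoiSpec("r", mask, 0.5),),
                          noise_sd=3.0, seed=8)
    proto = StimulusProtocol(pre_s=5, n_pulses=3, pulse_dur_s=5, ipi_s=10)
    movie, _ = generate_calcium_movie(spec, proto)
    r2 = voxel_r2_map(movie, proto).r2
    v = proto.drive(60, 1.0)
    for z in range(4):
        for y in range(8):
            for x in range(8):
                r, _ = stats.pearsonr(movie.data[:, z, y, x], v)
                assert r2[z, y, x] == pytest.approx(r**2, abs=1e-12)


def test_responsive_mask_separates_from_background(responsive_movie_spec,
                                                   six_pulse_protocol,
                                                   small_roi_mask):
    """amplitude = 25x noise-sd/baseline: in-mask R2 clears the out-of-mask
    99th percentile."""
    movie, truth = generate_calcium_movie(responsive_movie_spec,
                                          six_pulse_protocol)
    r2 = voxel_r2_map(movie, six_pulse_protocol).r2
    inside = r2[small_roi_mask]
    outside = r2[~small_roi_mask]
    assert inside.mean() > np.quantile(outside, 0.99)


def test_nan_voxels_zeroed_not_imputed(six_pulse_protocol):
    v = six_pulse_protocol.drive(220, 1.0)
    data = np.tile((100 + 50 * v)[:, None, None, None], (1, 1, 2, 2))
    data[3, 0, 0, 0] = np.nan
    res = voxel_r2_map(movie_from(data), six_pulse_protocol)
    assert res.r2[0, 0, 0] == 0.0
    assert res.n_invalid == 1
    assert res.r2[0, 1, 1] == pytest.approx(1.0, abs=1e-12)


def test_constant_drive_rejected():
    proto = StimulusProtocol(pre_s=100, n_pulses=1, pulse_dur_s=5, ipi_s=30)
    data = np.random.default_rng(0).uniform(0, 1, (20, 1, 2, 2))
    with pytest.raises(ValidationError):
        voxel_r2_map(movie_from(data), proto)  # no pulse within 20 volumes


# ---------------------------------------------------------------------------
# 16-bit projection


def test_uint16_projection_endpoints_and_midpoint():
    arr = np.array([[[0.0, 1.0, 0.5]]])
    out = r2_to_uint16_stack(arr)
    assert out.dtype == np.uint16
    assert out.tolist() == [[[0, 65535, 32768]]]


def test_uint16_projection_monotone_and_near_invertible():
    r2 = np.linspace(0, 1, 1000).reshape(1, 10, 100)
    out = r2_to_uint16_stack(r2)
    assert np.all(np.diff(out.ravel()) >= 0)
    assert np.max(np.abs(out / 65535.0 - r2)) <= 0.5 / 65535


def test_uint16_projection_rejects_out_of_range():
    with pytest.raises(ValidationError):
        r2_to_uint16_stack(np.array([[[1.2]]]))
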