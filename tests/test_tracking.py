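import numpy as np
import pytest

from plaqueifem.errors import ConfigurationError
from plaqueifem.tracking import (DisplacementField, IterationSettings,
                                 TrackingSettings, accumulate, demodulate,
                                 track_pair, zncc_map)
from plaqueifem.ultrasound import RFFrame


def make_frame(samples, pressure=10.0, origin=(0.0, 0.0)):
    return RFFrame(samples=samples, axial_pitch_um=2.75, lateral_pitch_um=27.5,
                   center_frequency_mhz=40.0, pressure_mmhg=pressure,
                   origin_mm=origin)


def uniform_field(value_samples, pitch=2.75, from_p=10.0, to_p=20.0, n=8):
    shape = (n, n)
    return DisplacementField(
        axial_um=np.full(shape, value_samples * pitch),
        lateral_um=np.zeros(shape), correlation=np.ones(shape),
        valid=np.ones(shape, bool),
        grid_axial_um=np.arange(n) * 100.0, grid_lateral_um=np.arange(n) * 100.0,
        origin_mm=(0.0, 0.0), from_pressure_mmhg=from_p, to_pressure_mmhg=to_p)


# ---------------------------------------------------------------- demodulate

def test_envelope_of_pure_tone_is_constant():
    z = np.arange(4000) * 2.75
    rf = np.cos(2 * np.pi * z / 19.25)[:, None] * np.ones((1, 4))
    env = demodulate(make_frame(rf)).samples
    interior = env[200:-200]
    assert np.all(np.abs(interior - 1.0) < 0.01)


def test_envelope_trivia():
    frame = make_frame(np.zeros((100, 4)))
    assert np.all(demodulate(frame).samples == 0.0)
    rng = np.random.default_rng(0)
    rf = rng.standard_normal((200, 6))
    e1 = demodulate(make_frame(rf)).samples
    e2 = demodulate(make_frame(3.0 * rf)).samples
    assert np.allclose(e2, 3.0 * e1)


# ---------------------------------------------------------------- zncc

def test_zncc_of_identical_blocks_is_one_to_machine_precision():
    rng = np.random.default_rng(1)
    block = rng.standard_normal((64, 9))
    corr = zncc_map(block, block)
    assert corr.shape == (1, 1)
    assert abs(corr[0, 0] - 1.0) < 1e-12


def test_zncc_is_invariant_to_gain_and_offset():
    rng = np.random.default_rng(2)
    search = rng.standard_normal((40, 15))
    template = search[10:25, 3:10]
    a = zncc_map(search, template)
    b = zncc_map(2.5 * search + 7.0, 0.7 * template - 3.0)
    assert np.allclose(a, b, atol=1e-10)
    assert np.unravel_index(np.argmax(a), a.shape) == (10, 3)


# ---------------------------------------------------------------- settings

def test_settings_validation():
    with pytest.raises(ConfigurationError):
        TrackingSettings(iterations=TrackingSettings().iterations[:2])
    with pytest.raises(ConfigurationError):
        IterationSettings(True, (500.0, 100.0), (400.0, 200.0), (50.0, 27.5))


def test_default_settings_map_to_integer_windows():
    s = TrackingSettings()
    assert s.iterations[0].use_demodulated
    assert not s.iterations[2].use_demodulated
    # standard sizes divide evenly into the default pitches
    assert s.iterations[0].template_um[0] / 2.75 == pytest.approx(175.0, abs=0.1)
    assert s.iterations[0].kernel_um[1] / 27.5 == pytest.approx(35.0, abs=0.1)


# ---------------------------------------------------------------- tracking

def test_zero_motion_pair_tracks_to_exact_zero(speckle_frames):
    ref = speckle_frames["ref"]
    field = track_pair(ref, ref)
    v = field.valid
    assert v.any()
    assert np.all(field.axial_um[v] == 0.0)
    assert np.all(field.lateral_um[v] == 0.0)
    assert np.all(field.correlation[v] > 1 - 1e-9)


def test_integer_sample_shift_recovered_exactly(speckle_frames):
    ref, moved = speckle_frames["ref"], speckle_frames["int5"]
    field = track_pair(ref, moved)
    good = field.valid & (field.correlation > 0.9)
    assert good.sum() > 100
    ax_samples = field.axial_um[good] / ref.axial_pitch_um
    assert np.all(np.abs(ax_samples - 5.0) < 1e-9)
    assert np.all(field.lateral_um[good] == 0.0)


def test_subsample_shift_recovered_within_five_hundredths(speckle_frames):
    ref, moved = speckle_frames["ref"], speckle_frames["sub03"]
    field = track_pair(ref, moved)
    good = field.valid & (field.correlation > 0.9)
    assert good.sum() >= 100
    ax_samples = field.axial_um[good] / ref.axial_pitch_um
    assert abs(ax_samples.mean() - 0.3) < 0.05
    assert ax_samples.std() < 0.2  # dispersion stays modest


def test_tracking_is_shift_invariant(speckle_frames):
    """Cropping both frames by the same offset shifts the grid but not the
    estimated displacements."""
    ref, moved = speckle_frames["ref"], speckle_frames["int5"]
    crop = (slice(40, None), slice(2, None))
    f_full = track_pair(ref, moved)
    f_crop = track_pair(make_frame(ref.samples[crop]),
                        make_frame(moved.samples[crop], pressure=20.0))
    good = f_crop.valid & (f_crop.correlation > 0.9)
    assert np.allclose(f_crop.axial_um[good] / ref.axial_pitch_um, 5.0)
    assert good.sum() > 50 and f_full.valid.sum() >= good.sum()


def test_mismatched_pitches_rejected(speckle_frames):
    ref = speckle_frames["ref"]
    other = RFFrame(samples=ref.samples, axial_pitch_um=5.0,
                    lateral_pitch_um=27.5, center_frequency_mhz=40.0,
                    pressure_mmhg=20.0)
    with pytest.raises(ConfigurationError):
        track_pair(ref, other)


def test_noise_robustness_regression(speckle_frames):
    """At 20 dB SNR on the RF the rigid-shift RMSE stays below 0.2 axial
    samples."""
    ref, moved = speckle_frames["ref"], speckle_frames["sub03"]
    rng = np.random.default_rng(5)
    sigma = np.sqrt(np.mean(ref.samples**2) * 10 ** (-20 / 10))

    def noisy(frame, p):
        return make_frame(frame.samples
                          + sigma * rng.standard_normal(frame.shape), pressure=p)

    field = track_pair(noisy(ref, 10.0), noisy(moved, 20.0))
    good = field.valid & (field.correlation > 0.7)
    assert good.sum() >= 100
    err = field.axial_um[good] / ref.axial_pitch_um - 0.3
    assert np.sqrt(np.mean(err**2)) < 0.2


# ---------------------------------------------------------------- accumulate

def test_accumulate_single_field_is_identity():
    f = uniform_field(2.0)
    assert accumulate([f]) is f


def test_accumulate_uniform_fields_adds():
    f1 = uniform_field(2.0, from_p=10.0, to_p=20.0)
    f2 = uniform_field(2.0, from_p=20.0, to_p=30.0)
    acc = accumulate([f1, f2])
    inner = acc.valid
    assert inner.any()
    assert np.allclose(acc.axial_um[inner], 4.0 * 2.75)
    assert acc.from_pressure_mmhg == 10.0 and acc.to_pressure_mmhg == 30.0


def test_accumulate_rejects_broken_chain():
    f1 = uniform_field(1.0, from_p=10.0, to_p=20.0)
    f3 = uniform_field(1.0, from_p=30.0, to_p=40.0)
    with pytest.raises(ConfigurationError):
        accumulate([f1, f3])


def test_accumulated_matches_direct_tracking_on_low_strain(speckle_frames,
                                                           imaging):
    """Chaining +5 then -4.7 samples (net +0.3) must agree with directly
    tracking the +0.3 pair to within 0.1 axial sample."""
    ref = speckle_frames["ref"]
    mid, end = speckle_frames["int5"], speckle_frames["sub03"]
    f1 = track_pair(ref, mid)
    f2 = track_pair(mid, make_frame(end.samples, pressure=30.0, origin=ref.origin_mm))
    acc = accumulate([f1, f2])
    direct = track_pair(ref, make_frame(end.samples, pressure=30.0,
                                        origin=ref.origin_mm))
    good = acc.valid & direct.valid & (direct.correlation > 0.9) \
        & (acc.correlation > 0.9)
    assert good.sum() > 100
    diff = (acc.axial_um - direct.axial_um)[good] / ref.axial_pitch_um
    assert np.mean(np.abs(diff)) < 0.1
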