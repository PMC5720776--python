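import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from selfgate3d import (
    AcquisitionConfig,
    ConfigurationError,
    GatingFailureError,
    PhantomSpec,
    center_of_mass,
    detect_extrema,
    extract_z_profiles,
    select_gating_coils,
    separate_bands,
    simulate_kspace,
)

FS = 1000.0 / 42.0  # self-gating sampling rate at TR 4.2 ms x 10 partitions


def _tone(freq_hz, fs=FS, seconds=67.0, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq_hz * t)


# -- z profiles --------------------------------------------------------------


def test_z_profiles_static_phantom_identical_across_projections():
    spec = PhantomSpec(
        grid=(24, 24, 4), fov_mm=(24.0, 24.0, 6.0), contraction_fraction=0.0,
        resp_amplitude_mm=0.0, noise_sigma=0.0, arrhythmia_jitter=0.0,
        blood_inflow_mod=0.0, long_shortening_mm=0.0,
        lv_outer_radius_mm=5.0, lv_wall_thickness_mm=1.6,
        chest_semiaxes_mm=(10.0, 9.0), heart_z_extent_mm=(-2.0, 1.0),
        liver_z_extent_mm=(1.0, 2.5),
    )
    cfg = AcquisitionConfig(
        n_projections=12, n_partitions=4, matrix=(24, 24, 4),
        fov_mm=(24.0, 24.0, 6.0), n_coils=1,
    )
    prof = extract_z_profiles(simulate_kspace(spec, cfg))
    assert prof.shape == (12, 4, 1)
    assert np.allclose(prof, prof[:1], rtol=1e-9)


def test_z_profile_length_matches_partition_count(default_sim):
    prof = extract_z_profiles(default_sim)
    assert prof.shape[1] == 10
    assert prof.shape[2] == default_sim.config.n_coils


def test_z_profiles_shift_with_rigid_z_translation():
    """Moving the organs one slice along z rolls the profile by one sample."""
    common = dict(
        grid=(24, 24, 8), fov_mm=(24.0, 24.0, 12.0), contraction_fraction=0.0,
        resp_amplitude_mm=0.0, noise_sigma=0.0, arrhythmia_jitter=0.0,
        blood_inflow_mod=0.0, long_shortening_mm=0.0,
        lv_outer_radius_mm=5.0, lv_wall_thickness_mm=1.6,
        chest_semiaxes_mm=(10.0, 9.0),
    )
    cfg = AcquisitionConfig(
        n_projections=4, n_partitions=8, matrix=(24, 24, 8),
        fov_mm=(24.0, 24.0, 12.0), n_coils=1,
    )
    dz = 12.0 / 8
    a = extract_z_profiles(simulate_kspace(PhantomSpec(
        heart_z_extent_mm=(-4.0, -1.0), liver_z_extent_mm=(-1.0, 1.0), **common
    ), cfg))
    b = extract_z_profiles(simulate_kspace(PhantomSpec(
        heart_z_extent_mm=(-4.0 + dz, -1.0 + dz),
        liver_z_extent_mm=(-1.0 + dz, 1.0 + dz), **common
    ), cfg))
    assert np.allclose(b, np.roll(a, 1, axis=1), atol=1e-6 * a.max())


# -- center of mass ----------------------------------------------------------


def test_com_symmetric_profile_is_zero():
    z = np.array([-3.0, -1.0, 1.0, 3.0])
    assert center_of_mass(np.array([1.0, 2.0, 2.0, 1.0]), z) == pytest.approx(0.0)


def test_com_impulse_returns_slice_position():
    z = np.array([-3.0, -1.5, 0.0, 1.5])
    p = np.array([0.0, 0.0, 0.0, 5.0])
    assert center_of_mass(p, z) == pytest.approx(1.5)


def test_com_hand_arithmetic():
    assert center_of_mass(np.array([1.0, 3.0]), np.array([0.0, 1.5])) == pytest.approx(1.125)


def test_com_all_zero_profile_errors():
    with pytest.raises(GatingFailureError):
        center_of_mass(np.zeros(4), np.arange(4.0))


# -- band separation ---------------------------------------------------------


def test_cardiac_tone_lands_in_cardiac_band():
    x = _tone(7.5)
    resp, cardiac = separate_bands(x, FS)
    core = slice(200, -200)
    assert np.abs(cardiac[core]).max() >= 0.9
    assert np.abs(resp[core]).max() <= 0.1


def test_respiratory_tone_lands_in_respiratory_band():
    x = _tone(1.5)
    resp, cardiac = separate_bands(x, FS)
    core = slice(200, -200)
    assert np.abs(resp[core]).max() >= 0.9
    assert np.abs(cardiac[core]).max() <= 0.1


def test_stopband_attenuation_one_octave_below_cardiac_band():
    x = _tone(6.7 / 2)
    _, cardiac = separate_bands(x, FS)
    assert np.abs(cardiac[200:-200]).max() <= 0.1  # >= 20 dB down


def test_zero_input_gives_zero_output():
    resp, cardiac = separate_bands(np.zeros(500), FS)
    assert np.allclose(resp, 0.0) and np.allclose(cardiac, 0.0)


@settings(deadline=None, max_examples=20)
@given(st.integers(0, 2**31 - 1))
def test_band_separation_is_linear(seed):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(600)
    b = rng.standard_normal(600)
    ra, ca = separate_bands(a, FS)
    rb, cb = separate_bands(b, FS)
    rs, cs = separate_bands(a + b, FS)
    assert np.allclose(rs, ra + rb, atol=1e-9)
    assert np.allclose(cs, ca + cb, atol=1e-9)


def test_band_above_nyquist_rejected():
    with pytest.raises(ConfigurationError):
        separate_bands(np.zeros(100), fs_hz=10.0, cardiac_band_hz=(6.7, 9.2))


# -- extrema detection -------------------------------------------------------


def test_detected_cardiac_rate_within_two_percent():
    ext = detect_extrema(_tone(430 / 60.0), FS, (400.0, 550.0))
    assert ext.rate_bpm == pytest.approx(430.0, rel=0.02)


def test_detected_respiratory_rate_within_two_percent():
    ext = detect_extrema(_tone(78 / 60.0), FS, (60.0, 150.0))
    assert ext.rate_bpm == pytest.approx(78.0, rel=0.02)


def test_monotonic_ramp_has_no_oscillation():
    with pytest.raises(GatingFailureError):
        detect_extrema(np.linspace(0, 1, 500), FS, (400.0, 550.0))


def test_peak_count_times_interval_covers_duration():
    x = _tone(1.3, seconds=60.0)
    ext = detect_extrema(x, FS, (60.0, 150.0))
    covered = ext.peaks.size * (FS / (ext.rate_bpm / 60.0))
    assert abs(covered - x.size) <= FS / 1.3  # within one cycle


# -- coil selection ----------------------------------------------------------


def test_clean_channel_beats_noisy_channel_for_both_roles():
    rng = np.random.default_rng(11)
    resp_clean = _tone(1.3, seconds=40.0)
    card_clean = _tone(7.2, seconds=40.0)
    resp = np.stack([resp_clean, resp_clean + 0.8 * rng.standard_normal(resp_clean.size)], axis=1)
    card = np.stack([card_clean, card_clean + 0.8 * rng.standard_normal(card_clean.size)], axis=1)
    r, c, _ = select_gating_coils(resp, card, FS)
    assert (r, c) == (0, 0)


def test_identical_channels_tie_break_to_lowest_index():
    resp = np.stack([_tone(1.3, seconds=40.0)] * 3, axis=1)
    card = np.stack([_tone(7.2, seconds=40.0)] * 3, axis=1)
    r, c, _ = select_gating_coils(resp, card, FS)
    assert (r, c) == (0, 0)


def test_all_channels_failing_raises():
    flat = np.zeros((400, 2))
    ramp = np.cumsum(np.ones((400, 2)), axis=0)
    with pytest.raises(GatingFailureError):
        select_gating_coils(flat + ramp, flat + ramp, FS)


# -- end-to-end recovery -----------------------------------------------------


def test_default_acquisition_recovers_both_rates_within_two_percent(
    default_sim, default_gating
):
    truth = default_sim.ground_truth
    assert default_gating.heart_rate_bpm == pytest.approx(
        truth.heart_rate_bpm, rel=0.02
    )
    assert default_gating.resp_rate_bpm == pytest.approx(
        truth.resp_rate_bpm, rel=0.02
    )
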