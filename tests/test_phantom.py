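import numpy as np
import pytest

from selfgate3d import (
    AcquisitionConfig,
    ConfigurationError,
    PhantomSpec,
    make_coil_maps,
    render_frame,
    simulate_kspace,
)
from selfgate3d.nufft import nudft_forward
from selfgate3d.phantom import wall_masks
from selfgate3d.recon import kz_decouple


def _static_spec(**overrides):
    kwargs = dict(
        grid=(24, 24, 4), fov_mm=(24.0, 24.0, 6.0),
        contraction_fraction=0.0, resp_amplitude_mm=0.0, noise_sigma=0.0,
        arrhythmia_jitter=0.0, blood_inflow_mod=0.0, long_shortening_mm=0.0,
        lv_outer_radius_mm=5.0, lv_wall_thickness_mm=1.6,
        chest_semiaxes_mm=(10.0, 9.0), heart_z_extent_mm=(-2.0, 1.0),
        liver_z_extent_mm=(1.0, 2.5),
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


def test_static_spec_renders_time_invariant():
    spec = _static_spec()
    a = render_frame(spec, 0.0)
    b = render_frame(spec, 137.7)
    assert np.array_equal(a, b)


def test_periodic_heartbeat_renders_identically_one_period_apart():
    spec = _static_spec(contraction_fraction=0.3, blood_inflow_mod=0.4)
    period = 60000.0 / spec.heart_rate_bpm
    t = 31.0
    assert np.allclose(render_frame(spec, t), render_frame(spec, t + period))


def test_infarct_sector_occupies_a_quarter_of_the_wall():
    spec = PhantomSpec(noise_sigma=0.0)  # default: 90 deg sector
    frame = render_frame(spec, 0.0, shape=(192, 192, 10), fov_mm=spec.fov_mm)
    wall, sector = wall_masks(spec, (192, 192), spec.fov_mm[:2], margin_mm=0.45)
    mid = frame[:, :, 5]
    enhanced = mid[wall] > 0.5 * (
        spec.signal_levels.myocardium + spec.signal_levels.infarct
    )
    assert enhanced.mean() == pytest.approx(90.0 / 360.0, abs=0.02)
    # and the enhanced voxels are the geometric sector
    assert enhanced.sum() == sector.sum()


def test_degenerate_wall_rejected():
    with pytest.raises(ConfigurationError):
        _static_spec(lv_wall_thickness_mm=0.0)
    with pytest.raises(ConfigurationError):
        _static_spec(lv_wall_thickness_mm=6.0)  # >= outer radius


def test_simulated_lines_match_direct_dft_oracle():
    """Every acquired line equals the direct-summation 3D DFT of the frame."""
    spec = _static_spec()
    cfg = AcquisitionConfig(
        n_projections=6, n_partitions=4, matrix=(24, 24, 4),
        fov_mm=(24.0, 24.0, 6.0), n_coils=1,
    )
    ks = simulate_kspace(spec, cfg)
    vol = render_frame(spec, 0.0)
    zc = np.arange(4) - 2
    worst = 0.0
    for p in range(6):
        for a in range(4):
            fz = (ks.trajectory.kz_order[a] - 2) / 4
            sl = (vol * np.exp(-2j * np.pi * fz * zc)[None, None, :]).sum(axis=2)
            want = nudft_forward(sl, ks.trajectory.kxy[p])
            got = ks.samples[p, a, :, 0]
            worst = max(worst, np.linalg.norm(got - want) / np.linalg.norm(want))
    assert worst < 1e-6


def test_simulation_deterministic_for_fixed_seed():
    spec = _static_spec(noise_sigma=0.05)
    cfg = AcquisitionConfig(
        n_projections=8, n_partitions=4, matrix=(24, 24, 4),
        fov_mm=(24.0, 24.0, 6.0), n_coils=2,
    )
    a = simulate_kspace(spec, cfg, seed=9)
    b = simulate_kspace(spec, cfg, seed=9)
    assert np.array_equal(a.samples, b.samples)


def test_opposed_spokes_conjugate_symmetric_for_real_object():
    spec = _static_spec()
    cfg = AcquisitionConfig(
        n_projections=2, n_partitions=4, matrix=(24, 24, 4),
        fov_mm=(24.0, 24.0, 6.0), golden_angle_deg=180.0, n_coils=1,
    )
    ks = simulate_kspace(spec, cfg)
    kz0 = 2  # the kz = 0 partition
    a = ks.samples[1, kz0, :, 0]
    b = np.conj(ks.samples[0, kz0, :, 0])
    assert np.linalg.norm(a - b) / np.linalg.norm(b) < 1e-6


def test_dc_magnitude_dominates_for_nonnegative_object():
    spec = _static_spec()
    cfg = AcquisitionConfig(
        n_projections=8, n_partitions=4, matrix=(24, 24, 4),
        fov_mm=(24.0, 24.0, 6.0), n_coils=1,
    )
    ks = simulate_kspace(spec, cfg)
    mags = np.abs(ks.samples[:, :, :, 0])
    p, a, m = np.unravel_index(np.argmax(mags), mags.shape)
    assert (a, m) == (2, ks.trajectory.dc_index)
    assert mags.max() >= mags.flat[np.argsort(mags.flat)[-2]]


def test_noise_variance_matches_sigma_across_repeated_angles():
    """With a zero angular increment every projection repeats the same spoke,
    so the per-sample variance across projections is the injected noise."""
    cfg = AcquisitionConfig(
        n_projections=400, n_partitions=2, matrix=(24, 24, 2),
        fov_mm=(24.0, 24.0, 3.0), golden_angle_deg=0.0, n_coils=1,
    )
    clean = simulate_kspace(
        _static_spec(grid=(24, 24, 2), heart_z_extent_mm=(-1.0, 0.5),
                     liver_z_extent_mm=(0.6, 1.2)), cfg)
    noisy = simulate_kspace(
        _static_spec(grid=(24, 24, 2), heart_z_extent_mm=(-1.0, 0.5),
                     liver_z_extent_mm=(0.6, 1.2), noise_sigma=0.05), cfg)
    sigma = 0.05 * np.abs(clean.samples).max()
    # complex variance across repeated identical acquisitions
    var = np.var(noisy.samples.real, axis=0).mean() + np.var(
        noisy.samples.imag, axis=0
    ).mean()
    assert var == pytest.approx(sigma**2, rel=0.2)


def test_coil_maps_shapes_and_support():
    ones = make_coil_maps((32, 32), 1)
    assert np.array_equal(ones, np.ones((1, 32, 32)))
    maps = make_coil_maps((32, 32), 4, seed=5)
    assert maps.shape == (4, 32, 32)
    sos = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    assert sos.min() > 0
    assert np.array_equal(maps, make_coil_maps((32, 32), 4, seed=5))
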