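import numpy as np
import pytest

from selfgate3d import (
    AcquisitionConfig,
    ConfigurationError,
    PhantomSpec,
    nrmse,
    simulate_kspace,
    temporal_tv,
)
from selfgate3d.nufft import NUFFT2D
from selfgate3d.phantom import render_frame
from selfgate3d.recon import (
    cs_slice,
    cyclic_diff,
    cyclic_diff_adjoint,
    kz_decouple,
    radial_density_weights,
    regrid_slice,
    sos_combine,
    tv_prox_cyclic,
)


def _cg_least_squares(plan, d, shape, n_iter=40):
    """Conjugate-gradient solve of F^H F x = F^H d (independent oracle)."""
    b = plan.adjoint(d)
    x = np.zeros(shape, dtype=complex)
    r = b.copy()
    p = r.copy()
    rs = np.vdot(r, r).real
    for _ in range(n_iter):
        ap = plan.adjoint(plan.forward(p))
        alpha = rs / np.vdot(p, ap).real
        x += alpha * p
        r -= alpha * ap
        rs_new = np.vdot(r, r).real
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x


# -- kz decoupling -----------------------------------------------------------


def test_kz_decouple_recovers_slice_integrals():
    """After decoupling, each slice's DC sample is that slice's integral."""
    spec = PhantomSpec(
        grid=(24, 24, 4), fov_mm=(24.0, 24.0, 6.0), contraction_fraction=0.0,
        resp_amplitude_mm=0.0, noise_sigma=0.0, arrhythmia_jitter=0.0,
        blood_inflow_mod=0.0, long_shortening_mm=0.0,
        lv_outer_radius_mm=5.0, lv_wall_thickness_mm=1.6,
        chest_semiaxes_mm=(10.0, 9.0), heart_z_extent_mm=(-2.0, 1.0),
        liver_z_extent_mm=(1.0, 2.5),
    )
    cfg = AcquisitionConfig(
        n_projections=1, n_partitions=4, matrix=(24, 24, 4),
        fov_mm=(24.0, 24.0, 6.0), n_coils=1,
    )
    ks = simulate_kspace(spec, cfg)
    per_slice = kz_decouple(ks.samples, ks.trajectory.kz_order)
    frame = render_frame(spec, 0.0)
    dc = ks.trajectory.dc_index
    for z in range(4):
        assert per_slice[0, z, dc, 0] == pytest.approx(
            frame[:, :, z].sum(), rel=1e-6
        )


def test_kz_decouple_single_partition_is_identity():
    d = np.random.default_rng(0).standard_normal((5, 1, 8, 2)) + 0j
    assert np.allclose(kz_decouple(d, np.array([0])), d)


def test_kz_decouple_is_linear():
    rng = np.random.default_rng(1)
    a = rng.standard_normal((3, 4, 8, 1)) + 1j * rng.standard_normal((3, 4, 8, 1))
    b = rng.standard_normal((3, 4, 8, 1)) + 1j * rng.standard_normal((3, 4, 8, 1))
    order = np.arange(4)
    assert np.allclose(
        kz_decouple(a + b, order), kz_decouple(a, order) + kz_decouple(b, order)
    )


# -- regridding --------------------------------------------------------------


def test_fully_sampled_regrid_matches_ground_truth(static64):
    ks, spec = static64
    truth = ks.ground_truth.phase_frames[0][:, :, 0]
    sdata = kz_decouple(ks.samples, ks.trajectory.kz_order)[:, 0, :, :]
    img = regrid_slice(sdata, ks.trajectory.kxy, [np.arange(110)], (64, 64))
    assert nrmse(img[:, :, 0], truth) < 0.05


def test_undersampling_increases_regrid_error(static64):
    ks, spec = static64
    truth = ks.ground_truth.phase_frames[0][:, :, 0]
    sdata = kz_decouple(ks.samples, ks.trajectory.kz_order)[:, 0, :, :]
    full = regrid_slice(sdata, ks.trajectory.kxy, [np.arange(110)], (64, 64))
    few = regrid_slice(sdata, ks.trajectory.kxy, [np.arange(50)], (64, 64))
    assert nrmse(few[:, :, 0], truth) > nrmse(full[:, :, 0], truth)


def test_zero_data_gives_zero_image(static64):
    ks, _ = static64
    sdata = np.zeros((110, ks.config.n_readout, 1), dtype=complex)
    img = regrid_slice(sdata, ks.trajectory.kxy, [np.arange(110)], (64, 64))
    assert np.allclose(img, 0.0)


def test_empty_phase_warns_and_zeroes(static64):
    ks, _ = static64
    sdata = kz_decouple(ks.samples, ks.trajectory.kz_order)[:, 0, :, :]
    with pytest.warns(UserWarning):
        img = regrid_slice(
            sdata, ks.trajectory.kxy, [np.arange(50), np.array([], dtype=int)],
            (64, 64),
        )
    assert np.allclose(img[:, :, 1], 0.0)


def test_density_weights_ramp_shape():
    w = radial_density_weights(16, 10)
    assert w[8] == pytest.approx(w[9] / 2)  # DC = half the first ring
    assert w[0] > w[4] > w[7]  # ramp decreasing toward DC


# -- temporal TV -------------------------------------------------------------


def test_cyclic_diff_adjoint_identity():
    rng = np.random.default_rng(2)
    x = rng.standard_normal((4, 4, 5)) + 1j * rng.standard_normal((4, 4, 5))
    p = rng.standard_normal((4, 4, 5)) + 1j * rng.standard_normal((4, 4, 5))
    assert np.vdot(p, cyclic_diff(x)) == pytest.approx(
        np.vdot(cyclic_diff_adjoint(p), x)
    )


def test_static_series_has_zero_temporal_tv():
    frame = np.random.default_rng(3).random((8, 8))
    series = np.repeat(frame[:, :, None], 4, axis=2)
    assert temporal_tv(series) == 0.0


def test_tv_prox_reduces_temporal_variation():
    rng = np.random.default_rng(4)
    v = rng.standard_normal((6, 6, 5))
    out = tv_prox_cyclic(v, tau=0.3)
    assert temporal_tv(out) < temporal_tv(v)
    assert tv_prox_cyclic(v, tau=0.0) is v


# -- compressed sensing ------------------------------------------------------


def test_cs_without_regularization_matches_cg_oracle(static64):
    ks, _ = static64
    sdata = kz_decouple(ks.samples, ks.trajectory.kz_order)[:, 0, :, :]
    projs = [np.arange(0, 110, 2), np.arange(1, 110, 2)]
    img, _ = cs_slice(sdata, ks.trajectory.kxy, projs, (64, 64), lam=0.0)
    oracle = np.stack(
        [
            np.abs(_cg_least_squares(
                NUFFT2D((64, 64), ks.trajectory.kxy[p].reshape(-1, 2)),
                sdata[p, :, 0].ravel(), (64, 64),
            ))
            for p in projs
        ],
        axis=-1,
    )
    assert nrmse(img, oracle) < 0.05


def test_cs_beats_regridding_on_undersampled_dynamic_data(dyn64):
    assert nrmse(dyn64["cs"], dyn64["truth"]) < nrmse(dyn64["regrid"], dyn64["truth"])


def test_cs_output_has_lower_temporal_tv_than_regridding(dyn64):
    assert temporal_tv(dyn64["cs"]) <= temporal_tv(dyn64["regrid"])


def test_bregman_residual_is_non_increasing(dyn64):
    res = np.array(dyn64["cs_log"]["residual"])
    assert np.all(res[1:] <= res[:-1] * (1.0 + 1e-8))


def test_cs_agrees_with_regridding_when_fully_sampled(static64):
    ks, _ = static64
    sdata = kz_decouple(ks.samples, ks.trajectory.kz_order)[:, 0, :, :]
    projs = [np.arange(0, 110, 2), np.arange(1, 110, 2)]
    # 55 spokes/phase at 64^2 is still near-complete; lam -> 0
    cs, _ = cs_slice(sdata, ks.trajectory.kxy, projs, (64, 64), lam=0.0)
    rg = regrid_slice(sdata, ks.trajectory.kxy, projs, (64, 64))
    assert nrmse(cs, rg) < 0.05


def test_cs_needs_at_least_two_phases(static64):
    ks, _ = static64
    sdata = kz_decouple(ks.samples, ks.trajectory.kz_order)[:, 0, :, :]
    with pytest.raises(ConfigurationError):
        cs_slice(sdata, ks.trajectory.kxy, [np.arange(110)], (64, 64))


def test_sos_combine_matches_manual():
    rng = np.random.default_rng(5)
    imgs = rng.standard_normal((3, 4, 4)) + 1j * rng.standard_normal((3, 4, 4))
    assert np.allclose(sos_combine(imgs), np.sqrt((np.abs(imgs) ** 2).sum(axis=0)))
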