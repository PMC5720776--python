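"""Shared fixtures: simulated acquisitions reused across test modules.

Session-scoped because the protocol-scale simulation takes ~15 s; every
fixture is deterministic (fixed seeds), so sharing does not couple tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from selfgate3d import (
    AcquisitionConfig,
    PhantomSpec,
    extract_gating,
    simulate_kspace,
)
from selfgate3d.phantom import cavity_mask, wall_masks
from selfgate3d.recon import cs_slice, kz_decouple, regrid_slice


@pytest.fixture(scope="session")
def default_sim():
    """Protocol-scale acquisition: 1600 projections, 10 partitions, 4 coils,
    430 bpm / 78 breaths/min, 5 % noise (128 in-plane matrix)."""
    config = AcquisitionConfig(matrix=(128, 128, 10), n_coils=4)
    spec = PhantomSpec(grid=(128, 128, 10), seed=1)
    return simulate_kspace(spec, config)


@pytest.fixture(scope="session")
def default_gating(default_sim):
    return extract_gating(default_sim)


def _dyn64_spec(seed=3, noise=0.05):
    return PhantomSpec(
        grid=(64, 64, 1),
        fov_mm=(29.0, 29.0, 1.5),
        resp_amplitude_mm=0.0,
        arrhythmia_jitter=0.0,
        long_shortening_mm=0.0,
        heart_z_extent_mm=(-0.75, 0.75),
        liver_z_extent_mm=(5.0, 6.0),
        noise_sigma=noise,
        seed=seed,
    )


@pytest.fixture(scope="session")
def dyn64():
    """Scaled-down dynamic 2D problem: 3 cardiac phases x ~60 spokes, 64^2,
    4 coils, plus both reconstructions and the matched ground truth."""
    config = AcquisitionConfig(
        n_projections=180, n_partitions=1, matrix=(64, 64, 1),
        fov_mm=(29.0, 29.0, 1.5), n_coils=4,
    )
    spec = _dyn64_spec()
    ks = simulate_kspace(spec, config)
    phase = np.minimum((ks.ground_truth.cardiac_phase * 3).astype(int), 2)
    projs = [np.nonzero(phase == t)[0] for t in range(3)]
    sdata = kz_decouple(ks.samples, ks.trajectory.kz_order)[:, 0, :, :]
    regrid = regrid_slice(sdata, ks.trajectory.kxy, projs, (64, 64))
    cs, log = cs_slice(sdata, ks.trajectory.kxy, projs, (64, 64))

    # reference: noiseless phase-window means, shaded by the coil profile
    ks_ref = simulate_kspace(_dyn64_spec(noise=0.0), config, n_gt_phases=24)
    sos = np.sqrt((np.abs(ks_ref.ground_truth.coil_maps) ** 2).sum(axis=0))
    frames = ks_ref.ground_truth.phase_frames[:, :, :, 0]
    truth = np.stack(
        [frames[t * 8 : (t + 1) * 8].mean(axis=0) for t in range(3)], axis=-1
    ) * sos[:, :, None]
    wall, _ = wall_masks(spec, (64, 64), (29.0, 29.0))
    cavity = cavity_mask(spec, (64, 64), (29.0, 29.0))
    return {
        "kspace": ks, "spec": spec, "projs": projs, "slice_data": sdata,
        "regrid": regrid, "cs": cs, "cs_log": log, "truth": truth,
        "wall": wall, "cavity": cavity,
    }


@pytest.fixture()
def static64():
    """Small static noiseless single-coil acquisition (oracle comparisons)."""
    config = AcquisitionConfig(
        n_projections=110, n_partitions=1, matrix=(64, 64, 1),
        fov_mm=(29.0, 29.0, 1.5), n_coils=1,
    )
    spec = PhantomSpec(
        grid=(64, 64, 1), fov_mm=(29.0, 29.0, 1.5),
        contraction_fraction=0.0, resp_amplitude_mm=0.0, noise_sigma=0.0,
        arrhythmia_jitter=0.0, blood_inflow_mod=0.0, long_shortening_mm=0.0,
        heart_z_extent_mm=(-0.75, 0.75), liver_z_extent_mm=(5.0, 6.0),
    )
    return simulate_kspace(spec, config), spec
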