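"""HDF5 raw-data container and result export.

Layout of the raw container (ISMRMRD-inspired, but self-describing and
minimal):

    /kspace/samples          complex, (projection, partition, readout, coil)
    /trajectory/angles_deg   (n_projections,)
    /trajectory/kxy          (n_projections, n_readout, 2), cycles/FOV
    /trajectory/kz_order     (n_partitions,)
    /trajectory/timestamps_ms (n_projections, n_partitions)
    /config                  YAML string (AcquisitionConfig)
    /phantom_spec            YAML string, optional (simulated data only)
    /ground_truth/*          optional noiseless frames + motion traces

Unknown extra groups are ignored on read, so foreign files that follow the
layout load fine.
"""

from __future__ import annotations

import h5py

from .errors import FormatError
from .phantom import GroundTruth, KSpaceData, spec_from_yaml, spec_to_yaml
from .trajectory import AcquisitionConfig, Trajectory


def write_raw(path: str, kspace: KSpaceData) -> None:
    """Write a KSpaceData container (lossless round-trip with read_raw)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace/samples", data=kspace.samples)
        t = kspace.trajectory
        f.create_dataset("trajectory/angles_deg", data=t.angles_deg)
        f.create_dataset("trajectory/kxy", data=t.kxy)
        f.create_dataset("trajectory/kz_order", data=t.kz_order)
        f.create_dataset("trajectory/timestamps_ms", data=t.timestamps_ms)
        f.create_dataset("config", data=kspace.config.to_yaml())
        if kspace.spec is not None:
            f.create_dataset("phantom_spec", data=spec_to_yaml(kspace.spec))
        gt = kspace.ground_truth
        if gt is not None:
            g = f.create_group("ground_truth")
            for name in (
                "phase_frames", "phase_centers", "profile_times_ms",
                "cardiac_phase", "cycle_index", "resp_mm", "r_in_mm",
                "cycle_boundaries_ms", "coil_maps",
            ):
                g.create_dataset(name, data=getattr(gt, name))
            g.attrs["heart_rate_bpm"] = gt.heart_rate_bpm
            g.attrs["resp_rate_bpm"] = gt.resp_rate_bpm


def read_raw(path: str) -> KSpaceData:
    """Read a raw container; missing datasets raise FormatError by path."""
    with h5py.File(path, "r") as f:
        def need(name: str):
            if name not in f:
                raise FormatError(f"raw container is missing dataset '{name}'")
            return f[name]

        config = AcquisitionConfig.from_yaml(need("config")[()].decode()
                                             if isinstance(need("config")[()], bytes)
                                             else str(need("config")[()]))
        traj = Trajectory(
            angles_deg=need("trajectory/angles_deg")[()],
            kxy=need("trajectory/kxy")[()],
            kz_order=need("trajectory/kz_order")[()],
            timestamps_ms=need("trajectory/timestamps_ms")[()],
            config=config,
        )
        samples = need("kspace/samples")[()]
        spec = None
        if "phantom_spec" in f:
            raw = f["phantom_spec"][()]
            spec = spec_from_yaml(raw.decode() if isinstance(raw, bytes) else str(raw))
        gt = None
        if "ground_truth" in f:
            g = f["ground_truth"]
            gt = GroundTruth(
                phase_frames=g["phase_frames"][()],
                phase_centers=g["phase_centers"][()],
                profile_times_ms=g["profile_times_ms"][()],
                cardiac_phase=g["cardiac_phase"][()],
                cycle_index=g["cycle_index"][()],
                resp_mm=g["resp_mm"][()],
                r_in_mm=g["r_in_mm"][()],
                cycle_boundaries_ms=g["cycle_boundaries_ms"][()],
                heart_rate_bpm=float(g.attrs["heart_rate_bpm"]),
                resp_rate_bpm=float(g.attrs["resp_rate_bpm"]),
                coil_maps=g["coil_maps"][()],
            )
    return KSpaceData(
        samples=samples, trajectory=traj, config=config, ground_truth=gt, spec=spec
    )


def write_gating(path: str, signals) -> None:
    """Append gating results under /gating of an HDF5 file."""
    with h5py.File(path, "a") as f:
        if "gating" in f:
            del f["gating"]
        g = f.create_group("gating")
        g.create_dataset("z_profiles", data=signals.z_profiles)
        g.create_dataset("com_trace", data=signals.com_trace)
        g.create_dataset("resp_trace", data=signals.resp_trace)
        g.create_dataset("cardiac_trace", data=signals.cardiac_trace)
        g.create_dataset("cardiac_peaks", data=signals.cardiac_extrema.peaks)
        g.create_dataset("resp_valleys", data=signals.resp_extrema.valleys)
        g.attrs["fs_hz"] = signals.fs_hz
        g.attrs["resp_coil"] = signals.resp_coil
        g.attrs["cardiac_coil"] = signals.cardiac_coil
        g.attrs["heart_rate_bpm"] = signals.heart_rate_bpm
        g.attrs["resp_rate_bpm"] = signals.resp_rate_bpm


def write_realign(path: str, assignment) -> None:
    """Append the realignment table under /realign of an HDF5 file."""
    with h5py.File(path, "a") as f:
        if "realign" in f:
            del f["realign"]
        g = f.create_group("realign")
        g.create_dataset("resp_bin", data=assignment.resp_bin)
        g.create_dataset("cardiac_phase", data=assignment.cardiac_phase)
        g.create_dataset("cycle_id", data=assignment.cycle_id)
        g.create_dataset("kept", data=assignment.kept)
        g.create_dataset("discarded_cycles", data=assignment.discarded_cycles)
        g.attrs["selected_resp_bin"] = assignment.selected_resp_bin
        g.attrs["n_cardiac_phases"] = assignment.n_cardiac_phases
        g.attrs["quiescent_phase"] = assignment.quiescent_phase
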