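"""Respiratory and cardiac gating-signal extraction from k-space-center data.

Pipeline: the partition-first stack-of-stars acquisition re-measures the
central kz line once per projection.  A centered 1D inverse DFT of those
center samples along kz gives a z intensity profile of the whole imaging
volume per projection and coil; its center of mass (COM) traces bulk motion.
Band-pass filtering of the COM trace separates respiration (1.0-2.5 Hz) from
the heartbeat (6.7-9.2 Hz, from the murine 60-150 breaths/min and
400-550 bpm physiological ranges).  Peaks/valleys are detected with a
rate-adaptive minimum spacing and re-estimated iteratively.  A virtual
channel (sum-of-squares of all real coils' z-profiles) is appended, and the
channel with the most stable respiratory valley level (resp.) or the most
regular R-R intervals (cardiac) is selected for gating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt, find_peaks, periodogram

from .errors import ConfigurationError, FormatError, GatingFailureError
from .phantom import KSpaceData

RESP_BAND_HZ = (1.0, 2.5)
CARDIAC_BAND_HZ = (6.7, 9.2)
RESP_RATE_RANGE_BPM = (60.0, 150.0)
CARDIAC_RATE_RANGE_BPM = (400.0, 550.0)

#: seconds trimmed at both trace ends when estimating rates (filter edge effects)
EDGE_EXCLUSION_S = 2.0


@dataclass
class Extrema:
    """Detected oscillation landmarks of one filtered trace."""

    peaks: np.ndarray
    valleys: np.ndarray
    rate_bpm: float
    intervals: np.ndarray  # inter-peak spacing in samples


@dataclass
class GatingSignals:
    """Per-projection gating waveforms and the channels chosen for gating.

    Channel axis = real coils followed by the virtual sum-of-squares coil
    (index ``n_real``).
    """

    z_profiles: np.ndarray  # (n_projections, nz, n_channels) magnitude
    com_trace: np.ndarray  # (n_projections, n_channels) mm
    resp_trace: np.ndarray  # band-passed, zero mean
    cardiac_trace: np.ndarray
    fs_hz: float
    n_real: int
    resp_coil: int
    cardiac_coil: int
    resp_extrema: Extrema
    cardiac_extrema: Extrema
    resp_band_hz: tuple[float, float] = RESP_BAND_HZ
    cardiac_band_hz: tuple[float, float] = CARDIAC_BAND_HZ
    per_channel: dict = field(default_factory=dict, repr=False)

    @property
    def heart_rate_bpm(self) -> float:
        return self.cardiac_extrema.rate_bpm

    @property
    def resp_rate_bpm(self) -> float:
        return self.resp_extrema.rate_bpm

    @property
    def cardiac_peaks(self) -> np.ndarray:
        return self.cardiac_extrema.peaks

    @property
    def rr_intervals(self) -> np.ndarray:
        return self.cardiac_extrema.intervals


def extract_z_profiles(kspace: KSpaceData) -> np.ndarray:
    """Magnitude z intensity profiles, (n_projections, nz, n_coils).

    Takes the DC readout sample of each partition line of every projection
    and applies a centered 1D inverse DFT along kz.
    """
    traj = kspace.trajectory
    dc = traj.dc_index
    if not np.allclose(traj.kxy[:, dc, :], 0.0):
        raise FormatError(
            f"readout sample {dc} is not at the k-space origin; "
            "trajectory lacks a DC sample"
        )
    center = kspace.samples[:, :, dc, :]  # (proj, partition-acq-order, coil)
    # reorder acquisition position -> partition (kz) index
    order = np.argsort(kspace.trajectory.kz_order)
    center = center[:, order, :]
    prof = np.fft.fftshift(
        np.fft.ifft(np.fft.ifftshift(center, axes=1), axis=1), axes=1
    )
    return np.abs(prof)


def center_of_mass(profiles: np.ndarray, z_positions_mm: np.ndarray) -> np.ndarray:
    """Intensity-weighted mean z position, per profile.

    ``profiles`` has z on its second-to-last or only axis matching
    ``z_positions_mm``; non-negative, not all zero.
    """
    profiles = np.asarray(profiles, dtype=float)
    z = np.asarray(z_positions_mm, dtype=float)
    if profiles.ndim == 1:
        profiles = profiles[None, :]
    axis = 1
    total = profiles.sum(axis=axis)
    if np.any(total <= 0):
        raise GatingFailureError("center of mass undefined for an all-zero profile")
    com = np.tensordot(profiles, z, axes=([axis], [0])) / total
    return com.squeeze()


def separate_bands(
    com_trace: np.ndarray,
    fs_hz: float,
    resp_band_hz: tuple[float, float] = RESP_BAND_HZ,
    cardiac_band_hz: tuple[float, float] = CARDIAC_BAND_HZ,
    order: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-phase band-pass split of the COM trace into the two motion bands.

    Butterworth (order 4) applied forward-backward, so filtering shifts no
    timing relative to the acquisition timestamps.
    """
    nyq = fs_hz / 2.0
    for band in (resp_band_hz, cardiac_band_hz):
        if band[1] >= nyq:
            raise ConfigurationError(
                f"band edge {band[1]} Hz is at/above Nyquist {nyq:.2f} Hz"
            )
        if band[0] <= 0 or band[0] >= band[1]:
            raise ConfigurationError(f"invalid band {band}")
    if fs_hz < 2.0 * cardiac_band_hz[1]:
        warnings.warn(
            f"gating sampling rate {fs_hz:.2f} Hz is below twice the cardiac "
            f"band upper edge {cardiac_band_hz[1]} Hz; cardiac waveform is "
            "coarsely sampled",
            stacklevel=2,
        )
    trace = np.asarray(com_trace, dtype=float)
    trace = trace - trace.mean(axis=0, keepdims=True) if trace.ndim > 1 else trace - trace.mean()
    out = []
    for band in (resp_band_hz, cardiac_band_hz):
        sos = butter(order, band, btype="bandpass", fs=fs_hz, output="sos")
        out.append(sosfiltfilt(sos, trace, axis=0))
    return out[0], out[1]


def detect_extrema(
    trace: np.ndarray,
    fs_hz: float,
    initial_rate_range_bpm: tuple[float, float],
    max_iter: int = 5,
    edge_exclusion_s: float = EDGE_EXCLUSION_S,
) -> Extrema:
    """Rate-adaptive peak/valley detection on a band-limited trace.

    The initial rate is the dominant in-band frequency of the trace
    (periodogram peak, clipped to the physiological range); detection then
    enforces a minimum inter-peak spacing of 0.7x the current mean interval
    and re-estimates the rate from the detected peaks, repeating until the
    peak set is stable (at most ``max_iter`` passes).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ConfigurationError("detect_extrema expects a single-channel trace")
    lo_hz, hi_hz = (r / 60.0 for r in initial_rate_range_bpm)
    f, pxx = periodogram(trace, fs=fs_hz)
    band = (f >= lo_hz) & (f <= hi_hz)
    if band.any() and np.max(pxx[band]) > 0:
        rate_hz = float(f[band][np.argmax(pxx[band])])
    else:
        rate_hz = 0.5 * (lo_hz + hi_hz)
    rate_hz = float(np.clip(rate_hz, lo_hz, hi_hz))
    prev: np.ndarray | None = None
    peaks = np.array([], dtype=int)
    for _ in range(max_iter):
        distance = max(1, int(round(0.7 * fs_hz / rate_hz)))
        peaks, _ = find_peaks(trace, distance=distance)
        if peaks.size < 2:
            raise GatingFailureError(
                "no oscillation found: fewer than two peaks detected"
            )
        rate_hz = _mean_rate_hz(peaks, trace.size, fs_hz, edge_exclusion_s)
        if prev is not None and prev.size == peaks.size and np.all(prev == peaks):
            break
        prev = peaks
    distance = max(1, int(round(0.7 * fs_hz / rate_hz)))
    valleys, _ = find_peaks(-trace, distance=distance)
    if valleys.size < 1:
        raise GatingFailureError("no valleys detected")
    edge = int(round(edge_exclusion_s * fs_hz))
    core = peaks[(peaks >= edge) & (peaks < trace.size - edge)]
    if core.size < 2:
        core = peaks
    intervals = np.diff(core).astype(float)
    return Extrema(
        peaks=peaks,
        valleys=valleys,
        rate_bpm=60.0 * rate_hz,
        intervals=intervals,
    )


def _mean_rate_hz(peaks: np.ndarray, n: int, fs_hz: float, edge_s: float) -> float:
    edge = int(round(edge_s * fs_hz))
    core = peaks[(peaks >= edge) & (peaks < n - edge)]
    if core.size < 2:
        core = peaks
    # endpoint-to-endpoint estimate: interior quantization errors telescope
    mean_interval = (core[-1] - core[0]) / (core.size - 1)
    return fs_hz / mean_interval


def select_gating_coils(
    resp_traces: np.ndarray,
    cardiac_traces: np.ndarray,
    fs_hz: float,
    resp_rate_range_bpm: tuple[float, float] = RESP_RATE_RANGE_BPM,
    cardiac_rate_range_bpm: tuple[float, float] = CARDIAC_RATE_RANGE_BPM,
) -> tuple[int, int, dict]:
    """Choose gating channels among real + virtual coils.

    Respiratory channel: smallest variance of the trace level at detected
    valleys (stability of the end-expiration baseline).  Cardiac channel:
    smallest variance of the detected R-R intervals.  Ties break toward the
    lowest channel index; channels where detection fails are excluded.
    """
    n_ch = resp_traces.shape[1]
    resp_var = np.full(n_ch, np.inf)
    card_var = np.full(n_ch, np.inf)
    details: dict[str, dict[int, Extrema]] = {"resp": {}, "cardiac": {}}
    for ch in range(n_ch):
        try:
            ext = detect_extrema(resp_traces[:, ch], fs_hz, resp_rate_range_bpm)
            details["resp"][ch] = ext
            resp_var[ch] = np.var(resp_traces[ext.valleys, ch])
        except GatingFailureError:
            pass
        try:
            ext = detect_extrema(cardiac_traces[:, ch], fs_hz, cardiac_rate_range_bpm)
            details["cardiac"][ch] = ext
            card_var[ch] = np.var(ext.intervals) if ext.intervals.size else np.inf
        except GatingFailureError:
            pass
    if not np.isfinite(resp_var).any() or not np.isfinite(card_var).any():
        raise GatingFailureError("extrema detection failed on every channel")
    return int(np.argmin(resp_var)), int(np.argmin(card_var)), details


def extract_gating(
    kspace: KSpaceData,
    resp_band_hz: tuple[float, float] = RESP_BAND_HZ,
    cardiac_band_hz: tuple[float, float] = CARDIAC_BAND_HZ,
    resp_rate_range_bpm: tuple[float, float] = RESP_RATE_RANGE_BPM,
    cardiac_rate_range_bpm: tuple[float, float] = CARDIAC_RATE_RANGE_BPM,
) -> GatingSignals:
    """Run the full gating pipeline on acquired k-space data."""
    profiles = extract_z_profiles(kspace)  # (proj, nz, n_real)
    virtual = np.sqrt(np.sum(profiles**2, axis=2, keepdims=True))
    profiles = np.concatenate([profiles, virtual], axis=2)
    n_real = profiles.shape[2] - 1

    cfg = kspace.config
    nz = cfg.n_partitions
    dz = cfg.fov_mm[2] / nz
    z_mm = (np.arange(nz) - nz // 2) * dz
    com = np.stack(
        [center_of_mass(profiles[:, :, ch], z_mm) for ch in range(profiles.shape[2])],
        axis=1,
    )
    fs = cfg.gating_fs_hz
    resp, cardiac = separate_bands(com, fs, resp_band_hz, cardiac_band_hz)
    resp_coil, cardiac_coil, details = select_gating_coils(
        resp, cardiac, fs, resp_rate_range_bpm, cardiac_rate_range_bpm
    )
    return GatingSignals(
        z_profiles=profiles,
        com_trace=com,
        resp_trace=resp,
        cardiac_trace=cardiac,
        fs_hz=fs,
        n_real=n_real,
        resp_coil=resp_coil,
        cardiac_coil=cardiac_coil,
        resp_extrema=details["resp"][resp_coil],
        cardiac_extrema=details["cardiac"][cardiac_coil],
        resp_band_hz=resp_band_hz,
        cardiac_band_hz=cardiac_band_hz,
        per_channel=details,
    )


def plot_gating(signals: GatingSignals, path: str) -> None:
    """Diagnostic four-panel figure: z-profiles, COM, and the two bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.arange(signals.com_trace.shape[0]) / signals.fs_hz
    fig, axes = plt.subplots(4, 1, figsize=(9, 9), sharex=False)
    ch = signals.cardiac_coil
    axes[0].imshow(
        signals.z_profiles[:, :, ch].T, aspect="auto", origin="lower",
        extent=[t[0], t[-1], 0, signals.z_profiles.shape[1]],
    )
    axes[0].set_ylabel("z (slice)")
    axes[1].plot(t, signals.com_trace[:, ch], lw=0.6)
    axes[1].set_ylabel("COM (mm)")
    axes[2].plot(t, signals.resp_trace[:, signals.resp_coil], lw=0.8)
    v = signals.resp_extrema.valleys
    axes[2].plot(t[v], signals.resp_trace[v, signals.resp_coil], "v", ms=3)
    axes[2].set_ylabel("respiratory")
    axes[3].plot(t, signals.cardiac_trace[:, ch], lw=0.6)
    p = signals.cardiac_extrema.peaks
    axes[3].plot(t[p], signals.cardiac_trace[p, ch], "^", ms=3)
    axes[3].set_ylabel("cardiac")
    axes[3].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
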