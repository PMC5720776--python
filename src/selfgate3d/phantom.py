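"""Dynamic digital mouse-thorax phantom and stack-of-stars k-space simulator.

The phantom emulates a post-contrast T1-weighted short-axis view of a mouse
thorax: a chest-wall ellipse (uniform along the slab), and a left-ventricular
"cylinder" spanning the central slices with bright blood in the cavity, a
darker myocardial ring, and a hyperenhanced infarct sector fixed to the wall.
Cardiac contraction periodically pulls the endocardial (inner) radius inward;
respiration translates the heart along z.  Object intensities already encode
the T1-weighted contrast; no Bloch simulation is performed, because the
self-gating/reconstruction chain operates downstream of contrast generation.

The k-space simulator evaluates, for every (projection, partition) line at
its own timestamp, the exact discrete Fourier transform of the current frame
along that spoke at that kz, multiplies by per-coil sensitivities, and adds
complex Gaussian noise.  Exactness at 16k lines is affordable because the
frame decomposes as

    frame(x, y, z, t) = static(x, y) + h(z; t) * dyn(x, y; r(t))

with a z-uniform static part, a heart z-occupancy profile h (partial-volume
weighted, shifted by respiration), and an in-plane heart difference image dyn
that depends on time only through the endocardial radius r(t), which is
quantized to a fine set of precomputed states.  Each line's samples are then
two cached-NUFFT spoke lookups times analytic kz weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .errors import ConfigurationError
from .nufft import NUFFT2D
from .trajectory import AcquisitionConfig, Trajectory, make_trajectory


@dataclass
class SignalLevels:
    """Relative T1-weighted intensities (infarct hyperenhanced vs healthy)."""

    blood: float = 1.0
    myocardium: float = 0.35
    infarct: float = 0.85
    chest_wall: float = 0.25
    lung: float = 0.04
    liver: float = 0.70
    background: float = 0.0


@dataclass
class PhantomSpec:
    """Geometry, motion, and noise of the digital mouse phantom.

    Defaults mirror the in-vivo protocol conditions: heart rate 430 bpm,
    respiratory rate 78 breaths/min (cohort means), 5 % complex Gaussian
    noise relative to the k-space peak, and a 90 deg hyperenhanced wall
    sector (a quarter of the LV circumference infarcted).
    """

    grid: tuple[int, int, int] = (128, 128, 10)
    fov_mm: tuple[float, float, float] = (58.0, 58.0, 15.0)
    heart_rate_bpm: float = 430.0
    resp_rate_bpm: float = 78.0
    lv_center_mm: tuple[float, float] = (0.0, -2.0)
    lv_outer_radius_mm: float = 4.2
    lv_wall_thickness_mm: float = 1.3
    contraction_fraction: float = 0.30
    systolic_fraction: float = 0.4
    resp_amplitude_mm: float = 1.2
    resp_width_frac: float = 0.2
    heart_z_extent_mm: tuple[float, float] = (-7.0, 2.0)
    long_shortening_mm: float = 1.5
    chest_semiaxes_mm: tuple[float, float] = (11.0, 9.0)
    chest_wall_thickness_mm: float = 1.8
    liver_center_mm: tuple[float, float] = (6.0, 4.0)
    liver_semiaxes_mm: tuple[float, float] = (3.5, 3.0)
    liver_z_extent_mm: tuple[float, float] = (2.0, 7.5)
    infarct_arc_deg: float = 90.0
    infarct_center_deg: float = 45.0
    blood_inflow_mod: float = 0.45
    signal_levels: SignalLevels = field(default_factory=SignalLevels)
    noise_sigma: float = 0.05
    arrhythmia_jitter: float = 0.02
    n_radius_levels: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.signal_levels, dict):
            self.signal_levels = SignalLevels(**self.signal_levels)
        self.validate()

    def validate(self) -> None:
        if not (0.0 <= self.contraction_fraction < 1.0):
            raise ConfigurationError("contraction_fraction must be in [0, 1)")
        if self.lv_wall_thickness_mm <= 0:
            raise ConfigurationError("lv_wall_thickness_mm must be > 0")
        if self.lv_wall_thickness_mm >= self.lv_outer_radius_mm:
            raise ConfigurationError("wall thickness must be < outer radius")
        if self.heart_rate_bpm <= 0 or self.resp_rate_bpm <= 0:
            raise ConfigurationError("rates must be > 0")
        if self.signal_levels.infarct <= self.signal_levels.myocardium:
            raise ConfigurationError(
                "infarct intensity must exceed healthy myocardium "
                "(delayed hyperenhancement)"
            )
        if not (0 < self.systolic_fraction <= 1):
            raise ConfigurationError("systolic_fraction must be in (0, 1]")
        if self.n_radius_levels < 1:
            raise ConfigurationError("n_radius_levels must be >= 1")

    # -- cardiac/respiratory kinematics ------------------------------------

    @property
    def r_diastole_mm(self) -> float:
        return self.lv_outer_radius_mm - self.lv_wall_thickness_mm

    @property
    def r_systole_mm(self) -> float:
        return self.r_diastole_mm * (1.0 - self.contraction_fraction)

    def radius_levels_mm(self) -> np.ndarray:
        """Quantized endocardial radius states, systole -> diastole."""
        if self.n_radius_levels == 1 or self.contraction_fraction == 0.0:
            return np.array([self.r_diastole_mm])
        return np.linspace(
            self.r_systole_mm, self.r_diastole_mm, self.n_radius_levels
        )

    def cycle_lengths_ms(self, duration_ms: float, rng: np.random.Generator) -> np.ndarray:
        """Cardiac cycle lengths covering [0, duration], with jitter.

        Jitter is a truncated normal (clipped at 3 sigma) fractional
        perturbation per cycle — the arrhythmia knob that exercises the
        +/-30 % cycle-rejection rule.
        """
        base = 60000.0 / self.heart_rate_bpm
        n = int(np.ceil(duration_ms / base)) + 8
        eps = np.clip(rng.standard_normal(n), -3.0, 3.0)
        lengths = base * (1.0 + self.arrhythmia_jitter * eps)
        return np.maximum(lengths, 0.1 * base)

    @staticmethod
    def _phase_in_cycles(t_ms: np.ndarray, boundaries_ms: np.ndarray):
        """(cycle index, fractional phase in [0,1)) for each time."""
        idx = np.searchsorted(boundaries_ms, t_ms, side="right") - 1
        idx = np.clip(idx, 0, len(boundaries_ms) - 2)
        frac = (t_ms - boundaries_ms[idx]) / np.diff(boundaries_ms)[idx]
        return idx, np.clip(frac, 0.0, 1.0 - 1e-12)

    def contraction_weight(self, phase: np.ndarray) -> np.ndarray:
        """Systolic pulse: raised-sine over the systolic fraction, then rest.

        The contraction peak sits mid-systole; late diastole (the quiescent
        period) is flat at zero displacement.
        """
        phase = np.asarray(phase, dtype=float)
        s = self.systolic_fraction
        w = np.where(phase < s, np.sin(np.pi * phase / s) ** 2, 0.0)
        return w

    def inflow_modulation(self, phase: np.ndarray) -> np.ndarray:
        """Fractional cavity-blood brightness modulation over the cycle.

        Emulates flow-related enhancement in GRE imaging: fresh unsaturated
        spins entering the slab during systolic inflow brighten the cavity;
        modeled as a zero-mean first harmonic peaking just after
        mid-systole.
        """
        phase = np.asarray(phase, dtype=float)
        return self.blood_inflow_mod * np.cos(2.0 * np.pi * (phase - 0.2))

    def resp_displacement_mm(self, t_ms: np.ndarray) -> np.ndarray:
        """Bulk z-translation: a Gaussian inspiration bump per breath.

        Most of each breath is spent near baseline (end-expiration), as in
        rodent ventilated breathing, so the lowest-amplitude respiratory bin
        is the most populated one.
        """
        period = 60000.0 / self.resp_rate_bpm
        phase = np.mod(np.asarray(t_ms, dtype=float), period) / period
        w = self.resp_width_frac
        return self.resp_amplitude_mm * np.exp(-(((phase - 0.5) / w) ** 2))


# ---------------------------------------------------------------------------
# rendering


EDGE_WIDTH_PX = 1.5  # anti-aliasing ramp width, in pixels


def _smooth_disk(rr: np.ndarray, radius: float, edge: float) -> np.ndarray:
    """Anti-aliased disk indicator: 1 inside, 0 outside, smooth ramp."""
    return np.clip((radius - rr) / (EDGE_WIDTH_PX * edge) + 0.5, 0.0, 1.0)


def _heart_inplane(spec: PhantomSpec, shape, fov, r_in_mm: float) -> np.ndarray:
    """In-plane heart difference image for one endocardial radius state.

    Returns heart intensity minus the chest-wall intensity it replaces, so
    it can be added on top of the z-uniform static image.
    """
    nx, ny = shape
    dx, dy = fov[0] / nx, fov[1] / ny
    x = (np.arange(nx) - nx // 2) * dx - spec.lv_center_mm[0]
    y = (np.arange(ny) - ny // 2) * dy - spec.lv_center_mm[1]
    xx, yy = np.meshgrid(x, y, indexing="ij")
    rr = np.hypot(xx, yy)
    edge = max(dx, dy)
    lv = spec.signal_levels
    outer = _smooth_disk(rr, spec.lv_outer_radius_mm, edge)
    inner = _smooth_disk(rr, r_in_mm, edge)
    wall = outer - inner

    ang = np.rad2deg(np.arctan2(yy, xx))
    half = spec.infarct_arc_deg / 2.0
    dang = np.mod(ang - spec.infarct_center_deg + 180.0, 360.0) - 180.0
    sector = (np.abs(dang) <= half).astype(float)

    img = (
        inner * lv.blood
        + wall * ((1.0 - sector) * lv.myocardium + sector * lv.infarct)
    )
    return img - outer * lv.chest_wall


def _blood_inplane(spec: PhantomSpec, shape, fov, r_in_mm: float) -> np.ndarray:
    """Cavity blood disk at unit relative brightness (inflow carrier)."""
    nx, ny = shape
    dx, dy = fov[0] / nx, fov[1] / ny
    x = (np.arange(nx) - nx // 2) * dx - spec.lv_center_mm[0]
    y = (np.arange(ny) - ny // 2) * dy - spec.lv_center_mm[1]
    xx, yy = np.meshgrid(x, y, indexing="ij")
    rr = np.hypot(xx, yy)
    edge = max(dx, dy)
    return _smooth_disk(rr, r_in_mm, edge) * spec.signal_levels.blood


def _liver_inplane(spec: PhantomSpec, shape, fov) -> np.ndarray:
    """In-plane liver bump (bright post-contrast), disjoint from the heart."""
    nx, ny = shape
    dx, dy = fov[0] / nx, fov[1] / ny
    x = (np.arange(nx) - nx // 2) * dx - spec.liver_center_mm[0]
    y = (np.arange(ny) - ny // 2) * dy - spec.liver_center_mm[1]
    xx, yy = np.meshgrid(x, y, indexing="ij")
    a, b = spec.liver_semiaxes_mm
    rho = np.hypot(xx / a, yy / b)
    grad = EDGE_WIDTH_PX * max(dx / a, dy / b)
    ellipse = np.clip((1.0 - rho) / grad + 0.5, 0.0, 1.0)
    lv = spec.signal_levels
    return ellipse * (lv.liver - lv.chest_wall)


def slab_z_profile(
    extent_mm: tuple[float, float], nz: int, dz_mm: float, dz_shift_mm
) -> np.ndarray:
    """Partial-volume occupancy of a translating z slab, per slice.

    ``dz_shift_mm`` may be scalar or an array; the slice axis is last.
    """
    z_lo = (np.arange(nz) - nz // 2) * dz_mm - dz_mm / 2.0
    z_hi = z_lo + dz_mm
    shift = np.asarray(dz_shift_mm, dtype=float)[..., None]
    lo = np.maximum(z_lo, extent_mm[0] + shift)
    hi = np.minimum(z_hi, extent_mm[1] + shift)
    return np.clip(hi - lo, 0.0, None) / dz_mm


def _static_inplane(spec: PhantomSpec, shape, fov) -> np.ndarray:
    """z-uniform static content: body-wall ring around near-dark lungs.

    The thorax cross-section is mostly air-filled lung, so the static mass
    is a thin muscle/fat ring — as in a real short-axis mouse scan, where
    the heart dominates the slab signal.
    """
    nx, ny = shape
    dx, dy = fov[0] / nx, fov[1] / ny
    x = (np.arange(nx) - nx // 2) * dx
    y = (np.arange(ny) - ny // 2) * dy
    xx, yy = np.meshgrid(x, y, indexing="ij")
    a, b = spec.chest_semiaxes_mm
    t = spec.chest_wall_thickness_mm
    lv = spec.signal_levels

    def ell(aa, bb):
        rho = np.hypot(xx / aa, yy / bb)
        grad = EDGE_WIDTH_PX * max(dx / aa, dy / bb)
        return np.clip((1.0 - rho) / grad + 0.5, 0.0, 1.0)

    outer = ell(a, b)
    inner = ell(a - t, b - t)
    return (
        lv.background
        + (lv.chest_wall - lv.background) * (outer - inner)
        + (lv.lung - lv.background) * inner
    )


def heart_z_profile(
    spec: PhantomSpec, nz: int, dz_mm: float, dz_shift_mm,
    shortening_mm=0.0,
) -> np.ndarray:
    """Partial-volume occupancy of the heart per slice.

    The whole extent translates with respiration; systolic longitudinal
    shortening pulls the basal end (upper bound) toward the fixed apex, the
    dominant through-slab source of the cardiac self-gating signal.
    Scalar or array arguments broadcast; the slice axis is last.
    """
    z_lo = (np.arange(nz) - nz // 2) * dz_mm - dz_mm / 2.0
    z_hi = z_lo + dz_mm
    h0, h1 = spec.heart_z_extent_mm
    shift = np.asarray(dz_shift_mm, dtype=float)[..., None]
    short = np.asarray(shortening_mm, dtype=float)[..., None]
    lo = np.maximum(z_lo, h0 + shift)
    hi = np.minimum(z_hi, h1 + shift - short)
    return np.clip(hi - lo, 0.0, None) / dz_mm


def _quantize_radius(spec: PhantomSpec, r_in_mm: np.ndarray) -> np.ndarray:
    levels = spec.radius_levels_mm()
    if levels.size == 1:
        return np.zeros(np.shape(r_in_mm), dtype=int)
    step = levels[1] - levels[0]
    idx = np.round((np.asarray(r_in_mm) - levels[0]) / step).astype(int)
    return np.clip(idx, 0, levels.size - 1)


def render_frame(
    spec: PhantomSpec,
    t_ms: float,
    shape: tuple[int, int, int] | None = None,
    fov_mm: tuple[float, float, float] | None = None,
    cycle_boundaries_ms: np.ndarray | None = None,
) -> np.ndarray:
    """Render the phantom volume at time ``t_ms`` (real-valued, (nx, ny, nz)).

    Without explicit cycle boundaries the cardiac cycle is strictly periodic
    at ``heart_rate_bpm`` (no jitter), so frames one period apart coincide.
    """
    if t_ms < 0:
        raise ConfigurationError("t_ms must be >= 0")
    shape = tuple(shape if shape is not None else spec.grid)
    fov = tuple(fov_mm if fov_mm is not None else spec.fov_mm)
    nx, ny, nz = shape
    if cycle_boundaries_ms is None:
        period = 60000.0 / spec.heart_rate_bpm
        phase = np.mod(float(t_ms), period) / period
    else:
        _, phase = PhantomSpec._phase_in_cycles(
            np.atleast_1d(float(t_ms)), cycle_boundaries_ms
        )
        phase = float(phase[0])
    w = float(spec.contraction_weight(phase))
    r_in = spec.r_diastole_mm - w * (spec.r_diastole_mm - spec.r_systole_mm)
    level = int(_quantize_radius(spec, np.array(r_in))[()])
    r_q = spec.radius_levels_mm()[level]

    dz = float(spec.resp_displacement_mm(np.atleast_1d(float(t_ms)))[0])
    static = _static_inplane(spec, (nx, ny), fov)
    dyn = _heart_inplane(spec, (nx, ny), fov, r_q)
    m = float(spec.inflow_modulation(phase))
    dyn = dyn + m * _blood_inplane(spec, (nx, ny), fov, r_q)
    liver = _liver_inplane(spec, (nx, ny), fov)
    h = heart_z_profile(spec, nz, fov[2] / nz, dz, spec.long_shortening_mm * w)
    g = slab_z_profile(spec.liver_z_extent_mm, nz, fov[2] / nz, dz)
    return (
        static[:, :, None]
        + dyn[:, :, None] * h[None, None, :]
        + liver[:, :, None] * g[None, None, :]
    )


def wall_masks(
    spec: PhantomSpec, shape: tuple[int, int], fov_mm: tuple[float, float],
    r_in_mm: float | None = None,
    margin_mm: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """(wall mask, infarct-sector mask) on the in-plane grid, boolean.

    Ground-truth ROI geometry for quantification; evaluated at the
    diastolic radius unless ``r_in_mm`` is given.  A positive ``margin_mm``
    shrinks the ring radially on both sides, keeping the ROI away from
    partial-volume voxels at the blood/wall and wall/background boundaries
    (as one would place it manually).
    """
    nx, ny = shape
    dx, dy = fov_mm[0] / nx, fov_mm[1] / ny
    r_in = spec.r_diastole_mm if r_in_mm is None else r_in_mm
    x = (np.arange(nx) - nx // 2) * dx - spec.lv_center_mm[0]
    y = (np.arange(ny) - ny // 2) * dy - spec.lv_center_mm[1]
    xx, yy = np.meshgrid(x, y, indexing="ij")
    rr = np.hypot(xx, yy)
    wall = (rr <= spec.lv_outer_radius_mm - margin_mm) & (rr > r_in + margin_mm)
    ang = np.rad2deg(np.arctan2(yy, xx))
    half = spec.infarct_arc_deg / 2.0
    dang = np.mod(ang - spec.infarct_center_deg + 180.0, 360.0) - 180.0
    sector = wall & (np.abs(dang) <= half)
    return wall, sector


def cavity_mask(
    spec: PhantomSpec, shape: tuple[int, int], fov_mm: tuple[float, float],
    shrink_mm: float = 0.5,
) -> np.ndarray:
    """Ventricular-cavity ROI (systolic inner radius minus a margin)."""
    nx, ny = shape
    dx, dy = fov_mm[0] / nx, fov_mm[1] / ny
    x = (np.arange(nx) - nx // 2) * dx - spec.lv_center_mm[0]
    y = (np.arange(ny) - ny // 2) * dy - spec.lv_center_mm[1]
    xx, yy = np.meshgrid(x, y, indexing="ij")
    rr = np.hypot(xx, yy)
    return rr <= max(spec.r_systole_mm - shrink_mm, 2 * max(dx, dy))


# ---------------------------------------------------------------------------
# coil sensitivities


def make_coil_maps(
    grid: tuple[int, int], n_coils: int, seed: int = 0
) -> np.ndarray:
    """Smooth complex coil sensitivity maps, (n_coils, nx, ny).

    A single coil is a uniform map of ones.  Multiple coils are Gaussian
    magnitude profiles centered at equally spaced positions around the FOV
    (a surface-coil array wrapped around the animal) with a gentle linear
    phase; the sum-of-squares magnitude is positive everywhere.
    """
    if n_coils < 1:
        raise ConfigurationError("n_coils must be >= 1")
    nx, ny = int(grid[0]), int(grid[1])
    if n_coils == 1:
        return np.ones((1, nx, ny), dtype=complex)
    rng = np.random.default_rng(seed)
    x = (np.arange(nx) - nx // 2) / nx
    y = (np.arange(ny) - ny // 2) / ny
    xx, yy = np.meshgrid(x, y, indexing="ij")
    maps = np.empty((n_coils, nx, ny), dtype=complex)
    for c in range(n_coils):
        ang = 2.0 * np.pi * c / n_coils
        cx, cy = 0.35 * np.cos(ang), 0.35 * np.sin(ang)
        width = 0.28 * (1.0 + 0.1 * rng.standard_normal())
        mag = 0.06 + np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * width**2)))
        phase = 2.0 * np.pi * (0.15 * (xx * np.cos(ang) + yy * np.sin(ang)))
        phase = phase + rng.uniform(0, 2 * np.pi)
        maps[c] = mag * np.exp(1j * phase)
    return maps


# ---------------------------------------------------------------------------
# k-space simulation


@dataclass
class GroundTruth:
    """Noiseless reference data retained by the simulator."""

    phase_frames: np.ndarray  # (n_gt_phases, nx, ny, nz), resp at baseline
    phase_centers: np.ndarray  # cardiac phase fraction of each frame
    profile_times_ms: np.ndarray  # per-projection self-gating timestamp
    cardiac_phase: np.ndarray  # fraction in [0,1) per projection
    cycle_index: np.ndarray  # cardiac cycle id per projection
    resp_mm: np.ndarray  # z displacement per projection
    r_in_mm: np.ndarray  # endocardial radius per projection
    cycle_boundaries_ms: np.ndarray
    heart_rate_bpm: float  # realized mean rate over the scan
    resp_rate_bpm: float
    coil_maps: np.ndarray


@dataclass
class KSpaceData:
    """Acquired multi-coil radial data plus trajectory and provenance."""

    samples: np.ndarray  # (n_projections, n_partitions, n_readout, n_coils)
    trajectory: Trajectory
    config: AcquisitionConfig
    ground_truth: GroundTruth | None = None
    spec: PhantomSpec | None = None

    def __post_init__(self) -> None:
        expect = (
            self.config.n_projections,
            self.config.n_partitions,
            self.config.n_readout,
            self.config.n_coils,
        )
        if tuple(self.samples.shape) != expect:
            raise ConfigurationError(
                f"samples shape {self.samples.shape} != config {expect}"
            )


def simulate_kspace(
    spec: PhantomSpec,
    config: AcquisitionConfig,
    n_gt_phases: int = 8,
    seed: int | None = None,
) -> KSpaceData:
    """Simulate the full stack-of-stars acquisition of the beating phantom.

    Every (projection, partition) line is evaluated at its own timestamp;
    deterministic for a fixed seed.  The phantom is rendered on the
    reconstruction grid (``config.matrix`` in-plane, ``n_partitions``
    slices) so simulated data and reconstructions share one coordinate
    system.
    """
    spec.validate()
    config.validate()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    traj = make_trajectory(config)
    nx, ny = int(config.matrix[0]), int(config.matrix[1])
    nz = config.n_partitions
    fov = config.fov_mm
    n_proj, n_read = config.n_projections, config.n_readout
    n_coils = config.n_coils

    coil_maps = make_coil_maps((nx, ny), n_coils, seed=seed)

    # timeline: cardiac cycles with jitter, respiration strictly periodic
    t_lines = traj.timestamps_ms  # (n_proj, nz)
    duration = float(t_lines[-1, -1]) + config.tr_ms
    lengths = spec.cycle_lengths_ms(duration, rng)
    boundaries = np.concatenate([[0.0], np.cumsum(lengths)])
    cyc_idx, phase = PhantomSpec._phase_in_cycles(t_lines.ravel(), boundaries)
    w = spec.contraction_weight(phase).reshape(n_proj, nz)
    r_in = spec.r_diastole_mm - w.ravel() * (spec.r_diastole_mm - spec.r_systole_mm)
    level = _quantize_radius(spec, r_in).reshape(n_proj, nz)
    dz = spec.resp_displacement_mm(t_lines.ravel()).reshape(n_proj, nz)

    # cached oversampled FFT grids: static per coil, dynamic per (level, coil)
    plan = NUFFT2D((nx, ny))
    static2d = _static_inplane(spec, (nx, ny), fov)
    levels_mm = spec.radius_levels_mm()
    liver2d = _liver_inplane(spec, (nx, ny), fov)
    g_static = [plan.plan_grid(coil_maps[c] * static2d) for c in range(n_coils)]
    g_liver = [plan.plan_grid(coil_maps[c] * liver2d) for c in range(n_coils)]
    g_dyn = [
        [plan.plan_grid(coil_maps[c] * _heart_inplane(spec, (nx, ny), fov, r))
         for c in range(n_coils)]
        for r in levels_mm
    ]
    g_blood = [
        [plan.plan_grid(coil_maps[c] * _blood_inplane(spec, (nx, ny), fov, r))
         for c in range(n_coils)]
        for r in levels_mm
    ]
    inflow = spec.inflow_modulation(phase).reshape(n_proj, nz)

    # per-angle interpolation plans (shared by every partition of a projection)
    pts = traj.kxy.reshape(-1, 2)
    ix, iy, wx, wy = plan.point_weights(pts)
    ix = ix.reshape(n_proj, n_read, -1)
    iy = iy.reshape(n_proj, n_read, -1)
    wx = wx.reshape(n_proj, n_read, -1)
    wy = wy.reshape(n_proj, n_read, -1)

    # kz encode weights: line (p, j_acq) measures centered frequency f_j
    kz = traj.kz_order  # partition index per acquired position
    f_j = (kz - nz // 2) / nz
    zc = np.arange(nz) - nz // 2
    # dynamic kz weights per line: DFT of the shifted occupancy profiles
    dz_mm = fov[2] / nz
    h_prof = heart_z_profile(spec, nz, dz_mm, dz, spec.long_shortening_mm * w)
    l_prof = slab_z_profile(spec.liver_z_extent_mm, nz, dz_mm, dz)
    phase_z = np.exp(-2j * np.pi * f_j[:, None] * zc[None, :])  # (acq pos, z)
    h_weights = np.einsum("paz,az->pa", h_prof, phase_z)
    l_weights = np.einsum("paz,az->pa", l_prof, phase_z)

    samples = np.zeros((n_proj, nz, n_read, n_coils), dtype=complex)

    def _gather(flat: np.ndarray, rows: np.ndarray, chunk: int = 64) -> np.ndarray:
        """Interpolate the gridded spectrum along the selected spokes."""
        out = np.empty((rows.size, n_read), dtype=complex)
        m2 = plan.grid_shape[1]
        for s in range(0, rows.size, chunk):
            r = rows[s : s + chunk]
            idx = (ix[r][:, :, :, None] * m2 + iy[r][:, :, None, :]).reshape(
                r.size, n_read, -1
            )
            w = (wx[r][:, :, :, None] * wy[r][:, :, None, :]).reshape(
                r.size, n_read, -1
            )
            out[s : s + chunk] = np.einsum("prw,prw->pr", flat[idx], w)
        return out

    # static part contributes only to the kz = 0 partition (z-uniform)
    dc_part = int(np.nonzero(kz == nz // 2)[0][0])
    all_rows = np.arange(n_proj)
    for c in range(n_coils):
        samples[:, dc_part, :, c] = nz * _gather(g_static[c].reshape(-1), all_rows)
        s_liv = _gather(g_liver[c].reshape(-1), all_rows)
        samples[:, :, :, c] += l_weights[:, :, None] * s_liv[:, None, :]

    # dynamic part, grouped by radius level
    for lev in range(len(levels_mm)):
        mask = level == lev  # (n_proj, nz)
        if not mask.any():
            continue
        p_sel = np.nonzero(mask.any(axis=1))[0]
        for c in range(n_coils):
            s_dyn = _gather(g_dyn[lev][c].reshape(-1), p_sel)
            s_blood = _gather(g_blood[lev][c].reshape(-1), p_sel)
            for local, p in enumerate(p_sel):
                parts = np.nonzero(mask[p])[0]
                hw = h_weights[p, parts][:, None]
                samples[p, parts, :, c] += hw * (
                    s_dyn[local][None, :]
                    + inflow[p, parts][:, None] * s_blood[local][None, :]
                )

    if spec.noise_sigma > 0:
        peak = np.max(np.abs(samples))
        sd = spec.noise_sigma * peak / np.sqrt(2.0)
        noise = rng.standard_normal(samples.shape) + 1j * rng.standard_normal(
            samples.shape
        )
        samples = samples + sd * noise

    # ground truth: noiseless frames at evenly spaced cardiac phases,
    # respiration at baseline, plus the true motion traces
    centers = (np.arange(n_gt_phases) + 0.5) / n_gt_phases
    frames = np.empty((n_gt_phases, nx, ny, nz))
    for k, ph in enumerate(centers):
        wk = float(spec.contraction_weight(ph))
        rk = spec.r_diastole_mm - wk * (spec.r_diastole_mm - spec.r_systole_mm)
        rq = levels_mm[int(_quantize_radius(spec, np.array(rk))[()])]
        dyn = _heart_inplane(spec, (nx, ny), fov, rq)
        dyn = dyn + float(spec.inflow_modulation(ph)) * _blood_inplane(
            spec, (nx, ny), fov, rq
        )
        hk = heart_z_profile(spec, nz, dz_mm, 0.0, spec.long_shortening_mm * wk)
        gk = slab_z_profile(spec.liver_z_extent_mm, nz, dz_mm, 0.0)
        frames[k] = (
            static2d[:, :, None]
            + dyn[:, :, None] * hk[None, None, :]
            + liver2d[:, :, None] * gk[None, None, :]
        )

    mid = nz // 2
    t_mid = t_lines[:, mid]
    cyc_mid, phase_mid = PhantomSpec._phase_in_cycles(t_mid, boundaries)
    in_scan = boundaries[1:] <= duration
    realized_hr = 60000.0 / float(np.mean(lengths[: max(1, int(in_scan.sum()))]))
    gt = GroundTruth(
        phase_frames=frames,
        phase_centers=centers,
        profile_times_ms=t_mid,
        cardiac_phase=phase_mid,
        cycle_index=cyc_mid,
        resp_mm=spec.resp_displacement_mm(t_mid),
        r_in_mm=r_in.reshape(n_proj, nz)[:, mid],
        cycle_boundaries_ms=boundaries,
        heart_rate_bpm=realized_hr,
        resp_rate_bpm=spec.resp_rate_bpm,
        coil_maps=coil_maps,
    )
    return KSpaceData(
        samples=samples, trajectory=traj, config=config, ground_truth=gt, spec=spec
    )


def spec_to_yaml(spec: PhantomSpec) -> str:
    return yaml.safe_dump(asdict(spec), sort_keys=False)


def spec_from_yaml(text: str) -> PhantomSpec:
    d = yaml.safe_load(text)
    if not isinstance(d, dict):
        raise ConfigurationError("phantom spec YAML must be a mapping")
    d = dict(d)
    for key in ("grid", "fov_mm", "lv_center_mm", "heart_z_extent_mm",
                "chest_semiaxes_mm", "liver_center_mm", "liver_semiaxes_mm",
                "liver_z_extent_mm"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return PhantomSpec(**d)
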