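"""Golden-angle stack-of-stars sampling pattern and acquisition timeline.

The acquisition interleaves Cartesian partition (kz) encoding with in-plane
radial spokes: all ``n_partitions`` kz lines of one projection angle are
collected back-to-back before the angle advances by the golden-angle
increment (180/phi ~ 111.246 deg).  The k-space-center sample of each line is
therefore re-acquired every ``tr_ms * n_partitions`` milliseconds, which sets
the sampling rate of the self-gating signal.

Conventions shared by every module:

* in-plane k-space coordinates are in cycles/FOV, normalized to [-0.5, 0.5);
* with an even readout length ``n_readout`` the DC sample sits at index
  ``n_readout // 2`` (0-based) and is exactly at the k-space origin;
* projection angles are stored mod 360 deg (full spokes, no merging of the
  mod-180 pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .errors import ConfigurationError

#: Golden-angle increment, 180 / golden ratio, in degrees.
GOLDEN_ANGLE_DEG = 180.0 / ((1.0 + np.sqrt(5.0)) / 2.0)  # 111.2461...


@dataclass
class AcquisitionConfig:
    """Scanner/sequence parameters of the stack-of-stars acquisition.

    Defaults follow the in-vivo mouse protocol: TR 4.2 ms, 10 partitions,
    1600 continuously acquired projections, 58 x 58 x 15 mm FOV at
    0.3 x 0.3 x 1.5 mm resolution (192 in-plane matrix).
    """

    tr_ms: float = 4.2
    n_partitions: int = 10
    n_projections: int = 1600
    n_readout: int | None = None  # default: 2x readout oversampling
    fov_mm: tuple[float, float, float] = (58.0, 58.0, 15.0)
    matrix: tuple[int, int, int] = (192, 192, 10)
    golden_angle_deg: float = 111.246
    n_coils: int = 4

    def __post_init__(self) -> None:
        if self.n_readout is None:
            self.n_readout = 2 * int(self.matrix[0])
        self.validate()

    def validate(self) -> None:
        if self.tr_ms <= 0:
            raise ConfigurationError(f"tr_ms must be > 0, got {self.tr_ms}")
        for name in ("n_partitions", "n_projections", "n_readout", "n_coils"):
            v = getattr(self, name)
            if int(v) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {v}")
        if any(int(m) < 1 for m in self.matrix):
            raise ConfigurationError(f"matrix entries must be >= 1, got {self.matrix}")
        if any(f <= 0 for f in self.fov_mm):
            raise ConfigurationError(f"fov_mm entries must be > 0, got {self.fov_mm}")

    @property
    def profile_interval_ms(self) -> float:
        """Temporal spacing of consecutive self-gating profiles (ms)."""
        return self.tr_ms * self.n_partitions

    @property
    def gating_fs_hz(self) -> float:
        """Sampling rate of the self-gating signal in Hz."""
        return 1000.0 / self.profile_interval_ms

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        return tuple(f / m for f, m in zip(self.fov_mm, self.matrix))

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "AcquisitionConfig":
        d = yaml.safe_load(text)
        if not isinstance(d, dict):
            raise ConfigurationError("acquisition config YAML must be a mapping")
        d = dict(d)
        for key in ("fov_mm", "matrix"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Trajectory:
    """Sampling pattern plus per-line acquisition timeline.

    Attributes
    ----------
    angles_deg : (n_projections,) projection angles, ``(i * increment) % 360``.
    kxy : (n_projections, n_readout, 2) in-plane coordinates, cycles/FOV in
        [-0.5, 0.5); the center readout sample of every spoke is exactly 0.
    kz_order : (n_partitions,) partition index acquired at each position
        within a projection (partition-first; sequential by default).
    timestamps_ms : (n_projections, n_partitions) acquisition time of each
        line, increasing by tr_ms per line, partition-first.
    """

    angles_deg: np.ndarray
    kxy: np.ndarray
    kz_order: np.ndarray
    timestamps_ms: np.ndarray
    config: AcquisitionConfig = field(repr=False, default=None)

    @property
    def n_projections(self) -> int:
        return self.angles_deg.shape[0]

    @property
    def n_readout(self) -> int:
        return self.kxy.shape[1]

    @property
    def dc_index(self) -> int:
        return self.n_readout // 2


def profile_interval(config: AcquisitionConfig) -> float:
    """Return tr_ms * n_partitions, the self-gating profile spacing in ms."""
    return config.profile_interval_ms


def spoke_angles(n_projections: int, golden_angle_deg: float = 111.246) -> np.ndarray:
    """Projection angles ``(i * increment) mod 360`` in degrees."""
    i = np.arange(n_projections, dtype=float)
    return np.mod(i * golden_angle_deg, 360.0)


def make_trajectory(config: AcquisitionConfig) -> Trajectory:
    """Build the golden-angle stack-of-stars trajectory for ``config``.

    Spokes are full diameters: readout sample m carries radius
    ``(m - n_readout//2) / n_readout`` cycles/FOV, so coordinates span
    [-0.5, 0.5) and the DC sample is exactly at the origin.
    """
    config.validate()
    angles = spoke_angles(config.n_projections, config.golden_angle_deg)
    theta = np.deg2rad(angles)

    m = np.arange(config.n_readout, dtype=float) - config.n_readout // 2
    radius = m / config.n_readout  # cycles/FOV in [-0.5, 0.5)
    kxy = np.empty((config.n_projections, config.n_readout, 2))
    kxy[:, :, 0] = np.cos(theta)[:, None] * radius[None, :]
    kxy[:, :, 1] = np.sin(theta)[:, None] * radius[None, :]
    # the DC sample must be bit-exact zero for self-gating extraction
    kxy[:, config.n_readout // 2, :] = 0.0

    kz_order = np.arange(config.n_partitions)
    line_index = (
        np.arange(config.n_projections)[:, None] * config.n_partitions
        + np.arange(config.n_partitions)[None, :]
    )
    timestamps = line_index * config.tr_ms
    return Trajectory(
        angles_deg=angles,
        kxy=kxy,
        kz_order=kz_order,
        timestamps_ms=timestamps.astype(float),
        config=config,
    )
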