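"""Nonuniform FFT on the radial sampling pattern.

Type-2 (forward: Cartesian image -> nonuniform k-space samples) and type-1
(adjoint: samples -> image) transforms via Kaiser-Bessel gridding on a
2x-oversampled FFT grid.  Conventions:

* image pixels sit at integer coordinates centered on the array
  (x = -N//2 .. N//2 - 1);
* nonuniform frequencies are in cycles/pixel, restricted to [-0.5, 0.5);
* forward evaluates S(k) = sum_x f(x) exp(-2 pi i k . x), the adjoint is its
  exact conjugate transpose (spreading with the same weights), so the pair
  passes a dot-product test to machine precision.

Kernel: Kaiser-Bessel, width 8 grid cells, shape parameter from Beatty's
min-max rule; with 2x oversampling this keeps the approximation error below
1e-7 relative to direct summation, comfortably inside the 1e-6 budget the
reconstruction relies on.
"""

from __future__ import annotations

import numpy as np
from scipy.special import i0

from .errors import ConfigurationError

_OVERSAMP = 2.0
_WIDTH = 8


def _beatty_beta(width: int, oversamp: float) -> float:
    return np.pi * np.sqrt((width / oversamp) ** 2 * (oversamp - 0.5) ** 2 - 0.8)


def _kernel(u: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Kaiser-Bessel kernel on |u| <= width/2 grid cells, zero outside."""
    t = 2.0 * u / width
    inside = np.abs(t) <= 1.0
    out = np.zeros_like(u, dtype=float)
    out[inside] = i0(beta * np.sqrt(1.0 - t[inside] ** 2))
    return out


def _kernel_ft(f: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Continuous Fourier transform of the kernel at frequency f (cycles/cell)."""
    arg = beta**2 - (np.pi * width * f) ** 2
    out = np.empty_like(arg)
    pos = arg > 0
    sq = np.sqrt(np.abs(arg))
    out[pos] = np.sinh(sq[pos]) / sq[pos]
    out[~pos] = np.sinc(sq[~pos] / np.pi)
    return width * out


class NUFFT2D:
    """Gridding NUFFT plan for a fixed 2D image shape.

    Parameters
    ----------
    shape : (N1, N2) image dimensions.
    points : optional (P, 2) nonuniform coordinates in cycles/pixel within
        [-0.5, 0.5); if given, interpolation indices/weights are precomputed
        and `forward`/`adjoint` can be called without re-passing points.
    """

    def __init__(self, shape: tuple[int, int], points: np.ndarray | None = None):
        self.shape = (int(shape[0]), int(shape[1]))
        self.grid_shape = tuple(int(round(_OVERSAMP * n)) for n in self.shape)
        self.beta = _beatty_beta(_WIDTH, _OVERSAMP)
        self._apod = [
            self._apodization(n, m) for n, m in zip(self.shape, self.grid_shape)
        ]
        self._plan = self.point_weights(points) if points is not None else None

    def _apodization(self, n: int, m: int) -> np.ndarray:
        x = np.arange(n, dtype=float) - n // 2
        return _kernel_ft(x / m, _WIDTH, self.beta)

    # -- point machinery ---------------------------------------------------

    def point_weights(self, points: np.ndarray):
        """Precompute gridding indices and separable kernel weights.

        Returns (ix, iy, wx, wy): integer index arrays (P, W) into the
        oversampled grid (wrapped) and the matching kernel weights.
        """
        points = np.asarray(points, dtype=float)
        if points.ndim != 2 or points.shape[1] != 2:
            raise ConfigurationError("points must have shape (P, 2)")
        if np.any(points < -0.5 - 1e-9) or np.any(points > 0.5 + 1e-9):
            raise ConfigurationError("coordinates must lie in [-0.5, 0.5)")
        # k-space is periodic on the unit torus; +0.5 is the same as -0.5
        points = np.mod(points + 0.5, 1.0) - 0.5
        out = []
        offsets = np.arange(_WIDTH) - _WIDTH // 2 + 1
        for axis, m in enumerate(self.grid_shape):
            g = points[:, axis] * m  # target position in grid-frequency units
            base = np.floor(g).astype(np.int64)
            idx = base[:, None] + offsets[None, :]
            w = _kernel(g[:, None] - idx, _WIDTH, self.beta)
            # centered index -> array index, wrapped onto the periodic grid
            out.append(((idx + m // 2) % m, w))
        (ix, wx), (iy, wy) = out
        return ix, iy, wx, wy

    # -- grid-space helpers (shared with the k-space simulator) ------------

    def plan_grid(self, image: np.ndarray) -> np.ndarray:
        """Deapodize, zero-pad, and FFT an image onto the oversampled grid."""
        n1, n2 = self.shape
        m1, m2 = self.grid_shape
        if image.shape != self.shape:
            raise ConfigurationError(f"image shape {image.shape} != plan {self.shape}")
        pre = image / np.outer(self._apod[0], self._apod[1])
        padded = np.zeros((m1, m2), dtype=complex)
        padded[
            m1 // 2 - n1 // 2 : m1 // 2 - n1 // 2 + n1,
            m2 // 2 - n2 // 2 : m2 // 2 - n2 // 2 + n2,
        ] = pre
        return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(padded)))

    def interpolate(
        self, grid: np.ndarray, plan=None, chunk: int = 1 << 17
    ) -> np.ndarray:
        """Evaluate the gridded spectrum at the planned nonuniform points."""
        ix, iy, wx, wy = plan if plan is not None else self._plan
        m2 = self.grid_shape[1]
        flat = grid.reshape(-1)
        n = ix.shape[0]
        out = np.empty(n, dtype=complex)
        for s in range(0, n, chunk):
            e = min(s + chunk, n)
            sub = flat[(ix[s:e, :, None] * m2 + iy[s:e, None, :]).reshape(e - s, -1)]
            w = (wx[s:e, :, None] * wy[s:e, None, :]).reshape(e - s, -1)
            out[s:e] = np.einsum("pw,pw->p", sub, w)
        return out

    # -- forward / adjoint --------------------------------------------------

    def forward(self, image: np.ndarray, points: np.ndarray | None = None) -> np.ndarray:
        """Type-2 NUFFT: image -> samples at the nonuniform points."""
        plan = self._plan if points is None else self.point_weights(points)
        if plan is None:
            raise ConfigurationError("no points given and none planned")
        return self.interpolate(self.plan_grid(np.asarray(image, dtype=complex)), plan)

    def adjoint(self, samples: np.ndarray, points: np.ndarray | None = None,
                chunk: int = 1 << 17) -> np.ndarray:
        """Type-1 NUFFT: samples -> image (exact adjoint of `forward`)."""
        plan = self._plan if points is None else self.point_weights(points)
        if plan is None:
            raise ConfigurationError("no points given and none planned")
        ix, iy, wx, wy = plan
        m1, m2 = self.grid_shape
        samples = np.asarray(samples, dtype=complex).reshape(-1)
        acc = np.zeros(m1 * m2, dtype=complex)
        for s in range(0, samples.size, chunk):
            e = min(s + chunk, samples.size)
            idx = (ix[s:e, :, None] * m2 + iy[s:e, None, :]).reshape(-1)
            val = (
                samples[s:e, None, None] * wx[s:e, :, None] * wy[s:e, None, :]
            ).reshape(-1)
            acc += np.bincount(idx, weights=val.real, minlength=m1 * m2)
            acc += 1j * np.bincount(idx, weights=val.imag, minlength=m1 * m2)
        grid = acc.reshape(m1, m2)
        img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(grid))) * (m1 * m2)
        n1, n2 = self.shape
        img = img[
            m1 // 2 - n1 // 2 : m1 // 2 - n1 // 2 + n1,
            m2 // 2 - n2 // 2 : m2 // 2 - n2 // 2 + n2,
        ]
        return img / np.outer(self._apod[0], self._apod[1])


def nudft_forward(image: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Direct-summation nonuniform DFT (oracle; O(N^2 P), small inputs only)."""
    image = np.asarray(image, dtype=complex)
    n1, n2 = image.shape
    x = np.arange(n1) - n1 // 2
    y = np.arange(n2) - n2 // 2
    xx, yy = np.meshgrid(x, y, indexing="ij")
    phase = np.exp(
        -2j
        * np.pi
        * (
            points[:, 0, None] * xx.reshape(-1)[None, :]
            + points[:, 1, None] * yy.reshape(-1)[None, :]
        )
    )
    return phase @ image.reshape(-1)


def nudft_adjoint(samples: np.ndarray, points: np.ndarray, shape) -> np.ndarray:
    """Direct-summation adjoint nonuniform DFT (oracle)."""
    n1, n2 = shape
    x = np.arange(n1) - n1 // 2
    y = np.arange(n2) - n2 // 2
    xx, yy = np.meshgrid(x, y, indexing="ij")
    phase = np.exp(
        2j
        * np.pi
        * (
            points[:, 0, None] * xx.reshape(-1)[None, :]
            + points[:, 1, None] * yy.reshape(-1)[None, :]
        )
    )
    return (samples[None, :] @ phase).reshape(n1, n2)
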