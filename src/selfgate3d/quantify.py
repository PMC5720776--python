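"""Image-analysis endpoints: CNR, infarct-area ratio, and method agreement.

Contrast-to-noise ratio between the LV cavity and the myocardial wall uses
ROI-local statistics (the noise of an iterative reconstruction varies
spatially, so a background-ROI noise estimate would be misleading):

    CNR = (mean(S_cavity) - mean(S_wall)) / sqrt(sd_cavity^2 + sd_wall^2)

Infarct size is reported as the enhanced fraction of the myocardial wall,

    ratio = area_infarct / (area_infarct + area_healthy),

with the enhanced region segmented inside a wall mask by Otsu thresholding
(or a user-supplied threshold/mask, replacing manual outlining).  Agreement
between two measurement methods is summarized by ordinary least-squares
regression and Bland-Altman bias with 95 % limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats
from skimage.filters import threshold_otsu

from .errors import ConfigurationError


@dataclass
class ROIStats:
    """First/second moments of the cavity and wall ROIs."""

    mean_cavity: float
    sd_cavity: float
    mean_wall: float
    sd_wall: float


@dataclass
class InfarctMeasurement:
    """Enhanced vs healthy myocardium areas and their ratio."""

    area_infarct_vox: int
    area_healthy_vox: int
    ratio: float
    threshold: float
    area_infarct_mm2: float | None = None
    area_healthy_mm2: float | None = None


@dataclass
class AgreementResult:
    """OLS regression and Bland-Altman agreement between two methods."""

    slope: float
    intercept: float
    r_squared: float
    bias: float
    loa_low: float
    loa_high: float


def roi_stats(image: np.ndarray, cavity_mask: np.ndarray, wall_mask: np.ndarray) -> ROIStats:
    """Extract ROI statistics from an image slice or volume."""
    cavity_mask = np.asarray(cavity_mask, dtype=bool)
    wall_mask = np.asarray(wall_mask, dtype=bool)
    if not cavity_mask.any() or not wall_mask.any():
        raise ConfigurationError("ROIs must be non-empty")
    if (cavity_mask & wall_mask).any():
        raise ConfigurationError("cavity and wall ROIs must be disjoint")
    img = np.asarray(image, dtype=float)
    return ROIStats(
        mean_cavity=float(img[cavity_mask].mean()),
        sd_cavity=float(img[cavity_mask].std()),
        mean_wall=float(img[wall_mask].mean()),
        sd_wall=float(img[wall_mask].std()),
    )


def compute_cnr(stats: ROIStats) -> float:
    """(mean cavity - mean wall) / root-sum-square of the ROI SDs."""
    denom = np.hypot(stats.sd_cavity, stats.sd_wall)
    if denom == 0:
        raise ConfigurationError("CNR undefined: both ROI standard deviations are zero")
    return (stats.mean_cavity - stats.mean_wall) / denom


def cnr(image: np.ndarray, cavity_mask: np.ndarray, wall_mask: np.ndarray) -> float:
    """Convenience wrapper: ROI extraction + CNR."""
    return compute_cnr(roi_stats(image, cavity_mask, wall_mask))


def segment_infarct(
    image: np.ndarray,
    wall_mask: np.ndarray,
    threshold: float | None = None,
    infarct_mask: np.ndarray | None = None,
    voxel_area_mm2: float | None = None,
) -> InfarctMeasurement:
    """Split the myocardial wall into enhanced (infarct) and healthy tissue.

    Voxels of ``image`` inside ``wall_mask`` above the threshold are labeled
    infarct.  The threshold defaults to Otsu's value computed within the
    wall (scale-invariant); a fixed ``threshold`` or an explicit
    ``infarct_mask`` (e.g. a manually refined contour) overrides it.
    """
    wall_mask = np.asarray(wall_mask, dtype=bool)
    if not wall_mask.any():
        raise ConfigurationError("wall mask is empty")
    img = np.asarray(image, dtype=float)
    vals = img[wall_mask]
    if infarct_mask is not None:
        enhanced = np.asarray(infarct_mask, dtype=bool) & wall_mask
        thr = float("nan")
    else:
        if threshold is None:
            if np.ptp(vals) == 0:
                # featureless wall: nothing is enhanced
                thr = float(vals.max())
                enhanced = np.zeros_like(wall_mask)
            else:
                thr = float(threshold_otsu(vals))
                enhanced = wall_mask & (img > thr)
        else:
            thr = float(threshold)
            enhanced = wall_mask & (img > thr)
    n_inf = int(np.count_nonzero(enhanced))
    n_healthy = int(np.count_nonzero(wall_mask & ~enhanced))
    total = n_inf + n_healthy
    ratio = n_inf / total if total else 0.0
    return InfarctMeasurement(
        area_infarct_vox=n_inf,
        area_healthy_vox=n_healthy,
        ratio=float(ratio),
        threshold=thr,
        area_infarct_mm2=(n_inf * voxel_area_mm2 if voxel_area_mm2 else None),
        area_healthy_mm2=(n_healthy * voxel_area_mm2 if voxel_area_mm2 else None),
    )


def agreement(x: np.ndarray, y: np.ndarray) -> AgreementResult:
    """OLS of y on x plus Bland-Altman statistics of the differences y - x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ConfigurationError("agreement needs two equal-length 1D arrays, n >= 3")
    if np.var(x) == 0:
        raise ConfigurationError("regression undefined: x has zero variance")
    fit = _stats.linregress(x, y)
    diffs = y - x
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if x.size > 1 else 0.0
    return AgreementResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )


def plot_agreement(x: np.ndarray, y: np.ndarray, path: str,
                   labels: tuple[str, str] = ("method A", "method B")) -> AgreementResult:
    """Side-by-side regression and Bland-Altman panels (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = agreement(x, y)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(x, y, "o")
    xs = np.linspace(min(x), max(x), 50)
    ax1.plot(xs, res.slope * xs + res.intercept, "-",
             label=f"y={res.slope:.3f}x+{res.intercept:.3f}, $R^2$={res.r_squared:.3f}")
    ax1.set_xlabel(labels[0]); ax1.set_ylabel(labels[1]); ax1.legend(fontsize=8)
    mean_ = (np.asarray(x) + np.asarray(y)) / 2
    ax2.plot(mean_, np.asarray(y) - np.asarray(x), "o")
    for v, st in ((res.bias, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax2.axhline(v, ls=st, color="k", lw=0.8)
    ax2.set_xlabel("mean"); ax2.set_ylabel("difference")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return res
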