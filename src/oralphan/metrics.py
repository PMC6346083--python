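"""Image-fidelity metrics and artifact extent / volume measurement.

Six fidelity measures are reported for every test/reference pair: MSE,
RMSE, PSNR, MAE, Pearson cross-correlation (NCC), and the structural
similarity index (SSIM; mean-pooled 11-tap Gaussian window, sigma 1.5,
stabilizers c1=(0.01 L)^2, c2=(0.03 L)^2, and the standard
(mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2) denominator).  Artifact
size is measured from the thresholded |test - reference| difference image
(largest connected component, bounding extents per axis) or from an
automatically contoured mask, and volumes are reported in ml.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.metrics import structural_similarity

from .phantom import ConfigurationError
from .volume import ImageVolume

__all__ = [
    "QualityReport",
    "ArtifactMeasurement",
    "fidelity",
    "artifact_extent",
    "artifact_volume",
    "sweep_report",
    "percent_differences",
]


@dataclass(frozen=True)
class QualityReport:
    """The six fidelity metrics for one (test, reference) pair.

    ``psnr`` is ``math.inf`` for identical images; ``ncc`` is NaN when
    either image is constant (undefined correlation).
    """

    mse: float
    rmse: float
    psnr: float
    mae: float
    ncc: float
    ssim: float
    pair: tuple[str, str] = ("test", "reference")

    def as_dict(self) -> dict:
        return {
            "mse": self.mse, "rmse": self.rmse, "psnr": self.psnr,
            "mae": self.mae, "ncc": self.ncc, "ssim": self.ssim,
        }


@dataclass(frozen=True)
class ArtifactMeasurement:
    """Bounding extents (mm) and volume (ml) of one artifact region."""

    extent_x: float
    extent_y: float
    extent_z: float
    volume_ml: float
    method: str = "difference_region"

    def as_dict(self) -> dict:
        return {
            "extent_x_mm": self.extent_x, "extent_y_mm": self.extent_y,
            "extent_z_mm": self.extent_z, "volume_ml": self.volume_ml,
        }


def _data(vol) -> np.ndarray:
    return vol.data if isinstance(vol, ImageVolume) else np.asarray(vol)


def fidelity(test, ref, dynamic_range: float | None = None,
             pair: tuple[str, str] = ("test", "reference")) -> QualityReport:
    """Compute all six fidelity metrics on congruent grids.

    ``dynamic_range`` (the L in PSNR and the SSIM stabilizers) defaults to
    the reference image's max - min.
    """
    x = _data(test).astype(np.float64)
    y = _data(ref).astype(np.float64)
    if x.shape != y.shape:
        raise ConfigurationError(f"shape mismatch: {x.shape} vs {y.shape}")
    if dynamic_range is None:
        dynamic_range = float(np.ptp(y))
        if dynamic_range == 0:
            dynamic_range = 1.0
    if dynamic_range <= 0:
        raise ConfigurationError("dynamic_range must be positive")

    diff = x - y
    mse = float(np.mean(diff**2))
    rmse = math.sqrt(mse)
    psnr = math.inf if mse == 0 else 10.0 * math.log10(dynamic_range**2 / mse)
    mae = float(np.mean(np.abs(diff)))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        ncc = float("nan")
    else:
        ncc = float(np.corrcoef(x.ravel(), y.ravel())[0, 1])
    # the standard 11-tap Gaussian window, shrunk (odd) for images smaller
    # than 11 voxels along any axis
    win = min(11, min(x.shape))
    if win % 2 == 0:
        win -= 1
    ssim_kwargs = dict(
        data_range=dynamic_range,
        gaussian_weights=True,
        sigma=1.5,
        use_sample_covariance=False,
        K1=0.01,
        K2=0.03,
    )
    if win < 11:
        ssim_kwargs["win_size"] = max(win, 3)
    ssim = float(structural_similarity(x, y, **ssim_kwargs))
    return QualityReport(mse, rmse, psnr, mae, ncc, ssim, pair)


def artifact_extent(
    test, ref,
    k: float = 3.0,
    off_arch_fraction: float = 0.25,
    spacing=None,
    opening_iter: int = 1,
    smooth_sigma: float = 1.0,
) -> ArtifactMeasurement:
    """Artifact size from the |test - reference| difference image.

    The absolute difference is smoothed with a Gaussian of ``smooth_sigma``
    voxels (noise suppression; 0 disables), then thresholded at ``k`` times
    a robust noise scale estimated from the off-arch portion of the
    smoothed difference (the first and last ``off_arch_fraction`` of axial
    slices, far from the dental arch in the mid-plane).  A binary opening
    (``opening_iter`` iterations) strips residual single-voxel excursions,
    then the largest connected component is measured: its bounding extent
    along each grid axis in mm and its volume in ml.  If nothing exceeds
    threshold (e.g. test == ref) the measurement is all-zero.
    """
    x = _data(test)
    y = _data(ref)
    if x.shape != y.shape:
        raise ConfigurationError(f"shape mismatch: {x.shape} vs {y.shape}")
    if spacing is None:
        spacing = test.spacing if isinstance(test, ImageVolume) else (1.0, 1.0, 1.0)
    spacing = tuple(float(s) for s in np.broadcast_to(spacing, (3,)))

    diff = np.abs(x - y)
    # noise scale from the raw off-arch difference: the threshold stays at
    # k raw-noise sigmas while smoothing only stabilizes the footprint
    nz = diff.shape[2]
    m = max(int(round(off_arch_fraction * nz)), 1)
    off_arch = np.concatenate([diff[:, :, :m].ravel(), diff[:, :, nz - m:].ravel()])
    med = np.median(off_arch)
    sigma = 1.4826 * np.median(np.abs(off_arch - med))  # robust MAD scale
    thr = med + k * sigma
    if smooth_sigma:
        diff = ndimage.gaussian_filter(diff, smooth_sigma)
    mask = diff > thr
    if opening_iter and mask.any():
        mask = ndimage.binary_opening(mask, iterations=opening_iter)
    if not mask.any():
        return ArtifactMeasurement(0.0, 0.0, 0.0, 0.0)

    lab, n = ndimage.label(mask)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    largest = int(np.argmax(counts))
    comp = lab == largest
    idx = np.nonzero(comp)
    extents = [
        float((idx[a].max() - idx[a].min() + 1) * spacing[a]) for a in range(3)
    ]
    vol_ml = artifact_volume(comp, spacing)
    return ArtifactMeasurement(*extents, vol_ml)


def artifact_volume(mask: np.ndarray, spacing) -> float:
    """Volume of a binary mask in ml (1 ml = 1000 mm^3)."""
    spacing = np.broadcast_to(spacing, (3,))
    voxel_mm3 = float(np.prod(spacing))
    return float(np.count_nonzero(mask)) * voxel_mm3 / 1000.0


def sweep_report(images: dict, ref, dynamic_range: float | None = None,
                 extent_kwargs: dict | None = None) -> pd.DataFrame:
    """One row of fidelity + artifact measurements per sweep member.

    ``images`` maps the swept parameter value (SE bandwidth in Hz/px or GRE
    echo time in ms) to the member volume; ``ref`` is the implant-free
    reference of the same sequence.  The result is CSV-serializable.
    """
    extent_kwargs = extent_kwargs or {}
    rows = []
    for value, img in images.items():
        q = fidelity(img, ref, dynamic_range=dynamic_range,
                     pair=(str(value), "reference"))
        a = artifact_extent(img, ref, **extent_kwargs)
        rows.append({"sweep_value": value, **q.as_dict(), **a.as_dict()})
    return pd.DataFrame(rows)


def percent_differences(a: float, b: float) -> dict:
    """Percent difference between two metric values under both denominator
    conventions (relative to ``a``, relative to ``b``)."""
    out = {}
    out["vs_first"] = math.nan if a == 0 else 100.0 * (b - a) / abs(a)
    out["vs_second"] = math.nan if b == 0 else 100.0 * (a - b) / abs(b)
    return out
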