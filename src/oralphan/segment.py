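"""Segmentation: CT thresholding, fuzzy c-means, MR metal-region extraction,
and gradient-driven automatic contouring.

The CT route mirrors the study procedure: an oral-region intensity window
(1200-3500 HU) selects teeth and restorations as foreground, and fuzzy
c-means clustering of the ROI intensities refines the hard threshold.  The
MR route extracts the susceptibility-artifact footprint (signal void plus
adjacent pile-up).  The automatic contour is a morphological geodesic
active contour used for artifact volume measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology, segmentation

from .phantom import ConfigurationError
from .volume import ImageVolume

__all__ = [
    "FcmParams",
    "FcmResult",
    "FcmDegenerateError",
    "threshold_segment",
    "fcm",
    "fcm_with_threshold",
    "mr_metal_region",
    "artifact_mask_vs_reference",
    "oral_roi",
    "solution_signal_level",
    "auto_contour",
    "dice",
]

ORAL_WINDOW_HU = (1200.0, 3500.0)


@dataclass(frozen=True)
class FcmParams:
    """Fuzzy c-means parameters.

    ``fuzzifier`` is the exponent F applied to memberships in the weighted
    within-group sum-of-squares objective; F -> 1 approaches hard k-means,
    F = 2 is the canonical choice.  Iteration stops when the largest
    absolute membership change falls below ``epsilon``.
    """

    n_clusters: int = 3
    fuzzifier: float = 2.0
    epsilon: float = 1e-5
    max_iter: int = 200
    seed: int = 0
    n_init: int = 4

    def __post_init__(self):
        if self.n_clusters < 1:
            raise ConfigurationError("n_clusters must be >= 1")
        if not self.fuzzifier > 1:
            raise ConfigurationError("fuzzifier must be > 1")
        if not 0 < self.epsilon < 1:
            raise ConfigurationError("epsilon must lie in (0, 1)")
        if self.n_init < 1:
            raise ConfigurationError("n_init must be >= 1")


@dataclass
class FcmResult:
    """Memberships (n x c, rows sum to 1), cluster centers, objective trace."""

    memberships: np.ndarray
    centers: np.ndarray
    objective_trace: np.ndarray
    n_iter: int
    converged: bool

    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.memberships, axis=1)


class FcmDegenerateError(RuntimeError):
    """Cluster centers collapsed and re-jittering did not separate them."""


def fcm_objective(values: np.ndarray, memberships: np.ndarray,
                  centers: np.ndarray, fuzzifier: float) -> float:
    """Weighted within-group sum of squared errors
    ``J = sum_a sum_b u_ab^F (x_a - c_b)^2``."""
    d2 = (values[:, None] - centers[None, :]) ** 2
    return float(np.sum(memberships**fuzzifier * d2))


def _init_centers(values: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding on 1-D intensities.

    Seeding operates on the sorted values so the initialization — and with
    it the whole run — is invariant to the input order.
    """
    values = np.sort(values)
    centers = [values[rng.integers(len(values))]]
    for _ in range(1, c):
        d2 = np.min((values[:, None] - np.asarray(centers)[None, :]) ** 2, axis=1)
        total = d2.sum()
        if total <= 0:
            # all remaining points coincide with a center; spread over range
            centers.append(values.min() + (values.max() - values.min())
                           * len(centers) / max(c - 1, 1))
            continue
        centers.append(values[rng.choice(len(values), p=d2 / total)])
    return np.asarray(centers, dtype=np.float64)


def _memberships(values: np.ndarray, centers: np.ndarray,
                 fuzzifier: float) -> np.ndarray:
    d = np.abs(values[:, None] - centers[None, :])
    u = np.empty((len(values), len(centers)))
    power = 2.0 / (fuzzifier - 1.0)
    exact = d == 0.0
    rows_exact = exact.any(axis=1)
    safe = ~rows_exact
    if safe.any():
        # scale each row by its nearest center distance so the ratio powers
        # stay in (0, 1] and cannot overflow however extreme the spread
        dmin = d[safe].min(axis=1, keepdims=True)
        inv = (d[safe] / dmin) ** (-power)
        u[safe] = inv / inv.sum(axis=1, keepdims=True)
    if rows_exact.any():
        u[rows_exact] = exact[rows_exact] / exact[rows_exact].sum(
            axis=1, keepdims=True
        )
    return u


def fcm(values, params: FcmParams | None = None) -> FcmResult:
    """Fuzzy c-means on a 1-D intensity vector by alternating optimization.

    Memberships ``u_ab = 1 / sum_k (|x_a - c_b| / |x_a - c_k|)^(2/(F-1))``
    and centers ``c_b = sum_a u_ab^F x_a / sum_a u_ab^F`` are alternated
    until ``max_ab |u_ab^(q+1) - u_ab^(q)| < epsilon`` or ``max_iter``.
    Each alternation minimizes the objective exactly in one block, so the
    returned objective trace is non-increasing.

    The alternation is restarted from ``n_init`` seeded initializations
    and the solution with the lowest final objective is returned — the
    fuzzy objective has poor local minima on strongly imbalanced 1-D data
    and the restarts make the outcome seed-robust.  ``n_clusters=1``
    short-circuits to the closed form (center = mean).  A degenerate
    restart (coincident centers) is re-jittered once; if every restart
    collapses an :class:`FcmDegenerateError` is raised.
    """
    params = params or FcmParams()
    values = np.asarray(values, dtype=np.float64).ravel()
    c = params.n_clusters
    if len(values) < c:
        raise ConfigurationError("need at least n_clusters data points")
    if c == 1:
        center = values.mean()
        j = float(np.sum((values - center) ** 2))
        return FcmResult(np.ones((len(values), 1)), np.array([center]),
                         np.array([j]), 0, True)
    if np.ptp(values) == 0:
        raise FcmDegenerateError("all input values identical")
    rng = np.random.default_rng(params.seed)
    span = np.ptp(values)

    best: FcmResult | None = None
    for _ in range(params.n_init):
        result = _fcm_single(values, c, params, rng, span, rejitter=True)
        if result is None:
            continue
        if best is None or result.objective_trace[-1] < best.objective_trace[-1]:
            best = result
    if best is None:
        raise FcmDegenerateError(
            f"cluster centers collapsed in every restart (c={c}, "
            f"n={len(values)}); the data may not support this many clusters"
        )
    return best


def _fcm_single(values, c, params, rng, span, rejitter):
    """One alternating-optimization run; None if centers collapse."""
    for attempt in range(2 if rejitter else 1):
        centers = _init_centers(values, c, rng)
        if attempt:  # re-jitter path after a degenerate first attempt
            centers = centers + rng.normal(0.0, 0.05 * span, size=c)
        u = _memberships(values, centers, params.fuzzifier)
        trace = []
        converged = False
        it = 0
        degenerate = False
        for it in range(1, params.max_iter + 1):
            w = u**params.fuzzifier
            centers = (w * values[:, None]).sum(axis=0) / w.sum(axis=0)
            if _coincident(centers, span):
                degenerate = True
                break
            u_new = _memberships(values, centers, params.fuzzifier)
            trace.append(fcm_objective(values, u_new, centers, params.fuzzifier))
            delta = float(np.max(np.abs(u_new - u)))
            u = u_new
            if delta < params.epsilon:
                converged = True
                break
        if not degenerate:
            return FcmResult(u, centers, np.asarray(trace), it, converged)
    return None


def _coincident(centers: np.ndarray, span: float) -> bool:
    cs = np.sort(centers)
    return bool(np.any(np.diff(cs) < 1e-9 * max(span, 1.0)))


def threshold_segment(ct: ImageVolume, lo: float = ORAL_WINDOW_HU[0],
                      hi: float = ORAL_WINDOW_HU[1]) -> np.ndarray:
    """Binary mask of voxels with ``lo <= HU <= hi`` (the oral window by
    default); everything outside the range is background."""
    if lo > hi:
        raise ConfigurationError(f"lo ({lo}) must not exceed hi ({hi})")
    if ct.modality != "CT":
        raise ConfigurationError("threshold_segment expects a CT volume")
    return (ct.data >= lo) & (ct.data <= hi)


def fcm_with_threshold(ct: ImageVolume, roi: np.ndarray,
                       params: FcmParams | None = None) -> np.ndarray:
    """FCM refinement of an oral region of interest (the ROI -> FCM ->
    threshold procedure): cluster the ROI intensities, keep the
    maximum-membership voxels of the cluster with the highest center (the
    teeth/restoration class), then close and fill holes.

    The ROI should be a compact region of the slice or volume around the
    dental arch that still contains background — e.g. :func:`oral_roi` of
    a window threshold — so that the background/teeth membership boundary
    falls below the hard window edge and noise-flipped boundary voxels are
    recovered rather than eroded.
    """
    params = params or FcmParams()
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ConfigurationError("roi must be nonempty")
    result = fcm(ct.data[roi], params)
    keep = result.hard_labels() == int(np.argmax(result.centers))
    mask = np.zeros(ct.data.shape, dtype=bool)
    mask[roi] = keep
    footprint = morphology.ball(1) if mask.ndim == 3 else morphology.disk(1)
    mask = morphology.closing(mask, footprint)
    mask = ndimage.binary_fill_holes(mask)
    return mask


def oral_roi(mask: np.ndarray, pad: int = 3) -> np.ndarray:
    """Compact region of interest around a foreground mask: its bounding
    box padded by ``pad`` voxels.  This is the "select the interest
    region" step that precedes FCM — the box deliberately includes local
    background so the clustering sees both classes."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ConfigurationError("mask must be nonempty")
    idx = np.nonzero(mask)
    roi = np.zeros(mask.shape, dtype=bool)
    sl = tuple(
        slice(max(int(i.min()) - pad, 0), int(i.max()) + pad + 1) for i in idx
    )
    roi[sl] = True
    return roi


def _solution_stats(data: np.ndarray, smoothed: np.ndarray, q_low: float,
                    off_arch_fraction: float = 0.25):
    """Robust location/scale of the bright (solution) compartment.

    The compartment is delineated on the smoothed image (half the 99.5th
    percentile), which keeps Rician-noise excursions in air out of the
    bright bulk even at high receiver bandwidth.  The noise scale comes
    from the (q_low, median) quantile spread of the *raw* intensities
    restricted to the off-arch axial slices (first and last quarters of
    the stack, far from the dental arch), so the artifact shadow around
    the arch cannot inflate it; on an artifact-free image essentially no
    solution voxel ends up flagged.
    """
    p99 = np.percentile(smoothed, 99.5)
    if p99 <= 0:
        return None
    bulk = smoothed > 0.5 * p99
    if bulk.sum() < 100:
        return None
    nz = data.shape[-1]
    m = max(int(round(off_arch_fraction * nz)), 1)
    far = np.zeros(data.shape, dtype=bool)
    far[..., :m] = True
    far[..., nz - m:] = True
    sample = bulk & far
    if sample.sum() < 100:
        sample = bulk
    vals = data[sample]
    med = float(np.median(vals))
    q10 = float(np.percentile(vals, 100 * q_low))
    sigma = max((med - q10) / 1.2816, 1e-12)  # normal-quantile scale estimate
    return bulk, med, sigma


def mr_metal_region(
    mr: ImageVolume,
    q_low: float = 0.10,
    q_high: float = 0.99,
    adjacency: int = 2,
    min_size: int = 5,
    k: float = 3.0,
) -> np.ndarray:
    """Footprint of the metal susceptibility artifact on an MR image.

    Union of the signal void (intensity below ``median - k*sigma`` of the
    solution compartment, inside the phantom) and pile-up (above
    ``median + k*sigma``) components within ``adjacency`` voxels of the
    void, morphologically closed; components smaller than ``min_size``
    voxels are dropped.  Returns an empty mask on artifact-free images.
    """
    if mr.modality != "MR":
        raise ConfigurationError("mr_metal_region expects an MR volume")
    data = mr.data
    smoothed = ndimage.gaussian_filter(data, 1.5)
    stats = _solution_stats(data, smoothed, q_low)
    empty = np.zeros(data.shape, dtype=bool)
    if stats is None:
        return empty
    bulk, med, sigma = stats

    interior = ndimage.binary_fill_holes(
        morphology.closing(bulk, morphology.ball(2))
    )
    interior = ndimage.binary_erosion(interior, iterations=2)

    # voids and pile-up are detected on the raw image (the smoothed image
    # only delineates the compartment: its blur would bleed dark teeth
    # outward and over-extend the mask into healthy solution)
    void = (data < med - k * sigma) & interior
    pile = (data > med + k * sigma) & ndimage.binary_dilation(
        void, iterations=adjacency
    )
    mask = morphology.closing(void | pile, morphology.ball(1))
    mask = _drop_small(mask, min_size)
    return mask


def artifact_mask_vs_reference(test: ImageVolume, ref: ImageVolume | None,
                               margin: int = 1, grow: int = 2,
                               **kwargs) -> np.ndarray:
    """Metal-artifact footprint of ``test``, excluding structures that are
    equally signal-free in an implant-free reference scan of the same
    sequence (normal teeth, Teflon rods, retainer) — the reference image
    plays the same role the normal dental scans play in the study
    protocol.  The footprint is grown by ``grow`` voxels so that the
    fusion repair blends inside the partially-shadowed rim of the artifact
    rather than seaming against it; ``margin`` dilates the reference
    footprint before subtraction."""
    mask = mr_metal_region(test, **kwargs)
    if grow and mask.any():
        mask = ndimage.binary_dilation(mask, iterations=grow)
    if ref is not None:
        static = mr_metal_region(ref, **kwargs)
        if margin:
            static = ndimage.binary_dilation(static, iterations=margin)
        mask &= ~static
    return mask


def solution_signal_level(data: np.ndarray) -> float | None:
    """Robust median of the solution compartment (None if no bright bulk),
    shared by the metal-region extractor and the fusion inpainting."""
    smoothed = ndimage.gaussian_filter(np.asarray(data, np.float64), 1.5)
    stats = _solution_stats(np.asarray(data, np.float64), smoothed, 0.10)
    return None if stats is None else stats[1]


def _drop_small(mask: np.ndarray, min_size: int) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n == 0:
        return mask
    counts = np.bincount(lab.ravel())
    keep = np.flatnonzero(counts >= min_size)
    keep = keep[keep != 0]
    return np.isin(lab, keep)


def auto_contour(
    img: ImageVolume | np.ndarray,
    seed_mask: np.ndarray,
    num_iter: int = 120,
    smoothing: int = 0,
    balloon: float = -1.0,
    sigma: float = 1.0,
    alpha: float = 100.0,
) -> np.ndarray:
    """Gradient-driven contour evolution from an initial mask.

    A morphological geodesic active contour shrinks (``balloon=-1``) from
    the seed until it locks onto the intensity-gradient edge of the lesion;
    used for artifact-volume measurement.  On a gradient-free (constant)
    image the seed is returned unchanged.  If the contour is still moving
    at ``num_iter`` a RuntimeWarning is issued and the last contour is
    returned.
    """
    data = img.data if isinstance(img, ImageVolume) else np.asarray(img)
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if not seed_mask.any():
        raise ConfigurationError("seed_mask must be nonempty")
    if np.ptp(data) == 0:
        return seed_mask.copy()

    gimage = segmentation.inverse_gaussian_gradient(
        data.astype(np.float64), alpha=alpha, sigma=sigma
    )
    history: list[np.ndarray] = []

    def _track(ls):
        history.append(np.asarray(ls, dtype=bool).copy())
        if len(history) > 2:
            del history[0]

    out = segmentation.morphological_geodesic_active_contour(
        gimage,
        num_iter=num_iter,
        init_level_set=seed_mask.astype(np.int8),
        smoothing=smoothing,
        balloon=balloon,
        iter_callback=_track,
    ).astype(bool)
    if len(history) == 2 and not np.array_equal(history[0], history[1]):
        warnings.warn(
            "auto_contour did not stabilize within num_iter; returning the "
            "last contour",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks (1.0 when both empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)
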