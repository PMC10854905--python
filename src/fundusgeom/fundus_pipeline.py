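"""Fundus image pipeline: preprocessing, vessel segmentation, A/V
classification, and optic-disc detection.

The deep-learning segmentation and disc-localization models used in
clinical analyzers are represented by a pluggable backend registry; the
shipped baseline is classical: multiscale ridge (vesselness) filtering
with hysteresis thresholding for vessels, and a brightest-compact-blob
search plus polar-coordinate Canny edge extraction for the optic disc.
The disc diameter DD is defined as the diameter of the smallest circle
circumscribing the detected boundary.

Conventions: pixel centers, origin top-left, x rightward, y downward,
0-based; positions are (x, y).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure, feature, filters, morphology, transform

from fundusgeom import geometry

__all__ = [
    "PreprocessedImage",
    "AVMask",
    "OpticDisc",
    "DiscNotFoundError",
    "preprocess",
    "segment_vessels",
    "register_backend",
    "classify_arteries_veins",
    "locate_and_segment_disc",
    "smallest_enclosing_circle",
]


class DiscNotFoundError(RuntimeError):
    """No acceptable optic-disc candidate in the image."""


@dataclass
class PreprocessedImage:
    """Normalized, enhanced fundus image restricted to the camera field.

    ``image`` is the contrast-enhanced working image in [0, 1]; ``norm``
    is the intensity-normalized image *before* local enhancement (A/V
    discrimination uses it, since adaptive equalization flattens exactly
    the global brightness cue that separates arteries from veins).
    """

    image: np.ndarray
    norm: np.ndarray
    roi_mask: np.ndarray
    roi_center: tuple[float, float]  # (x, y)
    roi_radius: float
    roi_contrast: float = 1.0  # raw p99-p1 dynamic range inside the ROI
    provenance: list[str] = field(default_factory=list)


@dataclass
class AVMask:
    """Per-pixel artery/vein labels: 0 background, 1 artery, 2 vein."""

    labels: np.ndarray
    confidence: np.ndarray | None = None

    ARTERY = 1
    VEIN = 2


@dataclass
class OpticDisc:
    """Detected optic disc: boundary contour and smallest enclosing circle.

    ``dd`` is the diameter of the smallest circle containing all boundary
    points and ``center`` that circle's center — the reference frame for
    zone definitions and relative calibers.
    """

    center: tuple[float, float]  # (x, y)
    dd: float
    boundary: np.ndarray  # (n, 2) closed contour, (x, y), counter-clockwise


def _to_gray(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3:
        # green channel carries the best vessel contrast on fundus photographs
        arr = arr[..., 1]
    if arr.max() > 1.0:
        arr = arr / 255.0
    return arr


def preprocess(image: np.ndarray) -> PreprocessedImage:
    """ROI extraction, denoising, normalization and local enhancement.

    The region of interest is the camera's circular field — the largest
    bright connected region; its radius is estimated from its area.
    Intensities inside the ROI are percentile-rescaled to [0, 1] and CLAHE
    is applied for edge sharpness.  Degenerate (constant) images pass
    through with the full frame as ROI.
    """
    arr = _to_gray(image)
    if min(arr.shape[:2]) < 64:
        raise ValueError(f"image too small: {arr.shape}, need >= 64 px per side")
    provenance = []

    den = ndimage.median_filter(arr, size=3)
    den = ndimage.gaussian_filter(den, sigma=0.5)
    provenance.append("denoise:median3+gauss0.5")

    if den.max() - den.min() < 1e-9:
        roi = np.ones_like(den, dtype=bool)
        cy, cx = (den.shape[0] - 1) / 2.0, (den.shape[1] - 1) / 2.0
        radius = math.hypot(cx, cy)
        provenance.append("roi:degenerate-full-frame")
        return PreprocessedImage(den, den, roi, (cx, cy), radius, 0.0, provenance)

    thr = filters.threshold_otsu(den)
    cand = den > min(thr, 0.5 * den.max())
    lbl, n = ndimage.label(cand)
    if n == 0:
        roi = np.ones_like(den, dtype=bool)
    else:
        sizes = ndimage.sum_labels(np.ones_like(den), lbl, index=range(1, n + 1))
        roi = lbl == (1 + int(np.argmax(sizes)))
        roi = ndimage.binary_fill_holes(roi)
    area = float(roi.sum())
    radius = math.sqrt(area / math.pi)
    cy, cx = ndimage.center_of_mass(roi)
    provenance.append("roi:otsu-largest-component")

    inside = den[roi]
    p1, p99 = np.percentile(inside, [1, 99])
    norm = np.clip((den - p1) / max(p99 - p1, 1e-9), 0.0, 1.0)
    norm[~roi] = 0.0
    provenance.append("normalize:p1-p99")

    enhanced = exposure.equalize_adapthist(norm, clip_limit=0.01)
    out = np.where(roi, enhanced, 0.0)
    provenance.append("enhance:clahe0.01-inside-roi")
    return PreprocessedImage(out, norm, roi, (float(cx), float(cy)), radius,
                             float(p99 - p1), provenance)


# --------------------------------------------------------------------------
# vessel segmentation backends
# --------------------------------------------------------------------------

_BACKENDS: dict[str, callable] = {}


def register_backend(name: str):
    """Decorator registering a segmentation backend.

    A backend is ``f(pre: PreprocessedImage, **kwargs) -> bool ndarray``;
    learned models plug in here without the pipeline caring.
    """

    def deco(fn):
        _BACKENDS[name] = fn
        return fn

    return deco


@register_backend("truth")
def _truth_backend(pre: PreprocessedImage, truth_mask: np.ndarray | None = None, **_):
    """Pass-through backend for testing against known ground truth."""
    if truth_mask is None:
        raise ValueError("truth backend requires truth_mask=")
    return np.asarray(truth_mask).astype(bool)


@register_backend("ridge")
def _ridge_backend(
    pre: PreprocessedImage,
    sigmas=(1.0, 2.0, 3.0),
    thresholds: tuple[float, float] = (0.2, 0.4),
    min_size: int = 40,
    roi_erode: int = 8,
    min_roi_contrast: float = 0.1,
    **_,
):
    """Classical baseline: multiscale Sato vesselness + hysteresis.

    Vesselness is computed on the enhanced image with dark ridges (vessels
    are darker than the fundus background), normalized to its maximum
    inside the ROI, hysteresis-thresholded at ``thresholds`` (low, high),
    confined to an eroded ROI (the field border itself is a strong ridge)
    and cleaned of small specks.  Lowering the thresholds can only grow
    the mask (hysteresis is monotone in both cuts).
    """
    roi = ndimage.binary_erosion(pre.roi_mask, iterations=roi_erode)
    # a vessel-free field has only sensor noise, which percentile
    # normalization would stretch into ridge-like structure; refuse to
    # segment when the raw ROI dynamic range is at noise level
    if pre.roi_contrast < min_roi_contrast:
        return np.zeros_like(roi)
    v = filters.sato(pre.image, sigmas=sigmas, black_ridges=True, mode="constant")
    vmax = v[roi].max() if roi.any() else v.max()
    if vmax <= 0:
        return np.zeros_like(roi)
    v = v / vmax
    low, high = thresholds
    mask = filters.apply_hysteresis_threshold(v, low, high)
    mask &= roi
    mask = morphology.remove_small_objects(mask, max_size=min_size - 1)
    return mask


def segment_vessels(pre: PreprocessedImage, backend: str = "ridge", **kwargs) -> np.ndarray:
    """Segment retinal vessels with a named backend; returns a bool mask."""
    if backend not in _BACKENDS:
        raise ValueError(
            f"unknown backend {backend!r}; registered: {sorted(_BACKENDS)}"
        )
    mask = _BACKENDS[backend](pre, **kwargs)
    return np.asarray(mask).astype(bool)


# --------------------------------------------------------------------------
# artery / vein discrimination
# --------------------------------------------------------------------------


def classify_arteries_veins(
    pre: PreprocessedImage | np.ndarray,
    vessel_mask: np.ndarray,
    clg: geometry.CenterlineGraph | None = None,
    veins_darker: bool = True,
) -> AVMask:
    """Label vessel pixels artery/vein from brightness and tree topology.

    Each centerline edge gets a median intensity; each connected tree is
    then classified as a whole (majority of its chain pixels), so labels
    are consistent along connected vasculature.  Tree intensities are
    split by two-means into a darker (vein, by default) and a brighter
    (artery) class; ``veins_darker=False`` inverts the prior.  Vessel
    pixels inherit the label of the nearest centerline pixel.  An empty
    mask yields an all-background AVMask.
    """
    intensity = pre.norm if isinstance(pre, PreprocessedImage) else _to_gray(pre)
    mask = np.asarray(vessel_mask).astype(bool)
    labels = np.zeros(mask.shape, dtype=np.uint8)
    if not mask.any():
        return AVMask(labels=labels)
    if clg is None:
        clg = geometry.extract_centerline(mask)
    trees = clg.trees()
    if not trees:
        return AVMask(labels=labels)

    tree_of_node = {}
    for tid, nodes in enumerate(trees):
        for n in nodes:
            tree_of_node[n] = tid
    tree_vals: dict[int, list[float]] = {tid: [] for tid in range(len(trees))}
    chain_px: list[tuple[int, int, int]] = []  # (row, col, tree)
    for u, _v, _k, d in clg.edges():
        tid = tree_of_node[u]
        rr, cc = np.round(d["chain"]).astype(int).T
        rr = np.clip(rr, 0, mask.shape[0] - 1)
        cc = np.clip(cc, 0, mask.shape[1] - 1)
        tree_vals[tid].extend(intensity[rr, cc].tolist())
        chain_px.extend((int(r), int(c), tid) for r, c in zip(rr, cc))

    med = np.array([np.median(tree_vals[t]) if tree_vals[t] else np.nan
                    for t in range(len(trees))])
    med = np.nan_to_num(med, nan=float(np.nanmean(med)) if np.isfinite(med).any() else 0.5)

    # deterministic 1-D two-means split of tree intensities
    if len(med) == 1 or np.ptp(med) < 1e-6:
        tree_label = np.full(len(med), AVMask.ARTERY, dtype=np.uint8)
    else:
        c_lo, c_hi = med.min(), med.max()
        for _ in range(50):
            assign = np.abs(med - c_lo) <= np.abs(med - c_hi)
            new_lo = med[assign].mean()
            new_hi = med[~assign].mean() if (~assign).any() else c_hi
            if abs(new_lo - c_lo) < 1e-12 and abs(new_hi - c_hi) < 1e-12:
                break
            c_lo, c_hi = new_lo, new_hi
        dark_is_vein = veins_darker
        tree_label = np.where(assign, AVMask.VEIN if dark_is_vein else AVMask.ARTERY,
                              AVMask.ARTERY if dark_is_vein else AVMask.VEIN).astype(np.uint8)

    # propagate tree labels to all vessel pixels via nearest centerline pixel
    from scipy.spatial import cKDTree

    pts = np.array([(r, c) for r, c, _t in chain_px], dtype=float)
    tl = np.array([tree_label[t] for _r, _c, t in chain_px], dtype=np.uint8)
    tree_kd = cKDTree(pts)
    vr, vc = np.nonzero(mask)
    _, nearest = tree_kd.query(np.stack([vr, vc], axis=1).astype(float))
    labels[vr, vc] = tl[nearest]
    return AVMask(labels=labels)


# --------------------------------------------------------------------------
# optic disc
# --------------------------------------------------------------------------


def _locate_disc_blob(pre: PreprocessedImage, smooth_sigma: float = 8.0):
    """Brightest compact blob inside the ROI: rough center + radius."""
    roi = ndimage.binary_erosion(pre.roi_mask, iterations=10)
    sm = ndimage.gaussian_filter(pre.norm, smooth_sigma)
    sm_roi = np.where(roi, sm, -np.inf)
    peak = np.unravel_index(int(np.argmax(sm_roi)), sm.shape)
    if not np.isfinite(sm_roi[peak]):
        raise DiscNotFoundError("no candidate blob inside the region of interest")
    thr = 0.5 * (sm[peak] + np.median(sm[roi]))
    blob = sm >= thr
    lbl, _ = ndimage.label(blob)
    blob = lbl == lbl[peak]
    cy, cx = ndimage.center_of_mass(blob)
    r_est = math.sqrt(blob.sum() / math.pi)
    return (float(cx), float(cy)), r_est, blob


def locate_and_segment_disc(
    pre: PreprocessedImage,
    radial_window: tuple[float, float] = (0.5, 1.7),
    edge_sigma: float = 2.0,
    border_margin: float = 4.0,
) -> OpticDisc:
    """Detect the optic disc boundary and its smallest enclosing circle.

    Localization finds the brightest compact blob; the neighborhood is
    then resampled in polar coordinates about the blob center (1 degree
    angular, 0.5 px radial resolution) and a Canny edge map of the polar
    image provides, for each angle, the outermost strong bright-to-dark
    radial edge within ``radial_window`` times the estimated blob radius.
    Unwrapping the per-angle radii gives a closed counter-clockwise
    contour; DD and center come from its smallest enclosing circle.

    Raises :class:`DiscNotFoundError` when no blob is found or the
    candidate touches the image/ROI border (a truncated disc would yield
    a silently biased DD).
    """
    (cx, cy), r_est, _blob = _locate_disc_blob(pre)
    h, w = pre.norm.shape
    r_max = radial_window[1] * r_est
    if (cx - r_max < border_margin or cy - r_max < border_margin
            or cx + r_max > w - border_margin or cy + r_max > h - border_margin):
        raise DiscNotFoundError(
            f"disc candidate at ({cx:.0f}, {cy:.0f}) with radius ~{r_est:.0f} px "
            "touches the image border; refusing a truncated measurement"
        )
    n_angles = 360
    radial_step = 0.5
    n_r = int(r_max / radial_step)
    polar = transform.warp_polar(
        pre.norm, center=(cy, cx), radius=r_max, output_shape=(n_angles, n_r),
        order=1, mode="edge",
    )
    edges = feature.canny(polar, sigma=edge_sigma)
    grad_r = np.gradient(ndimage.gaussian_filter(polar, edge_sigma), axis=1)
    falling = edges & (grad_r < 0)
    lo_idx = int(radial_window[0] * r_est / radial_step)
    falling[:, :max(lo_idx, 1)] = False

    # pass 1: strongest falling edge per ray -> robust rim radius estimate.
    # (rays that run along a vessel see extra falling edges far beyond the
    # rim, so "outermost" alone would overshoot on those angles)
    strongest = np.full(n_angles, np.nan)
    for a in range(n_angles):
        idx = np.nonzero(falling[a])[0]
        if len(idx):
            strongest[a] = idx[np.argmin(grad_r[a, idx])] * radial_step
    good = np.isfinite(strongest)
    if good.sum() < n_angles * 0.5:
        raise DiscNotFoundError("disc boundary too weak: edge found on "
                                f"{int(good.sum())}/{n_angles} rays")
    r_med = float(np.median(strongest[good]))

    # pass 2: outermost falling edge within a tight window around the rim
    radii = np.full(n_angles, np.nan)
    lo_r, hi_r = 0.75 * r_med, 1.3 * r_med
    for a in range(n_angles):
        idx = np.nonzero(falling[a])[0]
        idx = idx[(idx * radial_step >= lo_r) & (idx * radial_step <= hi_r)]
        if len(idx):
            radii[a] = idx[-1] * radial_step
    good = np.isfinite(radii)
    if not good.all():
        ang_idx = np.arange(n_angles)
        radii[~good] = np.interp(ang_idx[~good], ang_idx[good], radii[good],
                                 period=n_angles)
    # circular median filter knocks out isolated spikes (vessel entries)
    # before the max-sensitive smallest-enclosing-circle step
    radii = ndimage.median_filter(radii, size=7, mode="wrap")
    theta = np.deg2rad(np.arange(n_angles))
    # warp_polar angle 0 along +row? it unwraps counter-clockwise starting
    # from the +x axis in (row, col) convention; with y down this traces a
    # closed contour either way, and the enclosing circle is orientation-free
    xs = cx + radii * np.cos(theta)
    ys = cy + radii * np.sin(theta)
    boundary = np.stack([xs, ys], axis=1)
    center, radius = smallest_enclosing_circle(boundary)
    return OpticDisc(center=center, dd=2.0 * radius, boundary=boundary)


# --------------------------------------------------------------------------
# smallest enclosing circle (Welzl)
# --------------------------------------------------------------------------


def _circle_two(p, q):
    cx = (p[0] + q[0]) / 2.0
    cy = (p[1] + q[1]) / 2.0
    r = math.hypot(p[0] - q[0], p[1] - q[1]) / 2.0
    return (cx, cy, r)


def _circum_three(a, b, c):
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-14:
        return None
    ux = ((ax * ax + ay * ay) * (by - cy) + (bx * bx + by * by) * (cy - ay)
          + (cx * cx + cy * cy) * (ay - by)) / d
    uy = ((ax * ax + ay * ay) * (cx - bx) + (bx * bx + by * by) * (ax - cx)
          + (cx * cx + cy * cy) * (bx - ax)) / d
    return (ux, uy, math.hypot(ax - ux, ay - uy))


def _in_circle(c, p, eps=1e-10):
    return math.hypot(p[0] - c[0], p[1] - c[1]) <= c[2] * (1 + eps) + eps


def smallest_enclosing_circle(points) -> tuple[tuple[float, float], float]:
    """Smallest circle containing all points (Welzl, move-to-front).

    Deterministic: points are processed in a fixed seeded shuffle, so the
    same input always yields the same circle.  Expected O(n).  Raises on
    an empty point set.
    """
    pts = [tuple(map(float, p)) for p in np.asarray(points, dtype=float).reshape(-1, 2)]
    if not pts:
        raise ValueError("smallest_enclosing_circle needs at least one point")
    rng = np.random.default_rng(0)
    order = rng.permutation(len(pts))
    pts = [pts[i] for i in order]

    c = (pts[0][0], pts[0][1], 0.0)
    for i, p in enumerate(pts[1:], start=1):
        if _in_circle(c, p):
            continue
        # p is on the boundary of the minimal circle of pts[:i+1]
        c = (p[0], p[1], 0.0)
        for j, q in enumerate(pts[:i]):
            if _in_circle(c, q):
                continue
            c = _circle_two(p, q)
            for k, s in enumerate(pts[:j]):
                if _in_circle(c, s):
                    continue
                cc = _circum_three(p, q, s)
                if cc is not None:
                    c = cc
    return (c[0], c[1]), c[2]
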