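"""Synthetic fundus images and case-control cohorts with exact ground truth.

Two generators live here:

* a vascular-tree renderer that draws artery/vein trees radiating from a
  bright optic disc, recording every centerline, width, A/V label and
  bifurcation angle, so that segmentation, skeletonization, caliber and
  angle measurement can all be scored against known truth;
* a cohort simulator that draws per-eye clinical/MRI records (IOP, OA and
  ICA-C6 diameters, ONSASW at 3/9/15 mm, relative calibers, AVR, eight
  quadrant branching-angle means) from published group means and SDs for
  BRVO/CRVO-affected and contralateral-normal eyes, with the paired
  two-eyes-per-subject structure of a case-control study.

Coordinates are pixels, origin top-left, x rightward, y downward.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString

__all__ = [
    "VesselTreeSpec",
    "Segment",
    "Bifurcation",
    "VesselTreeTruth",
    "generate_vessel_tree",
    "render_fundus",
    "CohortSpec",
    "CohortTable",
    "generate_cohort",
    "TABLE_EYE_PARAMS",
    "TABLE_SUBJECT_PARAMS",
    "EYE_COLUMNS",
    "ANGLE_COLUMNS",
]


class SpecValidationError(ValueError):
    """A generator spec violated one of its invariants."""


# --------------------------------------------------------------------------
# vessel tree generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VesselTreeSpec:
    """Parameters of a synthetic vascular tree.

    Trees radiate outward from the optic-disc rim; at every bifurcation the
    two daughters subtend an angle drawn uniformly from ``angle_range_deg``
    and are oriented symmetrically about the local radial direction, which
    keeps subtrees inside disjoint azimuthal wedges.
    """

    n_roots: int = 4
    branching_depth: int = 2
    angle_range_deg: tuple[float, float] = (40.0, 110.0)
    width_root_px: float = 8.0
    width_taper: float = 0.75
    av_fraction: float = 0.5
    seed: int = 0
    image_size: int = 512
    disc_diameter_px: float = 80.0
    vein_width_factor: float = 4.0 / 3.0
    disc_aspect_range: tuple[float, float] = (0.9, 1.0)

    def validate(self) -> None:
        lo, hi = self.angle_range_deg
        if not (0.0 < lo <= hi < 180.0):
            raise SpecValidationError(
                f"angle_range_deg must lie within (0, 180), got {self.angle_range_deg}"
            )
        if self.n_roots < 1:
            raise SpecValidationError(f"n_roots must be >= 1, got {self.n_roots}")
        if self.branching_depth < 0:
            raise SpecValidationError(
                f"branching_depth must be >= 0, got {self.branching_depth}"
            )
        if self.width_root_px < 1.0:
            raise SpecValidationError(
                f"width_root_px must be >= 1 px, got {self.width_root_px}"
            )
        if not (0.0 < self.width_taper <= 1.0):
            raise SpecValidationError(
                f"width_taper must be in (0, 1], got {self.width_taper}"
            )
        if not (0.0 <= self.av_fraction <= 1.0):
            raise SpecValidationError(
                f"av_fraction must be in [0, 1], got {self.av_fraction}"
            )
        if self.disc_diameter_px <= 0:
            raise SpecValidationError(
                f"disc_diameter_px must be > 0, got {self.disc_diameter_px}"
            )
        if self.image_size < 64:
            raise SpecValidationError(
                f"image_size must be >= 64, got {self.image_size}"
            )


@dataclass(frozen=True)
class Segment:
    """A straight vessel segment: polyline (2 points), width, A/V label."""

    points: tuple[tuple[float, float], ...]  # (x, y) pixel coords
    width_px: float
    label: str  # "artery" | "vein"
    generation: int
    tree_id: int

    @property
    def length(self) -> float:
        pts = np.asarray(self.points)
        return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


@dataclass(frozen=True)
class Bifurcation:
    position: tuple[float, float]
    directions: tuple[tuple[float, float], tuple[float, float]]
    angle_deg: float
    label: str
    tree_id: int


@dataclass(frozen=True)
class VesselTreeTruth:
    """Exact geometry of a synthetic fundus: segments, bifurcations, disc."""

    segments: tuple[Segment, ...]
    bifurcations: tuple[Bifurcation, ...]
    disc_center: tuple[float, float]
    disc_diameter_px: float
    disc_aspect: float  # minor/major axis ratio of the rendered ellipse
    disc_angle_rad: float  # orientation of the major axis
    image_size: int

    def validate(self) -> None:
        for b in self.bifurcations:
            if not (0.0 < b.angle_deg < 180.0):
                raise ValueError(f"bifurcation angle out of (0, 180): {b.angle_deg}")
            starts = [
                s for s in self.segments
                if np.allclose(s.points[-1], b.position) or np.allclose(s.points[0], b.position)
            ]
            if not any(np.allclose(s.points[-1], b.position) for s in starts):
                raise ValueError(f"bifurcation at {b.position} is not a segment endpoint")
        if self.disc_diameter_px <= 0:
            raise ValueError("disc diameter must be > 0")


def _rot(v: np.ndarray, ang: float) -> np.ndarray:
    c, s = math.cos(ang), math.sin(ang)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _segments_collide(segments: list[Segment], clearance: float = 2.0) -> bool:
    """True if two non-adjacent segments come closer than their half-widths."""
    geoms = [LineString(s.points) for s in segments]
    n = len(segments)
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = segments[i], segments[j]
            # adjacent segments (sharing an endpoint) legitimately touch
            shared = any(
                np.allclose(p, q) for p in (si.points[0], si.points[-1])
                for q in (sj.points[0], sj.points[-1])
            )
            if shared:
                continue
            min_gap = 0.5 * (si.width_px + sj.width_px) + clearance
            if geoms[i].distance(geoms[j]) < min_gap:
                return True
    return False


def generate_vessel_tree(spec: VesselTreeSpec) -> VesselTreeTruth:
    """Grow ``n_roots`` binary trees from the disc rim.

    Deterministic for a fixed seed.  Each root produces
    ``2**branching_depth - 1`` bifurcations; every recorded bifurcation
    angle is drawn from ``angle_range_deg``.  Self-intersections between
    non-adjacent segments are rejected and the layout redrawn (bounded
    retries), so the rendered mask skeletonizes to the true topology.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    size = float(spec.image_size)
    center = np.array([size / 2.0, size / 2.0])
    dd = spec.disc_diameter_px
    aspect = float(rng.uniform(*spec.disc_aspect_range))
    disc_angle = float(rng.uniform(0.0, math.pi))

    # interleave arteries and veins around the disc, honoring av_fraction
    n_art = int(round(spec.n_roots * spec.av_fraction))
    labels = (["artery", "vein"] * spec.n_roots)[: spec.n_roots]
    while labels.count("artery") > n_art:
        labels[len(labels) - 1 - labels[::-1].index("artery")] = "vein"
    while labels.count("artery") < n_art:
        labels[len(labels) - 1 - labels[::-1].index("vein")] = "artery"

    wedge = 2.0 * math.pi / spec.n_roots
    margin = spec.width_root_px * spec.vein_width_factor / 2.0 + 4.0

    for _attempt in range(40):
        segments: list[Segment] = []
        bifs: list[Bifurcation] = []
        ok = True
        for tree_id in range(spec.n_roots):
            base_az = tree_id * wedge + float(rng.uniform(-0.08, 0.08)) * wedge
            label = labels[tree_id]
            w0 = spec.width_root_px * (
                spec.vein_width_factor if label == "vein" else 1.0
            )
            start = center + (dd / 2.0) * np.array([math.cos(base_az), math.sin(base_az)])
            direction = np.array([math.cos(base_az), math.sin(base_az)])
            # (point, direction, generation, width)
            frontier = [(start, direction, 0, w0)]
            while frontier:
                p, d, gen, w = frontier.pop()
                length = dd * 0.8 * (0.75 ** gen)
                end = p + length * d
                if np.any(end < margin) or np.any(end > size - margin):
                    ok = False
                    break
                segments.append(
                    Segment(
                        points=(tuple(p), tuple(end)),
                        width_px=max(w, 1.0),
                        label=label,
                        generation=gen,
                        tree_id=tree_id,
                    )
                )
                if gen < spec.branching_depth:
                    alpha = math.radians(float(rng.uniform(*spec.angle_range_deg)))
                    radial = end - center
                    radial = radial / np.linalg.norm(radial)
                    d1 = _rot(radial, -alpha / 2.0)
                    d2 = _rot(radial, +alpha / 2.0)
                    bifs.append(
                        Bifurcation(
                            position=tuple(end),
                            directions=(tuple(d1), tuple(d2)),
                            angle_deg=math.degrees(alpha),
                            label=label,
                            tree_id=tree_id,
                        )
                    )
                    wc = max(w * spec.width_taper, 1.0)
                    frontier.append((end, d1, gen + 1, wc))
                    frontier.append((end, d2, gen + 1, wc))
            if not ok:
                break
        if ok and not _segments_collide(segments):
            truth = VesselTreeTruth(
                segments=tuple(segments),
                bifurcations=tuple(bifs),
                disc_center=tuple(center),
                disc_diameter_px=dd,
                disc_aspect=aspect,
                disc_angle_rad=disc_angle,
                image_size=spec.image_size,
            )
            return truth
    raise RuntimeError(
        "could not lay out a collision-free vessel tree; "
        "reduce n_roots, branching_depth or angle range"
    )


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

BACKGROUND = 120.0
SURROUND = 8.0
DISC_BRIGHTNESS = 70.0  # disc value = BACKGROUND + DISC_BRIGHTNESS
ARTERY_DROP = 30.0  # artery value = BACKGROUND - ARTERY_DROP


def _segment_distance_field(seg: Segment, shape: tuple[int, int]) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Euclidean distance from pixel centers to the segment axis, within a
    bounding box padded by the half-width plus an anti-aliasing apron."""
    (x0, y0), (x1, y1) = seg.points[0], seg.points[-1]
    pad = seg.width_px / 2.0 + 2.0
    rmin = max(int(math.floor(min(y0, y1) - pad)), 0)
    rmax = min(int(math.ceil(max(y0, y1) + pad)) + 1, shape[0])
    cmin = max(int(math.floor(min(x0, x1) - pad)), 0)
    cmax = min(int(math.ceil(max(x0, x1) + pad)) + 1, shape[1])
    yy, xx = np.mgrid[rmin:rmax, cmin:cmax]
    px = xx.astype(np.float64)
    py = yy.astype(np.float64)
    vx, vy = x1 - x0, y1 - y0
    seg_len2 = vx * vx + vy * vy
    if seg_len2 == 0.0:
        d = np.hypot(px - x0, py - y0)
    else:
        t = np.clip(((px - x0) * vx + (py - y0) * vy) / seg_len2, 0.0, 1.0)
        d = np.hypot(px - (x0 + t * vx), py - (y0 + t * vy))
    return d, (slice(rmin, rmax), slice(cmin, cmax))


def render_fundus(
    truth: VesselTreeTruth,
    image_size: int | None = None,
    noise_sd: float = 4.0,
    av_contrast: float = 30.0,
    field_radius: float | None = None,
    noise_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Render a grayscale fundus image plus exact masks.

    Returns ``(image, vessel_mask, av_mask, disc_mask)``.  Vessels are
    stroked with a circular brush of diameter equal to the truth width
    (anti-aliased in the image; the binary mask is the set of pixel centers
    within width/2 of the centerline, so twice the maximum of the interior
    distance transform recovers the width to within half a pixel).  Veins
    are rendered ``av_contrast`` intensity units darker than arteries; the
    disc is a bright ellipse whose smallest circumscribed circle has
    diameter ``truth.disc_diameter_px``.

    ``av_mask`` uses 0 = background, 1 = artery, 2 = vein and is an exact
    partition of ``vessel_mask``.
    """
    size = int(image_size or truth.image_size)
    shape = (size, size)
    for i, seg in enumerate(truth.segments):
        pts = np.asarray(seg.points)
        if np.any(pts - seg.width_px / 2.0 < 0) or np.any(pts + seg.width_px / 2.0 > size):
            raise ValueError(f"segment {i} ({seg.points}) does not fit inside {size}x{size} image")

    image = np.full(shape, BACKGROUND, dtype=np.float64)

    # optic disc: bright ellipse, major axis = DD (so the smallest enclosing
    # circle of its boundary has diameter DD), minor axis = aspect * DD
    cx, cy = truth.disc_center
    yy, xx = np.mgrid[0:size, 0:size]
    ca, sa = math.cos(truth.disc_angle_rad), math.sin(truth.disc_angle_rad)
    xr = (xx - cx) * ca + (yy - cy) * sa
    yr = -(xx - cx) * sa + (yy - cy) * ca
    a = truth.disc_diameter_px / 2.0
    b = a * truth.disc_aspect
    f = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
    disc_cov = np.clip(0.5 - (f - 1.0) * b, 0.0, 1.0)
    disc_mask = f <= 1.0
    image += DISC_BRIGHTNESS * disc_cov

    # vessels: per-class minimum signed distance to any centerline
    inf = np.full(shape, np.inf, dtype=np.float64)
    signed = {"artery": inf.copy(), "vein": inf.copy()}
    for seg in truth.segments:
        d, window = _segment_distance_field(seg, shape)
        s = d - seg.width_px / 2.0
        tgt = signed[seg.label]
        tgt[window] = np.minimum(tgt[window], s)

    vessel_mask = (signed["artery"] <= 0.0) | (signed["vein"] <= 0.0)
    av_mask = np.zeros(shape, dtype=np.uint8)
    artery_closer = signed["artery"] <= signed["vein"]
    av_mask[vessel_mask & artery_closer] = 1
    av_mask[vessel_mask & ~artery_closer] = 2

    artery_val = BACKGROUND - ARTERY_DROP
    vein_val = artery_val - av_contrast
    for label, val in (("artery", artery_val), ("vein", vein_val)):
        cov = np.clip(0.5 - signed[label], 0.0, 1.0)
        image = image * (1.0 - cov) + val * cov

    # circular camera field with dark surround
    r_field = field_radius if field_radius is not None else 0.47 * size
    rr = np.hypot(xx - size / 2.0, yy - size / 2.0)
    field_cov = np.clip(0.5 - (rr - r_field), 0.0, 1.0)
    image = image * field_cov + SURROUND * (1.0 - field_cov)

    if noise_sd > 0:
        rng = np.random.default_rng(noise_seed)
        image = image + rng.normal(0.0, noise_sd, shape)
    image = np.clip(image, 0.0, 255.0)
    return image, vessel_mask, av_mask, disc_mask


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

#: per-eye variables: (group, eye_role) -> (mean, SD), published group summaries
TABLE_EYE_PARAMS: dict[str, dict[tuple[str, str], tuple[float, float]]] = {
    "iop_mmhg": {
        ("BRVO", "affected"): (16.39, 3.00),
        ("BRVO", "contralateral"): (16.11, 3.79),
        ("CRVO", "affected"): (19.58, 8.84),
        ("CRVO", "contralateral"): (15.92, 1.74),
    },
    "ica_c6_mm": {
        ("BRVO", "affected"): (4.07, 0.61),
        ("BRVO", "contralateral"): (4.03, 0.51),
        ("CRVO", "affected"): (3.98, 0.50),
        ("CRVO", "contralateral"): (3.91, 0.50),
    },
    "oa_mm": {
        ("BRVO", "affected"): (3.23, 0.43),
        ("BRVO", "contralateral"): (3.22, 0.46),
        ("CRVO", "affected"): (3.40, 0.41),
        ("CRVO", "contralateral"): (3.47, 0.28),
    },
    "onsasw_3mm": {
        ("BRVO", "affected"): (1.01, 0.21),
        ("BRVO", "contralateral"): (0.99, 0.34),
        ("CRVO", "affected"): (1.16, 0.19),
        ("CRVO", "contralateral"): (1.01, 0.16),
    },
    "onsasw_9mm": {
        ("BRVO", "affected"): (0.86, 0.15),
        ("BRVO", "contralateral"): (0.82, 0.12),
        ("CRVO", "affected"): (1.01, 0.21),
        ("CRVO", "contralateral"): (0.88, 0.14),
    },
    "onsasw_15mm": {
        ("BRVO", "affected"): (0.79, 0.12),
        ("BRVO", "contralateral"): (0.78, 0.13),
        ("CRVO", "affected"): (0.84, 0.10),
        ("CRVO", "contralateral"): (0.81, 0.09),
    },
    "rel_arteriolar_caliber": {
        ("BRVO", "affected"): (0.057, 0.010),
        ("BRVO", "contralateral"): (0.058, 0.010),
        ("CRVO", "affected"): (0.059, 0.015),
        ("CRVO", "contralateral"): (0.062, 0.009),
    },
    "rel_venular_caliber": {
        ("BRVO", "affected"): (0.076, 0.009),
        ("BRVO", "contralateral"): (0.077, 0.010),
        ("CRVO", "affected"): (0.095, 0.015),
        ("CRVO", "contralateral"): (0.077, 0.011),
    },
    "avr": {
        ("BRVO", "affected"): (0.747, 0.088),
        ("BRVO", "contralateral"): (0.766, 0.107),
        ("CRVO", "affected"): (0.642, 0.125),
        ("CRVO", "contralateral"): (0.809, 0.076),
    },
    "angle_superior_nasal_artery_deg": {
        ("BRVO", "affected"): (62.406, 14.605),
        ("BRVO", "contralateral"): (63.482, 16.364),
        ("CRVO", "affected"): (48.994, 12.865),
        ("CRVO", "contralateral"): (62.583, 24.240),
    },
    "angle_superior_nasal_vein_deg": {
        ("BRVO", "affected"): (66.999, 19.078),
        ("BRVO", "contralateral"): (61.722, 18.242),
        ("CRVO", "affected"): (55.403, 20.259),
        ("CRVO", "contralateral"): (61.500, 18.108),
    },
    "angle_inferior_nasal_artery_deg": {
        ("BRVO", "affected"): (64.673, 19.888),
        ("BRVO", "contralateral"): (65.773, 16.094),
        ("CRVO", "affected"): (53.089, 16.113),
        ("CRVO", "contralateral"): (59.049, 14.238),
    },
    "angle_inferior_nasal_vein_deg": {
        ("BRVO", "affected"): (67.788, 16.344),
        ("BRVO", "contralateral"): (65.380, 20.733),
        ("CRVO", "affected"): (59.778, 19.382),
        ("CRVO", "contralateral"): (69.518, 14.393),
    },
    "angle_superior_temporal_artery_deg": {
        ("BRVO", "affected"): (68.421, 18.789),
        ("BRVO", "contralateral"): (71.354, 11.650),
        ("CRVO", "affected"): (56.155, 16.306),
        ("CRVO", "contralateral"): (65.832, 14.445),
    },
    "angle_superior_temporal_vein_deg": {
        ("BRVO", "affected"): (66.719, 15.836),
        ("BRVO", "contralateral"): (67.096, 16.945),
        ("CRVO", "affected"): (66.907, 23.359),
        ("CRVO", "contralateral"): (64.552, 17.940),
    },
    "angle_inferior_temporal_artery_deg": {
        ("BRVO", "affected"): (78.268, 25.170),
        ("BRVO", "contralateral"): (74.581, 17.619),
        ("CRVO", "affected"): (57.872, 22.942),
        ("CRVO", "contralateral"): (80.617, 21.042),
    },
    "angle_inferior_temporal_vein_deg": {
        ("BRVO", "affected"): (72.225, 21.063),
        ("BRVO", "contralateral"): (74.826, 16.625),
        ("CRVO", "affected"): (67.992, 23.633),
        ("CRVO", "contralateral"): (66.566, 17.837),
    },
}

#: subject-level variables: group -> (mean, SD) or special parameters
TABLE_SUBJECT_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "age_y": {"BRVO": (53.0, 10.0), "CRVO": (50.0, 15.0)},
    "height_m": {"BRVO": (1.65, 0.06), "CRVO": (1.66, 0.08)},
    "bmi": {"BRVO": (25.97, 2.47), "CRVO": (26.08, 3.04)},
}

#: male fraction per group (18/34 BRVO, 16/25 CRVO)
MALE_FRACTION = {"BRVO": 18.0 / 34.0, "CRVO": 16.0 / 25.0}

#: zero-inflated log-normal hypertension duration: (P(zero), mu_log, sd_log),
#: calibrated to the published medians/IQRs (BRVO median 0, Q3 4.5 y;
#: CRVO IQR degenerate at 0)
HBP_DURATION_PARAMS = {
    "BRVO": (0.6, math.log(6.0), 1.0),
    "CRVO": (0.8, math.log(4.0), 1.0),
}

ANGLE_COLUMNS = [c for c in TABLE_EYE_PARAMS if c.startswith("angle_")]
EYE_COLUMNS = list(TABLE_EYE_PARAMS)


@dataclass(frozen=True)
class CohortSpec:
    """Simulation parameters for a paired case-control cohort.

    ``eye_params`` / ``subject_params`` default to the published group
    summaries.  With ``effects=False`` every affected-eye distribution is
    replaced by its contralateral counterpart, giving a null cohort in
    which no eye-level variable differs within subjects.
    """

    n_brvo: int = 34
    n_crvo: int = 25
    eye_params: dict = field(default_factory=lambda: TABLE_EYE_PARAMS)
    subject_params: dict = field(default_factory=lambda: TABLE_SUBJECT_PARAMS)
    effects: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_brvo < 1 or self.n_crvo < 1:
            raise SpecValidationError("group sizes must be >= 1")
        for var, cells in self.eye_params.items():
            for cell, (mean, sd) in cells.items():
                if sd < 0:
                    raise SpecValidationError(f"negative SD for {var} {cell}: {sd}")
        for var, groups in self.subject_params.items():
            for g, (mean, sd) in groups.items():
                if sd < 0:
                    raise SpecValidationError(f"negative SD for {var} {g}: {sd}")


@dataclass
class CohortTable:
    """Per-eye records, two rows (affected + contralateral) per subject."""

    df: pd.DataFrame

    def validate(self) -> None:
        counts = self.df.groupby("subject_id").size()
        if not (counts == 2).all():
            bad = counts[counts != 2].index.tolist()
            raise ValueError(f"subjects without exactly 2 eyes: {bad}")
        roles = self.df.groupby("subject_id")["eye_role"].nunique()
        if not (roles == 2).all():
            raise ValueError("each subject needs one affected and one contralateral eye")
        groups = self.df.groupby("subject_id")["group"].nunique()
        if not (groups == 1).all():
            raise ValueError("group label must be constant within subject")

    def to_csv(self) -> str:
        buf = io.StringIO()
        self.df.to_csv(buf, index=False, float_format="%.6g", lineterminator="\n")
        return buf.getvalue()


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int,
                      floor: float = 0.0) -> np.ndarray:
    """Normal draws resampled above a physiologic floor (rejection)."""
    if sd == 0.0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, n)
    for _ in range(100):
        bad = out < floor
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.maximum(out, floor)


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a paired cohort from the spec's group means and SDs.

    Subject-level variables (age, sex, height, BMI, hypertension duration)
    are shared by both of a subject's rows; weight is derived as
    BMI x height^2 so the three stay mutually consistent.  Eye-level
    variables are drawn independently per eye from their
    (group, eye-role) cell, truncated at 0.  Deterministic for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    subject_id = 0
    for group, n in (("BRVO", spec.n_brvo), ("CRVO", spec.n_crvo)):
        age = _truncated_normal(rng, *spec.subject_params["age_y"][group], n, floor=18.0)
        height = _truncated_normal(rng, *spec.subject_params["height_m"][group], n, floor=1.2)
        bmi = _truncated_normal(rng, *spec.subject_params["bmi"][group], n, floor=14.0)
        male = rng.random(n) < MALE_FRACTION[group]
        p0, mu, sdl = HBP_DURATION_PARAMS[group]
        hbp = np.where(rng.random(n) < p0, 0.0, rng.lognormal(mu, sdl, n))
        affected_od = rng.random(n) < 0.5
        eye_draws = {}
        for var in spec.eye_params:
            for role in ("affected", "contralateral"):
                cell = (group, role)
                src = (group, "contralateral") if (not spec.effects and role == "affected") else cell
                mean, sd = spec.eye_params[var][src]
                eye_draws[(var, role)] = _truncated_normal(rng, mean, sd, n)
        for i in range(n):
            for role in ("affected", "contralateral"):
                lat_od = affected_od[i] if role == "affected" else not affected_od[i]
                row = {
                    "subject_id": f"S{subject_id:05d}",
                    "group": group,
                    "eye_role": role,
                    "laterality": "OD" if lat_od else "OS",
                    "age_y": age[i],
                    "sex": "male" if male[i] else "female",
                    "height_m": height[i],
                    "bmi": bmi[i],
                    "weight_kg": bmi[i] * height[i] ** 2,
                    "hbp_duration_y": hbp[i],
                }
                for var in spec.eye_params:
                    row[var] = eye_draws[(var, role)][i]
                rows.append(row)
            subject_id += 1
    table = CohortTable(pd.DataFrame(rows))
    table.validate()
    return table


def recovery_sweep_specs(n_images: int = 20, base_seed: int = 1) -> list[VesselTreeSpec]:
    """Benchmark conditions for geometry recovery: 20 images sweeping
    vessel widths over ~4-12 px, branching angles over 40-110 degrees and
    disc diameters over 60-100 px."""
    specs = []
    for i in range(n_images):
        specs.append(
            VesselTreeSpec(
                seed=base_seed + i,
                width_root_px=7.0 + 2.0 * (i % 5) / 4.0,  # artery roots 7-9 px
                width_taper=0.78,
                angle_range_deg=(40.0, 110.0),
                disc_diameter_px=60.0 + 2.0 * i,  # 60-98 px
            )
        )
    return specs


def null_cohort_spec(n_per_group: int, seed: int) -> CohortSpec:
    """Convenience: a cohort with all affected-eye effects switched off."""
    return CohortSpec(n_brvo=n_per_group, n_crvo=n_per_group, effects=False, seed=seed)


def sized_cohort_spec(n_per_group: int, seed: int, effects: bool = True) -> CohortSpec:
    return CohortSpec(n_brvo=n_per_group, n_crvo=n_per_group, effects=effects, seed=seed)
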