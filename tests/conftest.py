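"""Shared fixtures: rendered synthetic scenes and recovery measurements."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pytest
from shapely.geometry import LineString, Point

from fundusgeom import fundus_pipeline as fp
from fundusgeom import geometry, synthgen


def dt_width(mask: np.ndarray) -> float:
    """Distance-transform width oracle for a single-stroke mask.

    The EDT measures to background pixel centers, overshooting the true
    boundary by half a pixel per side, hence the -1 correction.
    """
    from scipy import ndimage

    return 2.0 * float(ndimage.distance_transform_edt(mask).max()) - 1.0


@dataclass
class Scene:
    """One rendered synthetic fundus with its ground truth."""

    truth: synthgen.VesselTreeTruth
    image: np.ndarray
    vessel_mask: np.ndarray
    av_mask: np.ndarray
    disc_mask: np.ndarray


def make_scene(spec: synthgen.VesselTreeSpec, noise_sd: float = 4.0,
               av_contrast: float = 30.0) -> Scene:
    truth = synthgen.generate_vessel_tree(spec)
    img, vm, avm, dm = synthgen.render_fundus(
        truth, noise_sd=noise_sd, av_contrast=av_contrast, noise_seed=spec.seed)
    return Scene(truth, img, vm, avm, dm)


@pytest.fixture(scope="session")
def default_scene() -> Scene:
    return make_scene(synthgen.VesselTreeSpec(seed=7))


@dataclass
class RecoveryResult:
    """Per-image truth-vs-measured errors on the benchmark sweep."""

    width_abs_errors: list[float]
    angle_abs_errors: list[float]
    dd_rel_error: float
    disc_center_error: float
    n_bif_truth: int
    n_bif_found: int


def measure_recovery(scene: Scene) -> RecoveryResult:
    """Run the measurement chain on truth masks and score against truth."""
    clg = geometry.extract_centerline(scene.vessel_mask)
    geometry.label_edges(clg, scene.av_mask)
    profile = geometry.measure_diameters(scene.vessel_mask, clg)
    bif_nodes, _ = geometry.detect_bifurcations(clg)
    angles = geometry.bifurcation_angles(clg, profile=profile)

    # width error: each measured point vs the width of its truth segment
    segs = [(LineString(s.points), s.width_px) for s in scene.truth.segments]
    pts = profile.df[["x", "y"]].to_numpy()
    dia = profile.df["diameter_px"].to_numpy()
    werrs = []
    for p, d in zip(pts, dia):
        gp = Point(p)
        ls, w = min(segs, key=lambda sw: sw[0].distance(gp))
        if ls.distance(gp) <= 1.5:
            werrs.append(abs(d - w))

    aerrs = []
    for b in scene.truth.bifurcations:
        best = min(angles, key=lambda a: math.hypot(a.position[0] - b.position[0],
                                                    a.position[1] - b.position[1]))
        aerrs.append(abs(best.angle_deg - b.angle_deg))

    pre = fp.preprocess(scene.image)
    disc = fp.locate_and_segment_disc(pre)
    dd_err = abs(disc.dd - scene.truth.disc_diameter_px) / scene.truth.disc_diameter_px
    cerr = math.hypot(disc.center[0] - scene.truth.disc_center[0],
                      disc.center[1] - scene.truth.disc_center[1])
    return RecoveryResult(
        width_abs_errors=werrs,
        angle_abs_errors=aerrs,
        dd_rel_error=dd_err,
        disc_center_error=cerr,
        n_bif_truth=len(scene.truth.bifurcations),
        n_bif_found=len(bif_nodes),
    )


@pytest.fixture(scope="session")
def recovery_results() -> list[RecoveryResult]:
    """Geometry recovery on the 20-image benchmark sweep (session-cached)."""
    return [measure_recovery(make_scene(spec))
            for spec in synthgen.recovery_sweep_specs()]
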