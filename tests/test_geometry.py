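"""Centerline, diameter, caliber and branching-angle tests."""

import math
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from fundusgeom import geometry as geo
from fundusgeom import synthgen as sg
from conftest import make_scene


def disc_at(cx, cy, dd):
    return SimpleNamespace(center=(cx, cy), dd=dd)


class TestCenterlineExtraction:
    def test_empty_mask_gives_empty_graph(self):
        g = geo.extract_centerline(np.zeros((32, 32), bool))
        assert g.n_nodes == 0 and g.n_edges == 0

    def test_solid_bar_thins_to_single_path(self):
        """A 100 x 5 bar must thin to one edge between two endpoints with
        path length within [92, 100] (end erosion bounded by the width)."""
        mask = np.zeros((40, 120), bool)
        mask[18:23, 10:110] = True
        g = geo.extract_centerline(mask)
        assert g.n_edges == 1
        assert len(g.nodes_of_degree(1)) == 2
        (_u, _v, _k, d), = g.edges()
        length = float(np.sum(np.hypot(*np.diff(d["chain"], axis=0).T)))
        assert 92.0 <= length <= 100.0

    @pytest.mark.parametrize("seed", [3, 11, 21])
    def test_rendered_tree_recovers_truth_bifurcation_count(self, seed):
        scene = make_scene(sg.VesselTreeSpec(seed=seed))
        g = geo.extract_centerline(scene.vessel_mask)
        bif, crossings = geo.detect_bifurcations(g)
        assert len(bif) == len(scene.truth.bifurcations)
        assert crossings == []


class TestDiameters:
    def test_constant_width_bar(self):
        mask = np.zeros((40, 120), bool)
        mask[18:23, 10:110] = True
        g = geo.extract_centerline(mask)
        prof = geo.measure_diameters(mask, g)
        assert len(prof.df) > 50
        assert np.all(np.abs(prof.df["diameter_px"] - 5.0) <= 0.5)
        assert prof.n_skipped == 0

    def test_one_pixel_line(self):
        mask = np.zeros((20, 60), bool)
        mask[10, 5:55] = True
        g = geo.extract_centerline(mask)
        prof = geo.measure_diameters(mask, g)
        assert np.all(np.abs(prof.df["diameter_px"] - 1.0) <= 0.3)

    def test_rendered_width_8_recovered_within_half_pixel(self):
        truth = sg.VesselTreeTruth(
            segments=(sg.Segment(points=((40.0, 100.3), (220.0, 140.7)),
                                 width_px=8.0, label="vein", generation=0, tree_id=0),),
            bifurcations=(), disc_center=(400.0, 400.0), disc_diameter_px=1e-6,
            disc_aspect=1.0, disc_angle_rad=0.0, image_size=256)
        _img, vm, _avm, _dm = sg.render_fundus(truth, noise_sd=0.0)
        g = geo.extract_centerline(vm)
        prof = geo.measure_diameters(vm, g)
        assert abs(prof.df["diameter_px"].mean() - 8.0) <= 0.5


def synthetic_profile(widths: dict[str, float], dd: float, n_pts: int = 60):
    """Profile with arteries/veins of constant width on a ring at 1.25 DD."""
    rows = []
    eid = 0
    for label, w in widths.items():
        for start in (0.0, math.pi):  # two vessels per class
            for i in range(n_pts):
                ang = start + 0.3 * i / n_pts
                r = 1.25 * dd
                rows.append({
                    "x": 300 + r * math.cos(ang), "y": 300 + r * math.sin(ang),
                    "tx": 1.0, "ty": 0.0, "s": float(i),
                    "diameter_px": w, "label": label, "edge_id": eid,
                })
            eid += 1
    return geo.DiameterProfile(df=pd.DataFrame(rows))


class TestAnnulusCalibers:
    def test_forced_arithmetic(self):
        """Arteries 6 px, veins 9 px, DD 100 -> relA .06, relV .09, AVR 2/3."""
        prof = synthetic_profile({"artery": 6.0, "vein": 9.0}, dd=100.0)
        s = geo.annulus_calibers(prof, disc_at(300, 300, 100.0))
        assert s.complete
        assert s.rel_arteriolar == pytest.approx(0.06)
        assert s.rel_venular == pytest.approx(0.09)
        assert s.avr == pytest.approx(6.0 / 9.0)
        assert s.n_sections_arteriolar >= 10

    def test_equal_means_give_avr_one(self):
        prof = synthetic_profile({"artery": 7.0, "vein": 7.0}, dd=100.0)
        s = geo.annulus_calibers(prof, disc_at(300, 300, 100.0))
        assert s.avr == pytest.approx(1.0)

    def test_avr_identity_holds_on_rendered_scenes(self):
        for seed in (2, 9):
            scene = make_scene(sg.VesselTreeSpec(seed=seed))
            g = geo.extract_centerline(scene.vessel_mask)
            geo.label_edges(g, scene.av_mask)
            prof = geo.measure_diameters(scene.vessel_mask, g)
            disc = disc_at(*scene.truth.disc_center, scene.truth.disc_diameter_px)
            s = geo.annulus_calibers(prof, disc)
            assert s.complete
            assert s.avr == pytest.approx(s.rel_arteriolar / s.rel_venular, rel=1e-12)

    def test_missing_class_flags_incomplete(self):
        prof = synthetic_profile({"artery": 6.0}, dd=100.0)
        s = geo.annulus_calibers(prof, disc_at(300, 300, 100.0))
        assert not s.complete and s.avr is None and s.rel_venular is None

    def test_zone_excludes_points_outside_annulus(self):
        prof = synthetic_profile({"artery": 6.0, "vein": 9.0}, dd=100.0)
        far = disc_at(300, 300, 300.0)  # ring at 1.25*100 sits below 1.0*DD
        s = geo.annulus_calibers(prof, far)
        assert not s.complete

    def test_relative_calibers_scale_invariant(self):
        """Doubling all lengths (a x2 image rescale) leaves relative
        calibers and AVR unchanged within 3%."""
        scene = make_scene(sg.VesselTreeSpec(seed=4))
        g = geo.extract_centerline(scene.vessel_mask)
        geo.label_edges(g, scene.av_mask)
        prof = geo.measure_diameters(scene.vessel_mask, g)
        disc = disc_at(*scene.truth.disc_center, scene.truth.disc_diameter_px)
        s1 = geo.annulus_calibers(prof, disc)

        big = np.kron(scene.vessel_mask, np.ones((2, 2), bool))
        big_av = np.kron(scene.av_mask, np.ones((2, 2), np.uint8))
        g2 = geo.extract_centerline(big)
        geo.label_edges(g2, big_av)
        prof2 = geo.measure_diameters(big, g2)
        disc2 = disc_at(2 * scene.truth.disc_center[0], 2 * scene.truth.disc_center[1],
                        2 * scene.truth.disc_diameter_px)
        s2 = geo.annulus_calibers(prof2, disc2)
        assert s2.rel_arteriolar == pytest.approx(s1.rel_arteriolar, rel=0.03)
        assert s2.rel_venular == pytest.approx(s1.rel_venular, rel=0.03)
        assert s2.avr == pytest.approx(s1.avr, rel=0.03)


def _cross_mask():
    mask = np.zeros((60, 60), bool)
    mask[28:33, 5:55] = True
    mask[5:55, 28:33] = True
    return mask


class TestBifurcations:
    def test_unbranched_vessel_has_no_bifurcations(self):
        mask = np.zeros((40, 120), bool)
        mask[18:23, 10:110] = True
        g = geo.extract_centerline(mask)
        bif, cross = geo.detect_bifurcations(g)
        assert bif == [] and cross == []

    def test_crossing_is_degree_four_and_excluded(self):
        g = geo.extract_centerline(_cross_mask())
        bif, cross = geo.detect_bifurcations(g)
        assert len(cross) == 1
        assert bif == []

    def test_depth_two_single_root_finds_three_bifurcations(self):
        scene = make_scene(sg.VesselTreeSpec(n_roots=1, branching_depth=2, seed=5))
        g = geo.extract_centerline(scene.vessel_mask)
        bif, _ = geo.detect_bifurcations(g)
        assert len(bif) == 3


def _angle_graph(d1_deg: float, d2_deg: float, parent_deg: float = 180.0):
    """Graph with one degree-3 node and straight chains at given headings."""
    g = geo.CenterlineGraph()
    node_pos = (100.0, 100.0)
    g.graph.add_node(0, pos=node_pos, pixels={(100, 100)})
    for i, heading in enumerate((parent_deg, d1_deg, d2_deg), start=1):
        th = math.radians(heading)
        # (row, col) chain: x = cos, y = sin, row = y
        chain = np.array([(100.0 + t * math.sin(th), 100.0 + t * math.cos(th))
                          for t in np.linspace(0.0, 40.0 if i == 1 else 30.0, 61)])
        g.graph.add_node(i, pos=tuple(chain[-1]), pixels=set())
        g.graph.add_edge(0, i, chain=chain)
    return g


class TestBranchingAngles:
    def test_orthogonal_daughters_give_90_degrees(self):
        g = _angle_graph(0.0, 90.0)  # +x and +y; parent along -x (longest)
        ang, short = geo.branching_angle(g, 0)
        assert ang == pytest.approx(90.0, abs=0.5)
        assert not short

    def test_symmetric_pm30_about_vertical_gives_60(self):
        g = _angle_graph(60.0, 120.0)
        ang, _ = geo.branching_angle(g, 0)
        assert ang == pytest.approx(60.0, abs=0.5)

    def test_short_daughter_is_flagged(self):
        g = geo.CenterlineGraph()
        g.graph.add_node(0, pos=(50.0, 50.0), pixels={(50, 50)})
        for i, (dr, dc, ln) in enumerate([(0, -1, 40.0), (0, 1, 6.0), (1, 0, 6.0)], 1):
            chain = np.array([(50.0 + t * dr, 50.0 + t * dc)
                              for t in np.linspace(0, ln, int(ln) + 1)])
            g.graph.add_node(i, pos=tuple(chain[-1]), pixels=set())
            g.graph.add_edge(0, i, chain=chain)
        ang, short = geo.branching_angle(g, 0)
        assert short
        assert ang == pytest.approx(90.0, abs=1.0)

    @pytest.mark.parametrize("alpha", [55.0, 75.0, 95.0])
    def test_rendered_truth_angle_recovered_within_5_degrees(self, alpha):
        scene = make_scene(sg.VesselTreeSpec(
            n_roots=1, branching_depth=1, angle_range_deg=(alpha, alpha), seed=8))
        g = geo.extract_centerline(scene.vessel_mask)
        prof = geo.measure_diameters(scene.vessel_mask, g)
        (node,) = geo.detect_bifurcations(g)[0]
        ang, _ = geo.branching_angle(g, node, profile=prof)
        assert ang == pytest.approx(alpha, abs=5.0)


class TestQuadrants:
    DISC = disc_at(256.0, 256.0, 80.0)

    def test_od_above_and_left_is_superior_temporal(self):
        assert geo.assign_quadrant((200.0, 200.0), self.DISC, "OD") == "superior temporal"

    def test_os_below_and_left_is_inferior_nasal(self):
        assert geo.assign_quadrant((200.0, 300.0), self.DISC, "OS") == "inferior nasal"

    def test_laterality_flip_mirrors_nasal_temporal_only(self):
        for pos in [(200.0, 200.0), (300.0, 190.0), (190.0, 310.0), (310.0, 320.0)]:
            od = geo.assign_quadrant(pos, self.DISC, "OD").split()
            os_ = geo.assign_quadrant(pos, self.DISC, "OS").split()
            assert od[0] == os_[0]
            assert {od[1], os_[1]} == {"nasal", "temporal"}

    def test_disc_center_is_undefined(self):
        with pytest.raises(ValueError, match="undefined quadrant"):
            geo.assign_quadrant((256.0, 256.0), self.DISC, "OD")

    def test_quadrant_counts_partition_bifurcations(self):
        scene = make_scene(sg.VesselTreeSpec(seed=13))
        g = geo.extract_centerline(scene.vessel_mask)
        geo.label_edges(g, scene.av_mask)
        disc = disc_at(*scene.truth.disc_center, scene.truth.disc_diameter_px)
        angles = geo.bifurcation_angles(g, disc=disc, laterality="OD")
        per_quadrant = {}
        for a in angles:
            per_quadrant[a.quadrant] = per_quadrant.get(a.quadrant, 0) + 1
        assert sum(per_quadrant.values()) == len(angles)
        assert len(angles) == len(scene.truth.bifurcations)
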