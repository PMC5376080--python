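"""Phantom, treatment room, beamline and benchmark scenario builders."""

import math

import numpy as np
import pytest

from straydose import scenario as sn
from straydose.physics import MATERIALS


@pytest.fixture(scope="module")
def phantom():
    return sn.build_phantom()


@pytest.fixture(scope="module")
def p4_scenario():
    return sn.assemble_treatment_scenario("P4").validate()


class TestRoom:
    def test_inner_volume_is_493_2_m3(self):
        room = sn.build_room()
        assert room.inner_volume_m3 == pytest.approx(13.7 * 9 * 4)

    def test_control_room_volume_79_2_m3(self):
        room = sn.build_room()
        assert room.control_volume_m3 == pytest.approx(9.9 * 2 * 4)

    def test_air_density(self):
        assert sn.build_room().air_density == pytest.approx(0.00129)

    def test_concrete_density(self):
        assert MATERIALS["concrete"].density == pytest.approx(2.35)


class TestPhantom:
    def test_twelve_labelled_organs(self, phantom):
        assert set(phantom.organ_cells) == set(sn.ORGANS)
        assert len(phantom.organ_cells) == 12

    def test_irradiation_points_inside_named_organs(self, phantom, p4_scenario):
        """Each Pi lies inside its organ (checked in the assembled model,
        which is shifted so P4 sits at the isocenter)."""
        model = p4_scenario.model
        for pos, organ in sn.TARGET_ORGAN.items():
            p = p4_scenario.phantom.points[pos]
            assert model.locate_point(p).organ_label == organ

    def test_p4_point_is_at_isocenter(self, p4_scenario):
        assert np.allclose(p4_scenario.phantom.points["P4"], (0, 0, 0),
                           atol=1e-12)

    def test_organ_masses_positive_and_plausible(self, phantom):
        for organ, m in phantom.masses.items():
            assert m > 0
        assert 1000 < phantom.masses["brain"] < 1400          # g
        assert 300 < phantom.masses["left_lung"] < 500
        assert phantom.masses["testes"] < 50

    def test_monte_carlo_volume_audit(self, phantom):
        """Sampled organ volumes agree with the analytic quadric formulas."""
        model_cells = {c.id: c for c in phantom.cells}
        rng = np.random.default_rng(21)
        surfaces = {s.id: s for s in phantom.surfaces}
        for organ, bbox in (("liver", ((-15, 3), (-25, -11), (-4, 6))),
                            ("heart", ((-2.9, 3.9), (3.5, 12.5), (-1.5, 6.5))),
                            ("testes", ((-3.5, 3.5), (-83.5, -80.5),
                                        (-1.5, 1.5)))):
            (x0, x1), (y0, y1), (z0, z1) = bbox
            n = 40_000
            pts = np.column_stack([rng.uniform(x0, x1, n),
                                   rng.uniform(y0, y1, n),
                                   rng.uniform(z0, z1, n)])
            cell = model_cells[f"organ_{organ}"]
            inside = cell.region.contains_many(pts, surfaces)
            v_box = (x1 - x0) * (y1 - y0) * (z1 - z0)
            p = cell.volume / v_box
            sigma = math.sqrt(p * (1 - p) / n)
            assert abs(inside.mean() - p) < 3 * sigma, organ

    def test_lungs_disjoint(self, phantom):
        """No point of the left lung belongs to the right lung."""
        surfaces = {s.id: s for s in phantom.surfaces}
        left = phantom.organ_cells["left_lung"].region
        right = phantom.organ_cells["right_lung"].region
        rng = np.random.default_rng(22)
        pts = np.column_stack([rng.uniform(4, 13, 100_000),
                               rng.uniform(6, 30, 100_000),
                               rng.uniform(-6, 6, 100_000)])
        in_left = left.contains_many(pts, surfaces)
        assert in_left.sum() > 1000
        assert not np.any(right.contains_many(pts[in_left], surfaces))

    def test_bad_scale_rejected(self):
        with pytest.raises(sn.ScenarioError):
            sn.build_phantom(scale=-1.0)


class TestAiming:
    def test_aim_at_p5_hits_brain(self, p4_scenario):
        sc5 = sn.aim_beam(p4_scenario, "P5")
        segs = sc5.model.ray_trace(sc5.source.position, (0, 0, -1.0))
        assert "organ_brain" in [c for c, _ in segs]

    def test_retarget_translation_is_rigid(self, p4_scenario):
        """Moving the aim from P4 to P1 shifts the phantom by P4 - P1 in the
        phantom frame, exactly."""
        sc1 = sn.aim_beam(p4_scenario, "P1")
        base = sn._phantom_geometry()[4]
        expected = np.array(base["P4"]) - np.array(base["P1"])
        delta = np.array(sc1.phantom.shift) - np.array(p4_scenario.phantom.shift)
        assert np.allclose(delta, expected, atol=1e-12)

    def test_first_tissue_on_beam_axis_is_skin(self, p4_scenario):
        segs = p4_scenario.model.ray_trace(p4_scenario.source.position,
                                           (0, 0, -1.0))
        organs = [p4_scenario.model.cell(c).organ_label for c, _ in segs]
        tissues = [o for o in organs if o is not None]
        assert tissues[0] == "skin"

    def test_room_cells_unchanged_by_retarget(self, p4_scenario):
        sc2 = sn.aim_beam(p4_scenario, "P2")
        assert len(sc2.model.cells) == len(p4_scenario.model.cells)

    def test_unknown_target_rejected(self):
        with pytest.raises(sn.ScenarioError, match="P1..P5"):
            sn.assemble_treatment_scenario("P9")


class TestAssembledScenario:
    def test_space_filling_audit(self, p4_scenario):
        """>= 1e5 random points in the bounding box each locate to exactly
        one cell: the model is space-filling and non-overlapping."""
        rng = np.random.default_rng(23)
        (x0, x1), (y0, y1), (z0, z1) = p4_scenario.model.bounding_box
        n = 100_000
        pts = np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n),
                               rng.uniform(z0, z1, n)])
        counts = p4_scenario.model.locate_points(pts)
        assert np.all(counts == 1)

    def test_source_to_isocenter_distance(self, p4_scenario):
        assert np.linalg.norm(p4_scenario.source.position) == pytest.approx(100.0)


class TestSources:
    def test_spectrum_normalised(self):
        e, p = sn.synthetic_6mv_spectrum()
        assert p.sum() == pytest.approx(1.0)
        assert np.all(e > 0) and e.max() <= 6.0
        src = sn.BeamSource("spectrum-beam", (0, 0, 100), e, p)
        assert 1.0 < src.mean_energy < 2.5      # hardened 6 MV beam in air

    def test_cs137_point_source(self):
        src = sn.cs137_source()
        rng = np.random.default_rng(1)
        for _ in range(5):
            pos, u, E = src.sample(rng)
            assert E == 0.6616
            assert np.linalg.norm(u) == pytest.approx(1.0)

    def test_beam_directions_fill_field(self):
        e, p = np.array([1.0]), np.array([1.0])
        src = sn.BeamSource("spectrum-beam", (0, 0, 100), e, p, (10.0, 10.0))
        rng = np.random.default_rng(2)
        xs = []
        for _ in range(500):
            pos, u, _ = src.sample(rng)
            t = -pos[2] / u[2]                   # to the isocenter plane
            xs.append(pos[0] + t * u[0])
        assert -5 <= min(xs) and max(xs) <= 5
        assert max(xs) > 3 and min(xs) < -3

    def test_bad_spectrum_rejected(self):
        with pytest.raises(sn.ScenarioError):
            sn.BeamSource("spectrum-beam", (0, 0, 100), np.array([1.0, -2.0]),
                          np.array([0.5, 0.5]))
        with pytest.raises(sn.ScenarioError):
            sn.BeamSource("nonsense", (0, 0, 100), np.array([1.0]),
                          np.array([1.0]))


class TestWaterBenchmark:
    def test_sixty_bins_for_30cm_at_half_cm(self):
        sc = sn.build_water_phantom_benchmark()
        assert len(sc.pdd_bin_ids) == 60
        assert sc.pdd_depths[0] == pytest.approx(0.25)
        assert sc.pdd_depths[-1] == pytest.approx(29.75)

    def test_bins_centred_on_beam_axis(self):
        sc = sn.build_water_phantom_benchmark()
        for k in (0, 30, 59):
            cell = sc.model.locate_point((0.0, 0.0, -(k + 0.5) * 0.5))
            assert cell.id == f"pdd_bin_{k:03d}"

    def test_beam_axis_intersects_every_bin(self):
        sc = sn.build_water_phantom_benchmark()
        segs = sc.model.ray_trace((0, 0, 100.0), (0, 0, -1.0))
        traversed = {c for c, _ in segs}
        assert set(sc.pdd_bin_ids) <= traversed

    def test_fractional_depth_rejected(self):
        with pytest.raises(sn.ScenarioError):
            sn.build_water_phantom_benchmark(depth=30.3, bin_width=0.5)
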