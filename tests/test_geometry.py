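"""Margin phantom construction: shapes, layouts, invariants."""

import math

import numpy as np
import pytest

from marginqus.geometry import (
    DOMAIN_SIZE,
    DUCT_RADIUS,
    CalcLayoutConfig,
    EllipseShape,
    Pathology,
    build_margin_model,
    calcification_layout,
    homogeneous_control,
    standard_offsets,
)


class TestStandardOffsets:
    def test_five_positions_one_centered(self):
        offs = standard_offsets()
        assert len(offs) == 5
        assert (0.0, 0.0) in offs
        assert all(abs(dx) + abs(dy) in (0.0, 0.4e-3) for dx, dy in offs)

    def test_all_offsets_keep_duct_inside_domain(self):
        for dx, dy in standard_offsets():
            assert math.hypot(dx, dy) + DUCT_RADIUS <= DOMAIN_SIZE / 2 + 1e-15

    def test_offset_set_symmetric_under_mirroring(self):
        offs = set(standard_offsets())
        assert {(-dx, dy) for dx, dy in offs} == offs
        assert {(dx, -dy) for dx, dy in offs} == offs


class TestBuildMarginModel:
    def test_normal_duct_region_structure(self):
        m = build_margin_model(Pathology.NORMAL)
        assert len(m.regions) == 3
        ann = m.regions[1].shape
        assert m.regions[1].material_label == "glandular"
        assert ann.outer_radius - ann.inner_radius == pytest.approx(40e-6)
        assert m.regions[2].shape.radius == pytest.approx(0.46e-3)

    def test_normal_area_accounting(self):
        m = build_margin_model(Pathology.NORMAL)
        fluid_area = m.regions[2].shape.area()
        gland_area = m.regions[1].shape.area()
        assert fluid_area == pytest.approx(math.pi * 0.46e-3**2, rel=1e-9)
        assert gland_area == pytest.approx(
            math.pi * (0.5e-3**2 - 0.46e-3**2), rel=1e-9
        )

    def test_adh_ring_thickness_and_dominance(self):
        m = build_margin_model(Pathology.ADH)
        ring = m.regions[1].shape
        assert ring.outer_radius - ring.inner_radius == pytest.approx(0.25e-3)
        # proliferative tissue covers more than half of the duct area
        assert ring.area() > m.regions[2].shape.area()

    def test_dcis_is_a_full_tumor_disk(self):
        m = build_margin_model(Pathology.DCIS, (0.4e-3, 0.0))
        assert len(m.regions) == 2
        disk = m.regions[1].shape
        assert disk.center == (0.4e-3, 0.0)
        assert disk.radius == pytest.approx(DUCT_RADIUS)
        # containment inside the 2 mm block
        assert abs(disk.center[0]) + disk.radius <= DOMAIN_SIZE / 2 + 1e-15

    def test_calcified_models_have_eight_solid_ovals(self):
        for p, mineral in [
            (Pathology.CALC_HAP, "HAp"),
            (Pathology.CALC_CC, "calcium_carbonate"),
            (Pathology.CALC_CO, "calcium_oxalate"),
        ]:
            m = build_margin_model(p)
            solids = [r for r in m.regions if r.physics == "solid"]
            assert len(solids) == 8
            assert all(r.material_label == mineral for r in solids)

    def test_calc_hap_duct_is_tumor_but_benign_ducts_are_fibroadenoma(self):
        assert build_margin_model(Pathology.CALC_HAP).regions[1].material_label == "tumor"
        for p in (Pathology.CALC_CC, Pathology.CALC_CO):
            assert build_margin_model(p).regions[1].material_label == "fibroadenoma"

    def test_offset_violating_containment_rejected(self):
        with pytest.raises(ValueError):
            build_margin_model(Pathology.NORMAL, (0.6e-3, 0.0))

    @pytest.mark.parametrize("pathology", list(Pathology))
    def test_region_structure_invariant_across_standard_offsets(self, pathology):
        ref = build_margin_model(pathology)
        for off in standard_offsets():
            m = build_margin_model(pathology, off)
            assert len(m.regions) == len(ref.regions)
            for a, b in zip(m.regions, ref.regions):
                assert a.shape.area() == pytest.approx(b.shape.area(), rel=1e-12)

    def test_json_serialization_round_trips_key_fields(self, tmp_path):
        import json

        m = build_margin_model(Pathology.CALC_HAP, (0.0, 0.4e-3))
        payload = json.loads(m.to_json())
        assert payload["pathology"] == "calc_hap"
        assert payload["duct_offset"] == [0.0, 0.4e-3]
        assert len(payload["regions"]) == 10


class TestCalcificationLayout:
    def _overlap_brute_force(self, regions):
        shapes = [r.shape for r in regions]
        for i, e1 in enumerate(shapes):
            for e2 in shapes[i + 1:]:
                if e2.contains(e1.boundary_points(512)).any():
                    return True
        return False

    def test_default_layout_eight_separated_ovals_inside_duct(self):
        regs = calcification_layout((0.0, 0.0), DUCT_RADIUS)
        assert len(regs) == 8
        assert not self._overlap_brute_force(regs)
        for r in regs:
            bd = r.shape.boundary_points(512)
            assert np.all(np.hypot(bd[:, 0], bd[:, 1]) < DUCT_RADIUS)

    def test_half_scale_ovals_keep_centers(self):
        cfg = CalcLayoutConfig(semi_axes=(25e-6, 15e-6))
        regs = calcification_layout((0.0, 0.0), DUCT_RADIUS, config=cfg)
        ref = calcification_layout((0.0, 0.0), DUCT_RADIUS)
        assert [r.shape.center for r in regs] != []
        # same grid pitch would shift centers; centers shrink with the gap
        assert len(regs) == len(ref)
        assert not self._overlap_brute_force(regs)

    def test_oversized_ovals_rejected(self):
        cfg = CalcLayoutConfig(semi_axes=(500e-6, 300e-6))
        with pytest.raises(ValueError):
            calcification_layout((0.0, 0.0), DUCT_RADIUS, config=cfg)


class TestPainterStack:
    def test_topmost_region_wins(self):
        m = build_margin_model(Pathology.CALC_HAP)
        # duct center lies in the tumor disk, not in any oval
        labels = m.material_at(np.array([[0.0, 0.0]]))
        assert labels == ["tumor"]
        # an oval center resolves to the mineral
        oval = next(r for r in m.regions if r.physics == "solid")
        labels = m.material_at(np.array([oval.shape.center]))
        assert labels == ["HAp"]
        # far corner is ambient
        labels = m.material_at(np.array([[0.9e-3, 0.9e-3]]))
        assert labels == ["fatty"]

    def test_homogeneous_control_is_all_fatty(self):
        m = homogeneous_control(Pathology.CALC_HAP)
        pts = np.random.default_rng(0).uniform(-1e-3, 1e-3, size=(200, 2))
        assert set(m.material_at(pts)) == {"fatty"}
        assert all(r.physics == "fluid" for r in m.regions)
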