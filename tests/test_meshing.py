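"""Mesh generation: conformity, sizing, quality, PML frame."""

import numpy as np
import pytest

from marginqus.geometry import (
    Pathology,
    build_inclusion_model,
    build_margin_model,
)
from marginqus.materials import builtin_db
from marginqus.meshing import Mesh, generate_mesh, mesh_quality

DB = builtin_db()


@pytest.fixture(scope="module")
def coarse_normal() -> Mesh:
    # 5 MHz keeps the glandular ring resolvable while staying desk-fast
    return generate_mesh(build_margin_model(Pathology.NORMAL), 5e6, 6, db=DB)


@pytest.fixture(scope="module")
def coarse_calc() -> Mesh:
    return generate_mesh(build_margin_model(Pathology.CALC_HAP), 5e6, 6, db=DB)


class TestSizing:
    def test_max_edge_respects_wavelength_rule(self, coarse_normal):
        q = mesh_quality(coarse_normal)
        # ambient cap: c_fatty / f_max / divisor
        assert q.target_edge_per_region[0] == pytest.approx(1422 / 5e6 / 6)
        for r, cap in q.target_edge_per_region.items():
            assert q.max_edge_per_region[r] <= cap * (1 + 1e-12)

    def test_brute_force_max_edge_agrees_with_report(self, coarse_normal):
        m = coarse_normal
        q = mesh_quality(m)
        t = m.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [0, 2]]])
        ln = np.linalg.norm(m.nodes[e[:, 0]] - m.nodes[e[:, 1]], axis=1)
        reg = np.concatenate([m.tri_region] * 3)
        for r in q.max_edge_per_region:
            assert q.max_edge_per_region[r] == pytest.approx(
                float(ln[reg == r].max())
            )

    def test_finer_divisor_gives_more_triangles(self):
        model = build_inclusion_model(0.4e-3, "tumor")
        n6 = len(generate_mesh(model, 4e6, 6, db=DB).triangles)
        n9 = len(generate_mesh(model, 4e6, 9, db=DB).triangles)
        assert n9 > n6

    def test_divisor_out_of_range_rejected(self):
        model = build_inclusion_model(0.4e-3, "tumor")
        with pytest.raises(ValueError):
            generate_mesh(model, 4e6, 5, db=DB)
        with pytest.raises(ValueError):
            generate_mesh(model, 4e6, 13, db=DB)


class TestConformityAndTags:
    def test_min_angle_floor(self, coarse_normal, coarse_calc):
        assert mesh_quality(coarse_normal).min_angle_deg >= 20.0
        assert mesh_quality(coarse_calc).min_angle_deg >= 20.0

    def test_every_triangle_has_a_resolvable_region(self, coarse_calc):
        m = coarse_calc
        assert m.tri_region.min() >= 0
        assert m.tri_region.max() < len(m.model.regions)

    def test_wall_tags_lie_exactly_on_domain_edges(self, coarse_normal):
        m = coarse_normal
        half = m.model.domain_size / 2
        for tag, x0 in (("front_wall", -half), ("back_wall", half)):
            edges = m.boundary_edges[tag]
            assert len(edges) > 0
            nodes = np.unique(edges)
            assert np.max(np.abs(m.nodes[nodes, 0] - x0)) < 1e-12

    def test_wall_tags_span_the_full_edge(self, coarse_normal):
        m = coarse_normal
        half = m.model.domain_size / 2
        for tag in ("front_wall", "back_wall"):
            nodes = np.unique(m.boundary_edges[tag])
            ys = np.sort(m.nodes[nodes, 1])
            assert ys[0] == pytest.approx(-half)
            assert ys[-1] == pytest.approx(half)
            # contiguous: summed edge lengths equal the wall length
            e = m.boundary_edges[tag]
            ln = np.abs(m.nodes[e[:, 0], 1] - m.nodes[e[:, 1], 1]).sum()
            assert ln == pytest.approx(m.model.domain_size)

    def test_interface_loops_are_mesh_edges_on_their_curves(self, coarse_normal):
        m = coarse_normal
        t = np.sort(
            np.vstack([m.triangles[:, [0, 1]], m.triangles[:, [1, 2]],
                       m.triangles[:, [0, 2]]]), axis=1,
        )
        edge_set = set(map(tuple, t))
        assert m.interface_loops
        for _, loop in m.interface_loops:
            for a, b in zip(loop[:-1], loop[1:]):
                assert (min(a, b), max(a, b)) in edge_set

    def test_interface_nodes_lie_on_their_circles(self, coarse_normal):
        m = coarse_normal
        radii = {0.5e-3, 0.46e-3}
        seen = set()
        for _, loop in m.interface_loops:
            r = np.hypot(*m.nodes[loop[:-1]].T)
            assert r.std() < 1e-12
            seen.add(round(float(r.mean()), 9))
        assert seen == {round(r, 9) for r in radii}

    def test_solid_interface_edges_separate_fluid_and_solid(self, coarse_calc):
        m = coarse_calc
        edge_owner: dict[tuple[int, int], list[int]] = {}
        for it, tri in enumerate(m.triangles):
            for a, b in ((0, 1), (1, 2), (0, 2)):
                key = tuple(sorted((tri[a], tri[b])))
                edge_owner.setdefault(key, []).append(it)
        solid = m.tri_is_solid()
        for reg_idx, loop in m.interface_loops:
            if m.model.regions[reg_idx].physics != "solid":
                continue
            for a, b in zip(loop[:-1], loop[1:]):
                owners = edge_owner[tuple(sorted((a, b)))]
                assert len(owners) == 2
                assert sorted(solid[o] for o in owners) == [False, True]


class TestPMLFrame:
    def test_quads_are_axis_aligned_rectangles(self, coarse_normal):
        m = coarse_normal
        c = m.nodes[m.quads]
        w = c.max(axis=1) - c.min(axis=1)
        assert np.all(w > 0)
        # each quad has exactly two distinct x and two distinct y coordinates
        for q in m.quads[:50]:
            xs = np.unique(np.round(m.nodes[q, 0], 15))
            ys = np.unique(np.round(m.nodes[q, 1], 15))
            assert len(xs) == 2 and len(ys) == 2

    def test_frame_thickness_matches_layer_count(self, coarse_normal):
        m = coarse_normal
        half = m.model.domain_size / 2
        outer = np.max(np.abs(m.nodes))
        assert outer == pytest.approx(half + m.pml_layers * m.h_boundary)

    def test_quads_share_boundary_nodes_with_triangles(self, coarse_normal):
        m = coarse_normal
        tri_nodes = set(m.triangles.ravel())
        quad_nodes = set(m.quads.ravel())
        shared = tri_nodes & quad_nodes
        half = m.model.domain_size / 2
        coords = m.nodes[sorted(shared)]
        on_boundary = np.isclose(np.abs(coords), half).any(axis=1)
        assert on_boundary.all()
        assert len(shared) > 0

    def test_vtk_export_smoke(self, coarse_normal, tmp_path):
        p = tmp_path / "mesh.vtk"
        coarse_normal.export_vtk(p)
        head = p.read_text().splitlines()[:5]
        assert head[0].startswith("# vtk")
        assert any("UNSTRUCTURED_GRID" in line for line in head)
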