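"""Interface-conforming triangular meshing with a mapped-quadrilateral PML frame.

The physical 2 mm x 2 mm tissue block is triangulated with a distmesh-style
algorithm: fixed nodes are placed on the square boundary and on every material
interface curve (duct wall, annulus circles, calcification ovals), interior
nodes are seeded on per-region hexagonal lattices and relaxed by a few
spring-force iterations, and the final Delaunay triangulation of the point set
conforms to the interface polylines.  Element sizing is wavelength-resolved:
each region's maximum edge targets ``c_region / f_max / divisor``, where
``c_region`` is the fluid sound speed or, in solids, the smaller of the shear
and longitudinal speeds.

The perfectly-matched-layer frame is a structured grid of axis-aligned
quadrilaterals extruded from the square boundary nodes on all four sides, so
triangle edges and quad edges match node-for-node on the interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .geometry import Curve, EllipseShape, MarginModel
from .materials import MaterialDB, builtin_db

__all__ = ["Mesh", "MeshQualityReport", "generate_mesh", "mesh_quality"]

# PML stretch-direction flags per quad
STRETCH_X, STRETCH_Y, STRETCH_XY = 1, 2, 3


@dataclass
class Mesh:
    """Conforming hybrid mesh: physical triangles plus a PML quad frame.

    ``nodes`` holds corner (P1) coordinates; higher-order nodes are created by
    the solver.  ``boundary_edges`` maps tag names (``front_wall`` at
    x = -L/2, ``back_wall`` at +L/2, ``outer`` on the PML rim) to (E, 2) node
    pairs.  ``interface_loops`` lists, per region index, the closed
    counter-clockwise node loop tracing that region's boundary curve.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    tri_region: np.ndarray
    quads: np.ndarray
    quad_stretch: np.ndarray
    boundary_edges: dict[str, np.ndarray]
    interface_loops: list[tuple[int, np.ndarray]]
    sizes: dict[int, float]
    model: MarginModel
    f_max: float
    divisor: int
    pml_layers: int
    h_boundary: float
    pml_thickness: float

    def tri_is_solid(self) -> np.ndarray:
        solid = np.array(
            [r.physics == "solid" for r in self.model.regions], dtype=bool
        )
        return solid[self.tri_region]

    def export_vtk(self, path: str | Path) -> None:
        """Legacy ASCII VTK export of triangles + quads with region labels."""
        n = len(self.nodes)
        cells = []
        for t in self.triangles:
            cells.append((5, list(t)))
        for q in self.quads:
            cells.append((9, list(q)))
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\nmarginqus mesh\nASCII\n")
            fh.write("DATASET UNSTRUCTURED_GRID\n")
            fh.write(f"POINTS {n} double\n")
            for x, y in self.nodes:
                fh.write(f"{x:.9e} {y:.9e} 0.0\n")
            total = sum(len(c[1]) + 1 for c in cells)
            fh.write(f"CELLS {len(cells)} {total}\n")
            for _, conn in cells:
                fh.write(f"{len(conn)} " + " ".join(map(str, conn)) + "\n")
            fh.write(f"CELL_TYPES {len(cells)}\n")
            for ctype, _ in cells:
                fh.write(f"{ctype}\n")
            fh.write(f"CELL_DATA {len(cells)}\nSCALARS region int 1\n")
            fh.write("LOOKUP_TABLE default\n")
            for r in self.tri_region:
                fh.write(f"{r}\n")
            for _ in self.quads:
                fh.write("-1\n")


@dataclass(frozen=True)
class MeshQualityReport:
    n_triangles: int
    n_quads: int
    n_nodes: int
    min_angle_deg: float
    max_edge_per_region: dict[int, float]
    target_edge_per_region: dict[int, float]


class MeshingError(RuntimeError):
    pass


def _region_sizes(model: MarginModel, db: MaterialDB, f_max: float, divisor: int):
    sizes: dict[int, float] = {}
    for i, reg in enumerate(model.regions):
        mat = db.material(reg.material_label)
        if reg.physics == "solid":
            c = min(mat.shear_speed, mat.longitudinal_speed)
        else:
            c = mat.sound_speed
        sizes[i] = c / f_max / divisor
    return sizes


def _h_at(model: MarginModel, sizes: dict[int, float], pts: np.ndarray) -> np.ndarray:
    idx = model.region_at(pts)
    return np.array([sizes[i] for i in idx])


def _curve_spacing(model, sizes, curve: Curve) -> float:
    """Point spacing on an interface curve: min of the sizes on either side."""
    # probe just inside and outside along the normal at a few angles
    pts = curve.sample(16)
    ctr = np.asarray(curve.center)
    nrm = pts - ctr
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    eps = 1e-7
    h_in = _h_at(model, sizes, pts - eps * nrm)
    h_out = _h_at(model, sizes, pts + eps * nrm)
    return float(min(h_in.min(), h_out.min()))


def generate_mesh(
    model: MarginModel,
    f_max: float,
    wavelength_divisor: int,
    db: MaterialDB | None = None,
    pml_layers: int = 8,
    smooth_iters: int = 30,
) -> Mesh:
    """Generate the hybrid triangle/PML-quad mesh for one margin model.

    ``wavelength_divisor`` is the elements-per-wavelength target (6-12); the
    mesh is built at ``f_max`` and reused for every lower frequency of a sweep.
    """
    if not 6 <= wavelength_divisor <= 12:
        raise ValueError(f"wavelength_divisor must be in 6..12, got {wavelength_divisor}")
    if f_max <= 0:
        raise ValueError("f_max must be positive")
    db = db or builtin_db()
    L = model.domain_size
    half = L / 2
    caps = _region_sizes(model, db, f_max, wavelength_divisor)
    # generate against a slightly smaller size so the stated cap is a true
    # maximum after relaxation; small solid inclusions are never sized coarser
    # than their own minor dimension
    sizes = {}
    for i, reg in enumerate(model.regions):
        h = caps[i] / 1.15
        if reg.physics == "solid" and isinstance(reg.shape, EllipseShape):
            h = min(h, 0.8 * min(reg.shape.semi_axes))
        sizes[i] = h
    h_amb = sizes[0]

    # --- fixed nodes: square boundary ------------------------------------
    n_side = int(math.ceil(L / h_amb))
    hb = L / n_side
    s = np.linspace(-half, half, n_side + 1)
    bottom = np.column_stack([s[:-1], np.full(n_side, -half)])
    right = np.column_stack([np.full(n_side, half), s[:-1]])
    top = np.column_stack([s[::-1][:-1], np.full(n_side, half)])
    left = np.column_stack([np.full(n_side, -half), s[::-1][:-1]])
    square_pts = np.vstack([bottom, right, top, left])  # CCW, corners once
    # helper nodes filling the corner gap left by the interior-point inset
    ci = half - 0.55 * hb
    corner_helpers = np.array([[sx * ci, sy * ci] for sx in (-1, 1) for sy in (-1, 1)])

    # --- fixed nodes: interface curves -----------------------------------
    curves = model.interface_curves()
    curve_pts: list[np.ndarray] = []
    curve_slices: list[slice] = []
    dense_samples: list[np.ndarray] = []
    dense_clearance: list[np.ndarray] = []
    start = len(square_pts)
    # choose point counts; thin annuli (ring gap below the local cap) get
    # phase-aligned, equal-count sampling on both circles with the tangential
    # spacing constrained so ring-crossing diagonals stay under the cap
    npts_of: dict[int, int] = {}
    for i, c in enumerate(curves):
        sp = 0.85 * _curve_spacing(model, sizes, c)
        npts_of[i] = max(12, int(math.ceil(c.length() / sp)))
    for i, ci in enumerate(curves):
        for j, cj in enumerate(curves[i + 1:], start=i + 1):
            if ci.kind != "circle" or cj.kind != "circle":
                continue
            if not np.allclose(ci.center, cj.center, atol=1e-12):
                continue
            ri, rj = ci.params[0], cj.params[0]
            gap = abs(ri - rj)
            rm = 0.5 * (ri + rj)
            mid = (ci.center[0] + rm, ci.center[1])
            cap = float(_h_at(model, sizes, np.array([mid]))[0]) * 1.15  # true cap
            if gap >= cap:
                continue
            sp_t = 0.95 * math.sqrt(max(cap**2 - gap**2, (0.4 * cap) ** 2))
            n = max(12, int(math.ceil(max(ci.length(), cj.length()) / sp_t)))
            npts_of[i] = npts_of[j] = max(npts_of[i], npts_of[j], n)
    for i, c in enumerate(curves):
        npts = npts_of[i]
        pts = c.sample(npts)
        curve_pts.append(pts)
        curve_slices.append(slice(start, start + npts))
        start += npts
        dense = c.sample(8 * npts)
        dense_samples.append(dense)
        # clearance keeping interface chords Delaunay-stable
        dense_clearance.append(np.full(len(dense), 0.58 * c.length() / npts))
    fixed = np.vstack([square_pts] + curve_pts + [corner_helpers])
    n_fixed = len(fixed)

    # --- interior seed points: per-size hexagonal lattices ----------------
    # lattice pitch below the per-region cap so relaxed edges stay within it
    seeds = []
    for h_cap in sorted(set(sizes.values())):
        h = 0.85 * h_cap
        dy = h * math.sqrt(3) / 2
        ny = int(math.ceil(L / dy))
        nx = int(math.ceil(L / h)) + 1
        ys = -half + dy * (np.arange(ny) + 0.5)
        grid = []
        for j, y in enumerate(ys):
            xs = -half + h * (np.arange(nx) + (0.25 if j % 2 else 0.75))
            xs = xs[xs < half - 0.2 * h]
            grid.append(np.column_stack([xs, np.full(len(xs), y)]))
        pts = np.vstack(grid)
        keep = np.isclose(_h_at(model, sizes, pts), h_cap)
        seeds.append(pts[keep])
    interior = np.vstack(seeds)

    # drop seeds crowding the fixed nodes
    tree = cKDTree(fixed)
    d, _ = tree.query(interior, k=1)
    h_loc = 0.85 * _h_at(model, sizes, interior)
    interior = interior[d > 0.5 * h_loc]

    # --- spring relaxation (distmesh-style, deterministic) ----------------
    pts = np.vstack([fixed, interior])
    n_pts = len(pts)
    free = np.zeros(n_pts, dtype=bool)
    free[n_fixed:] = True

    def _edges(tri: Delaunay) -> np.ndarray:
        e = np.vstack(
            [tri.simplices[:, [0, 1]], tri.simplices[:, [1, 2]], tri.simplices[:, [0, 2]]]
        )
        e.sort(axis=1)
        return np.unique(e, axis=0)

    tri = Delaunay(pts)
    for it in range(smooth_iters):
        if it % 5 == 0 and it > 0:
            tri = Delaunay(pts)
        e = _edges(tri)
        vec = pts[e[:, 1]] - pts[e[:, 0]]
        ln = np.linalg.norm(vec, axis=1)
        mid = 0.5 * (pts[e[:, 0]] + pts[e[:, 1]])
        l0 = 1.02 * _h_at(model, sizes, mid) * 0.85
        f = np.maximum(l0 - ln, 0.0) / np.maximum(ln, 1e-30)
        fv = f[:, None] * vec
        force = np.zeros_like(pts)
        np.add.at(force, e[:, 0], -fv)
        np.add.at(force, e[:, 1], fv)
        pts[free] += 0.2 * force[free]
        # keep interior points strictly inside the square
        m = 0.3 * hb
        pts[free, 0] = np.clip(pts[free, 0], -half + m, half - m)
        pts[free, 1] = np.clip(pts[free, 1], -half + m, half - m)

    # remove interior points that ended up nearly coincident
    tree = cKDTree(pts[: n_fixed])
    d, _ = tree.query(pts[n_fixed:], k=1)
    h_loc = _h_at(model, sizes, pts[n_fixed:])
    keep = d > 0.35 * h_loc
    pts = np.vstack([pts[:n_fixed], pts[n_fixed:][keep]])

    if dense_samples:
        dense_all = np.vstack(dense_samples)
        clear_all = np.concatenate(dense_clearance)
        dense_tree = cKDTree(dense_all)
    else:
        dense_tree = None

    def _repel_from_fixed(pts: np.ndarray) -> np.ndarray:
        """Keep free nodes clear of the interface polylines (measured as
        distance to a dense curve resampling) so the chords stay Delaunay."""
        if dense_tree is None:
            return pts
        d, j = dense_tree.query(pts[n_fixed:], k=1)
        close = d < clear_all[j]
        if close.any():
            src = pts[n_fixed:][close]
            anchor = dense_all[j[close]]
            vec = src - anchor
            nrm = np.linalg.norm(vec, axis=1, keepdims=True)
            nrm[nrm < 1e-30] = 1e-30
            pts[n_fixed:][close] = anchor + vec / nrm * clear_all[j[close]][:, None]
        return pts

    def _laplacian(pts: np.ndarray, rounds: int) -> np.ndarray:
        for _ in range(rounds):
            tri_l = Delaunay(pts)
            e = _edges(tri_l)
            acc = np.zeros_like(pts)
            cnt = np.zeros(len(pts))
            np.add.at(acc, e[:, 0], pts[e[:, 1]])
            np.add.at(acc, e[:, 1], pts[e[:, 0]])
            np.add.at(cnt, e[:, 0], 1)
            np.add.at(cnt, e[:, 1], 1)
            target = acc / np.maximum(cnt, 1)[:, None]
            pts[n_fixed:] += 0.5 * (target[n_fixed:] - pts[n_fixed:])
            pts = _repel_from_fixed(pts)
            m = 0.3 * hb
            pts[n_fixed:, 0] = np.clip(pts[n_fixed:, 0], -half + m, half - m)
            pts[n_fixed:, 1] = np.clip(pts[n_fixed:, 1], -half + m, half - m)
        return pts

    def _merge_crowded(pts: np.ndarray) -> np.ndarray:
        """Drop free nodes that sit closer than ~0.45 h to another node."""
        free_pts = pts[n_fixed:]
        h_loc = _h_at(model, sizes, free_pts)
        tree = cKDTree(pts)
        pairs = tree.query_pairs(0.45 * h_loc.max(), output_type="ndarray")
        drop = np.zeros(len(pts), dtype=bool)
        if len(pairs):
            d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
            hh = np.full(len(pts), np.inf)
            hh[n_fixed:] = h_loc
            lim = 0.45 * np.minimum(hh[pairs[:, 0]], hh[pairs[:, 1]])
            for a, b in pairs[d < lim]:
                victim = b if b >= n_fixed else a
                if victim >= n_fixed and not (drop[a] or drop[b]):
                    drop[victim] = True
        return pts[~drop]

    # enforce the per-region edge cap: smooth, then split any oversized edge
    for _ in range(4):
        pts = _laplacian(pts, 2)
        pts = _merge_crowded(pts)
        tri = Delaunay(pts)
        e = _edges(tri)
        ln = np.linalg.norm(pts[e[:, 1]] - pts[e[:, 0]], axis=1)
        mid = 0.5 * (pts[e[:, 0]] + pts[e[:, 1]])
        cap = _h_at(model, sizes, mid)
        long = ln > 0.90 * cap
        if not long.any():
            break
        new = mid[long]
        # never crowd the fixed boundary nodes or the interface curves
        d, _ = cKDTree(pts[:n_fixed]).query(new, k=1)
        new = new[d > 0.4 * _h_at(model, sizes, new)]
        if len(new) and dense_tree is not None:
            d, j = dense_tree.query(new, k=1)
            new = new[d > clear_all[j]]
        if len(new) == 0:
            break
        pts = np.vstack([pts, new])
    pts = _laplacian(pts, 2)
    pts = _merge_crowded(pts)
    pts = _laplacian(pts, 1)

    tri = Delaunay(pts)
    simplices = tri.simplices.copy()

    # enforce counter-clockwise triangles
    v1 = pts[simplices[:, 1]] - pts[simplices[:, 0]]
    v2 = pts[simplices[:, 2]] - pts[simplices[:, 0]]
    det = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    flip = det < 0
    simplices[flip] = simplices[flip][:, [0, 2, 1]]

    centroids = pts[simplices].mean(axis=1)
    tri_region = model.region_at(centroids)

    # --- conformity: every interface segment must be a mesh edge ----------
    edge_set = set(map(tuple, np.sort(
        np.vstack([simplices[:, [0, 1]], simplices[:, [1, 2]], simplices[:, [0, 2]]]),
        axis=1,
    )))
    interface_loops: list[tuple[int, np.ndarray]] = []
    curve_owner: dict[int, int] = {}
    for ireg, reg in enumerate(model.regions):
        for c in reg.shape.boundary_curves():
            for ic, cc in enumerate(curves):
                if cc == c:
                    curve_owner[ic] = ireg
    missing = 0
    for ic, sl in enumerate(curve_slices):
        ids = np.arange(sl.start, sl.stop)
        loop = np.append(ids, ids[0])
        for a, b in zip(loop[:-1], loop[1:]):
            if (min(a, b), max(a, b)) not in edge_set:
                missing += 1
        interface_loops.append((curve_owner.get(ic, -1), loop))
    if missing:
        raise MeshingError(
            f"{missing} interface segments are not triangulation edges; "
            "the point distribution failed to conform"
        )

    # --- PML frame ---------------------------------------------------------
    pml_t = pml_layers * hb
    ext = hb * np.arange(1, pml_layers + 1)
    xs_in = s  # boundary coordinates along each side
    x_all = np.concatenate([(-half - ext)[::-1], xs_in, half + ext])
    node_id: dict[tuple[int, int], int] = {}
    new_nodes: list[tuple[float, float]] = []
    n_base = len(pts)

    def _nid(i: int, j: int) -> int:
        x, y = x_all[i], x_all[j]
        inside = (abs(x) <= half + 1e-15) and (abs(y) <= half + 1e-15)
        if inside:
            # must be one of the fixed square-boundary nodes
            on_b = (abs(abs(x) - half) < 1e-15) or (abs(abs(y) - half) < 1e-15)
            if not on_b:
                raise MeshingError("internal PML node landed inside the domain")
            d2 = (square_pts[:, 0] - x) ** 2 + (square_pts[:, 1] - y) ** 2
            return int(np.argmin(d2))
        key = (i, j)
        if key not in node_id:
            node_id[key] = n_base + len(new_nodes)
            new_nodes.append((x, y))
        return node_id[key]

    nl = pml_layers
    ni = len(x_all) - 1  # cells per row
    quads = []
    stretch = []
    for i in range(ni):
        for j in range(ni):
            xm = 0.5 * (x_all[i] + x_all[i + 1])
            ym = 0.5 * (x_all[j] + x_all[j + 1])
            out_x = abs(xm) > half
            out_y = abs(ym) > half
            if not (out_x or out_y):
                continue
            quads.append(
                (_nid(i, j), _nid(i + 1, j), _nid(i + 1, j + 1), _nid(i, j + 1))
            )
            stretch.append(
                STRETCH_XY if (out_x and out_y) else (STRETCH_X if out_x else STRETCH_Y)
            )
    nodes = np.vstack([pts, np.array(new_nodes)]) if new_nodes else pts
    quads = np.array(quads, dtype=int)
    quad_stretch = np.array(stretch, dtype=int)

    # --- boundary edge tags -------------------------------------------------
    def _wall_edges(side: str) -> np.ndarray:
        if side in ("front", "back"):
            x0 = -half if side == "front" else half
            mask = np.abs(square_pts[:, 0] - x0) < 1e-15
        else:
            y0 = -half if side == "bottom" else half
            mask = np.abs(square_pts[:, 1] - y0) < 1e-15
        ids = np.where(mask)[0]
        coord = square_pts[ids, 1] if side in ("front", "back") else square_pts[ids, 0]
        order = np.argsort(coord)
        ids = ids[order]
        return np.column_stack([ids[:-1], ids[1:]])

    outer_lo = abs(x_all[0])
    outer_ids = [
        idx
        for (i, j), idx in node_id.items()
        if abs(abs(x_all[i]) - outer_lo) < 1e-15 or abs(abs(x_all[j]) - outer_lo) < 1e-15
    ]
    outer_edges = np.array([[i, i] for i in outer_ids], dtype=int)  # node list form

    boundary_edges = {
        "front_wall": _wall_edges("front"),
        "back_wall": _wall_edges("back"),
        "bottom_wall": _wall_edges("bottom"),
        "top_wall": _wall_edges("top"),
        "outer": outer_edges,
    }

    return Mesh(
        nodes=nodes,
        triangles=simplices,
        tri_region=tri_region,
        quads=quads,
        quad_stretch=quad_stretch,
        boundary_edges=boundary_edges,
        interface_loops=interface_loops,
        sizes=caps,
        model=model,
        f_max=f_max,
        divisor=wavelength_divisor,
        pml_layers=pml_layers,
        h_boundary=hb,
        pml_thickness=pml_t,
    )


def mesh_quality(mesh: Mesh) -> MeshQualityReport:
    """Min-angle and per-region max-edge report for a generated mesh."""
    p = mesh.nodes
    t = mesh.triangles
    a, b, c = p[t[:, 0]], p[t[:, 1]], p[t[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    angles = []
    for opp, e1, e2 in ((la, lb, lc), (lb, la, lc), (lc, la, lb)):
        cosv = np.clip((e1**2 + e2**2 - opp**2) / (2 * e1 * e2), -1, 1)
        angles.append(np.degrees(np.arccos(cosv)))
    min_angle = float(np.min(angles))
    max_edge = {}
    lens = np.maximum(np.maximum(la, lb), lc)
    for r in np.unique(mesh.tri_region):
        max_edge[int(r)] = float(lens[mesh.tri_region == r].max())
    return MeshQualityReport(
        n_triangles=len(t),
        n_quads=len(mesh.quads),
        n_nodes=len(p),
        min_angle_deg=min_angle,
        max_edge_per_region=max_edge,
        target_edge_per_region=dict(mesh.sizes),
    )
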