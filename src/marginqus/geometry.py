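"""Parametric 2D surgical-margin phantoms.

Each phantom is a 2 mm x 2 mm block of fatty tissue containing one breast duct
(1 mm diameter) in one of six pathological states:

* ``NORMAL`` — duct fluid core (radius 0.46 mm) lined by a 40 um glandular
  epithelial layer (two 20 um cell layers);
* ``ADH`` — atypical ductal hyperplasia: the epithelium proliferates to half the
  duct radius (0.25 mm ring of tumor tissue) around a shrunken fluid core;
* ``DCIS`` — ductal carcinoma in situ: the duct completely filled with tumor tissue;
* ``CALC_HAP`` — the DCIS duct carrying two clusters of oval hydroxyapatite
  microcalcifications (malignancy-associated mineral);
* ``CALC_CC`` / ``CALC_CO`` — a fibroadenoma-filled (benign) duct carrying calcium
  carbonate / calcium oxalate clusters.

Regions form a painter's stack: later regions override earlier ones wherever they
overlap, so annuli and disks need no boolean subtraction.  The duct can be offset
from the block center to create computational variation (five standard positions).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path


import numpy as np

__all__ = [
    "Pathology",
    "Disk",
    "Annulus",
    "EllipseShape",
    "RectShape",
    "Region",
    "MarginModel",
    "CalcLayoutConfig",
    "DOMAIN_SIZE",
    "DUCT_RADIUS",
    "standard_offsets",
    "build_margin_model",
    "calcification_layout",
    "homogeneous_control",
]

# All lengths SI (meters).
DOMAIN_SIZE = 2.0e-3          # side of the square fatty-tissue block
DUCT_RADIUS = 0.5e-3          # duct radius (1 mm diameter)
GLANDULAR_THICKNESS = 40.0e-6  # two 20 um epithelial cell layers
ADH_RING_THICKNESS = 0.25e-3   # half the duct radius
STANDARD_OFFSET = 0.4e-3       # duct displacement for off-center positions


class Pathology(Enum):
    NORMAL = "normal"
    ADH = "adh"
    DCIS = "dcis"
    CALC_HAP = "calc_hap"
    CALC_CC = "calc_cc"
    CALC_CO = "calc_co"


# ---------------------------------------------------------------------------
# shape primitives


@dataclass(frozen=True)
class RectShape:
    """Axis-aligned rectangle given by center and full side lengths."""

    center: tuple[float, float]
    width: float
    height: float

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("rectangle dimensions must be positive")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        cx, cy = self.center
        return (np.abs(pts[:, 0] - cx) <= self.width / 2) & (
            np.abs(pts[:, 1] - cy) <= self.height / 2
        )

    def area(self) -> float:
        return self.width * self.height

    def boundary_curves(self) -> list["Curve"]:
        return []  # the domain boundary is handled by the mesher


@dataclass(frozen=True)
class Disk:
    center: tuple[float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("disk radius must be positive")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d2 = (pts[:, 0] - self.center[0]) ** 2 + (pts[:, 1] - self.center[1]) ** 2
        return d2 <= self.radius**2

    def area(self) -> float:
        return math.pi * self.radius**2

    def boundary_curves(self) -> list["Curve"]:
        return [Curve.circle(self.center, self.radius)]


@dataclass(frozen=True)
class Annulus:
    center: tuple[float, float]
    outer_radius: float
    inner_radius: float

    def __post_init__(self):
        if not 0 < self.inner_radius < self.outer_radius:
            raise ValueError("annulus requires 0 < inner_radius < outer_radius")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d2 = (pts[:, 0] - self.center[0]) ** 2 + (pts[:, 1] - self.center[1]) ** 2
        return (d2 <= self.outer_radius**2) & (d2 >= self.inner_radius**2)

    def area(self) -> float:
        return math.pi * (self.outer_radius**2 - self.inner_radius**2)

    def boundary_curves(self) -> list["Curve"]:
        return [
            Curve.circle(self.center, self.outer_radius),
            Curve.circle(self.center, self.inner_radius),
        ]


@dataclass(frozen=True)
class EllipseShape:
    """Ellipse with semi-axes ``(a, b)`` rotated by ``rotation`` radians."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float = 0.0

    def __post_init__(self):
        if self.semi_axes[0] <= 0 or self.semi_axes[1] <= 0:
            raise ValueError("ellipse semi-axes must be positive")

    def _local(self, pts: np.ndarray) -> np.ndarray:
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        dx = pts[:, 0] - self.center[0]
        dy = pts[:, 1] - self.center[1]
        return np.column_stack([c * dx + s * dy, -s * dx + c * dy])

    def contains(self, pts: np.ndarray) -> np.ndarray:
        loc = self._local(pts)
        a, b = self.semi_axes
        return (loc[:, 0] / a) ** 2 + (loc[:, 1] / b) ** 2 <= 1.0

    def area(self) -> float:
        return math.pi * self.semi_axes[0] * self.semi_axes[1]

    def boundary_points(self, n: int = 256) -> np.ndarray:
        t = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
        a, b = self.semi_axes
        x, y = a * np.cos(t), b * np.sin(t)
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        return np.column_stack(
            [self.center[0] + c * x - s * y, self.center[1] + s * x + c * y]
        )

    def boundary_curves(self) -> list["Curve"]:
        return [Curve.ellipse(self.center, self.semi_axes, self.rotation)]


@dataclass(frozen=True)
class Curve:
    """A closed parametric boundary curve, sampled on demand by the mesher."""

    kind: str  # "circle" | "ellipse"
    center: tuple[float, float]
    params: tuple[float, ...]

    @classmethod
    def circle(cls, center, radius) -> "Curve":
        return cls("circle", tuple(center), (float(radius),))

    @classmethod
    def ellipse(cls, center, semi_axes, rotation) -> "Curve":
        return cls("ellipse", tuple(center), (semi_axes[0], semi_axes[1], rotation))

    def length(self) -> float:
        if self.kind == "circle":
            return 2 * math.pi * self.params[0]
        a, b, _ = self.params
        # Ramanujan approximation, ample for choosing a point count
        h = ((a - b) / (a + b)) ** 2
        return math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))

    def sample(self, n: int) -> np.ndarray:
        t = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
        if self.kind == "circle":
            r = self.params[0]
            return np.column_stack(
                [self.center[0] + r * np.cos(t), self.center[1] + r * np.sin(t)]
            )
        a, b, rot = self.params
        x, y = a * np.cos(t), b * np.sin(t)
        c, s = math.cos(rot), math.sin(rot)
        return np.column_stack(
            [self.center[0] + c * x - s * y, self.center[1] + s * x + c * y]
        )


Shape = RectShape | Disk | Annulus | EllipseShape


# ---------------------------------------------------------------------------
# regions and models


@dataclass(frozen=True)
class Region:
    """A shaped patch of one material with one physics."""

    shape: Shape
    material_label: str
    physics: str  # "fluid" | "solid"

    def __post_init__(self):
        if self.physics not in ("fluid", "solid"):
            raise ValueError(f"physics must be 'fluid' or 'solid', got {self.physics}")


@dataclass(frozen=True)
class MarginModel:
    """One pathology phantom: an ordered painter's stack of regions.

    ``regions[0]`` is the ambient fatty block; later regions override earlier
    ones where they overlap.
    """

    pathology: Pathology
    domain_size: float
    duct_offset: tuple[float, float]
    regions: tuple[Region, ...]
    ambient_material: str = "fatty"

    def __post_init__(self):
        if not self.regions:
            raise ValueError("region list must be nonempty")

    @property
    def duct_center(self) -> tuple[float, float]:
        return self.duct_offset

    def region_at(self, pts: np.ndarray) -> np.ndarray:
        """Index (into ``regions``) of the topmost region containing each point."""
        pts = np.atleast_2d(pts)
        idx = np.zeros(len(pts), dtype=int)
        for i, reg in enumerate(self.regions):
            idx[reg.shape.contains(pts)] = i
        return idx

    def material_at(self, pts: np.ndarray) -> list[str]:
        return [self.regions[i].material_label for i in self.region_at(pts)]

    def interface_curves(self) -> list[Curve]:
        curves: list[Curve] = []
        for reg in self.regions:
            curves.extend(reg.shape.boundary_curves())
        # deduplicate identical curves (e.g. annulus inner circle == disk boundary)
        seen: dict[tuple, Curve] = {}
        for c in curves:
            key = (c.kind, tuple(np.round(c.center, 12)), tuple(np.round(c.params, 12)))
            seen.setdefault(key, c)
        return list(seen.values())

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        def shape_dict(s: Shape) -> dict:
            d = {"type": type(s).__name__}
            d.update({k: getattr(s, k) for k in s.__dataclass_fields__})
            return d

        payload = {
            "pathology": self.pathology.value,
            "domain_size": self.domain_size,
            "duct_offset": list(self.duct_offset),
            "ambient_material": self.ambient_material,
            "regions": [
                {
                    "shape": shape_dict(r.shape),
                    "material": r.material_label,
                    "physics": r.physics,
                }
                for r in self.regions
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# construction


def standard_offsets() -> list[tuple[float, float]]:
    """The five standard duct positions: centered and +/-0.4 mm along each axis."""
    d = STANDARD_OFFSET
    return [(0.0, 0.0), (d, 0.0), (-d, 0.0), (0.0, d), (0.0, -d)]


@dataclass(frozen=True)
class CalcLayoutConfig:
    """Layout of the microcalcification clusters inside the duct.

    Two clusters sit symmetrically about the duct center on the horizontal axis
    at ``+/- cluster_offset_fraction * duct_radius``; each holds ``grid`` ovals
    with the given semi-axes, separated edge-to-edge by ``gap``.
    """

    semi_axes: tuple[float, float] = (50.0e-6, 30.0e-6)
    gap: float = 30.0e-6
    grid: tuple[int, int] = (2, 2)
    cluster_offset_fraction: float = 0.5
    rotation: float = 0.0


def calcification_layout(
    duct_center: tuple[float, float],
    duct_radius: float,
    material_label: str = "HAp",
    config: CalcLayoutConfig | None = None,
) -> list[Region]:
    """Deterministic oval-microcalcification layout for one duct.

    Raises ``ValueError`` if any oval protrudes beyond the duct (clearance of at
    least one minor semi-axis is required) or if ovals overlap.
    """
    cfg = config or CalcLayoutConfig()
    a, b = cfg.semi_axes
    nx, ny = cfg.grid
    dx = 2 * a + cfg.gap
    dy = 2 * b + cfg.gap
    cluster_xs = (
        -cfg.cluster_offset_fraction * duct_radius,
        +cfg.cluster_offset_fraction * duct_radius,
    )
    ellipses: list[EllipseShape] = []
    for cx in cluster_xs:
        x0 = cx - dx * (nx - 1) / 2
        y0 = -dy * (ny - 1) / 2
        for i in range(nx):
            for j in range(ny):
                ellipses.append(
                    EllipseShape(
                        center=(duct_center[0] + x0 + i * dx, duct_center[1] + y0 + j * dy),
                        semi_axes=(a, b),
                        rotation=cfg.rotation,
                    )
                )

    clearance = min(a, b)
    for e in ellipses:
        bd = e.boundary_points(256)
        r = np.hypot(bd[:, 0] - duct_center[0], bd[:, 1] - duct_center[1])
        if r.max() > duct_radius - clearance:
            raise ValueError(
                "calcification layout protrudes beyond the duct "
                f"(max radius {r.max():.3e} vs allowed {duct_radius - clearance:.3e})"
            )
    for i, e1 in enumerate(ellipses):
        for e2 in ellipses[i + 1 :]:
            if e2.contains(e1.boundary_points(256)).any() or e2.contains(
                np.array([e1.center])
            ):
                raise ValueError("calcification ovals overlap")

    return [Region(e, material_label, "solid") for e in ellipses]


_CALC_MINERAL = {
    Pathology.CALC_HAP: "HAp",
    Pathology.CALC_CC: "calcium_carbonate",
    Pathology.CALC_CO: "calcium_oxalate",
}


def build_margin_model(
    pathology: Pathology,
    duct_offset: tuple[float, float] = (0.0, 0.0),
    calc_config: CalcLayoutConfig | None = None,
) -> MarginModel:
    """Build one surgical-margin phantom at the given duct offset."""
    off = (float(duct_offset[0]), float(duct_offset[1]))
    if math.hypot(*off) + DUCT_RADIUS > DOMAIN_SIZE / 2 + 1e-15:
        raise ValueError(
            f"duct at offset {off} protrudes beyond the {DOMAIN_SIZE:.1e} m block"
        )

    ambient = Region(
        RectShape((0.0, 0.0), DOMAIN_SIZE, DOMAIN_SIZE), "fatty", "fluid"
    )
    regions: list[Region] = [ambient]

    if pathology is Pathology.NORMAL:
        regions.append(
            Region(
                Annulus(off, DUCT_RADIUS, DUCT_RADIUS - GLANDULAR_THICKNESS),
                "glandular",
                "fluid",
            )
        )
        regions.append(
            Region(Disk(off, DUCT_RADIUS - GLANDULAR_THICKNESS), "duct_fluid", "fluid")
        )
    elif pathology is Pathology.ADH:
        regions.append(
            Region(
                Annulus(off, DUCT_RADIUS, DUCT_RADIUS - ADH_RING_THICKNESS),
                "tumor",
                "fluid",
            )
        )
        regions.append(
            Region(Disk(off, DUCT_RADIUS - ADH_RING_THICKNESS), "duct_fluid", "fluid")
        )
    elif pathology is Pathology.DCIS:
        regions.append(Region(Disk(off, DUCT_RADIUS), "tumor", "fluid"))
    elif pathology in _CALC_MINERAL:
        duct_tissue = "tumor" if pathology is Pathology.CALC_HAP else "fibroadenoma"
        regions.append(Region(Disk(off, DUCT_RADIUS), duct_tissue, "fluid"))
        regions.extend(
            calcification_layout(off, DUCT_RADIUS, _CALC_MINERAL[pathology], calc_config)
        )
    else:  # pragma: no cover
        raise ValueError(f"unknown pathology {pathology}")

    return MarginModel(
        pathology=pathology,
        domain_size=DOMAIN_SIZE,
        duct_offset=off,
        regions=tuple(regions),
    )


def build_inclusion_model(
    radius: float,
    material_label: str,
    physics: str = "fluid",
    domain_size: float = DOMAIN_SIZE,
    center: tuple[float, float] = (0.0, 0.0),
) -> MarginModel:
    """A single centered circular inclusion in a fatty block.

    This is the benchmark geometry matched by the analytic cylinder-scattering
    series; ``domain_size`` is adjustable so absorbing-layer placement can be
    varied with the scatterer fixed.
    """
    regions = (
        Region(RectShape((0.0, 0.0), domain_size, domain_size), "fatty", "fluid"),
        Region(Disk(center, radius), material_label, physics),
    )
    return MarginModel(
        pathology=Pathology.DCIS,
        domain_size=domain_size,
        duct_offset=center,
        regions=regions,
    )


def homogeneous_control(
    pathology: Pathology = Pathology.NORMAL,
    duct_offset: tuple[float, float] = (0.0, 0.0),
) -> MarginModel:
    """A zero-contrast control: the phantom's geometry with every region fatty fluid.

    The scattered field of this model is identically zero, which makes it the
    null case for solver verification.
    """
    model = build_margin_model(pathology, duct_offset)
    regions = tuple(
        replace(r, material_label="fatty", physics="fluid") for r in model.regions
    )
    return replace(model, regions=regions)
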