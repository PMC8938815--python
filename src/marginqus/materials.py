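"""Acoustic and elastic material properties of breast tissue and microcalcification minerals.

Soft tissues and duct fluid are modelled as lossy acoustic fluids characterised by
density, sound speed and a frequency-linear attenuation coefficient in Np/(m MHz).
Microcalcification minerals are linear isotropic elastic solids characterised by
density, Young's modulus and Poisson's ratio (lossless: no solid damping is modelled).

The built-in database carries the literature values used throughout the margin
phantoms: five fluids (fatty, glandular, tumor, fibroadenoma, duct fluid) and three
minerals (hydroxyapatite, calcium carbonate, calcium oxalate).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Union

__all__ = [
    "FluidMaterial",
    "SolidMaterial",
    "MaterialDB",
    "builtin_db",
    "complex_wavenumber",
    "lame_constants",
]


@dataclass(frozen=True)
class FluidMaterial:
    """A lossy acoustic fluid.

    Parameters
    ----------
    name
        Label used by geometry regions.
    density
        Mass density in kg/m^3.
    sound_speed
        Longitudinal sound speed in m/s.
    attenuation
        Attenuation coefficient in Np/(m MHz); amplitude decays as
        ``exp(-attenuation * f_MHz * distance)``.
    """

    name: str
    density: float
    sound_speed: float
    attenuation: float

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        if self.sound_speed <= 0:
            raise ValueError(f"sound_speed must be positive, got {self.sound_speed}")
        if self.attenuation < 0:
            raise ValueError(f"attenuation must be nonnegative, got {self.attenuation}")


@dataclass(frozen=True)
class SolidMaterial:
    """A linear isotropic elastic solid (lossless)."""

    name: str
    density: float
    sound_speed: float
    youngs_modulus: float
    poisson_ratio: float

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        if self.youngs_modulus <= 0:
            raise ValueError("youngs_modulus must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ValueError(
                f"poisson_ratio must lie in [0, 0.5), got {self.poisson_ratio}"
            )

    @property
    def shear_speed(self) -> float:
        """Shear (transverse) wave speed sqrt(mu/rho) in m/s."""
        _, mu = lame_constants(self)
        return math.sqrt(mu / self.density)

    @property
    def longitudinal_speed(self) -> float:
        """Bulk longitudinal wave speed sqrt((lambda + 2 mu)/rho) in m/s."""
        lam, mu = lame_constants(self)
        return math.sqrt((lam + 2.0 * mu) / self.density)


@dataclass(frozen=True)
class MaterialDB:
    """Lookup of fluid and solid materials by label."""

    fluids: dict[str, FluidMaterial]
    solids: dict[str, SolidMaterial]

    def __post_init__(self) -> None:
        clash = set(self.fluids) & set(self.solids)
        if clash:
            raise ValueError(f"labels shared between fluids and solids: {clash}")

    def material(self, label: str) -> Union[FluidMaterial, SolidMaterial]:
        if label in self.fluids:
            return self.fluids[label]
        if label in self.solids:
            return self.solids[label]
        raise KeyError(f"unknown material label {label!r}")

    def is_solid(self, label: str) -> bool:
        if label in self.solids:
            return True
        if label in self.fluids:
            return False
        raise KeyError(f"unknown material label {label!r}")

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fluids": [asdict(m) for m in self.fluids.values()],
            "solids": [asdict(m) for m in self.solids.values()],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MaterialDB":
        payload = json.loads(Path(path).read_text())
        fluids = {d["name"]: FluidMaterial(**d) for d in payload["fluids"]}
        solids = {d["name"]: SolidMaterial(**d) for d in payload["solids"]}
        return cls(fluids=fluids, solids=solids)


# Literature values: density kg/m^3, sound speed m/s, attenuation Np/(m MHz),
# Young's modulus Pa, Poisson ratio.
_FLUIDS = (
    ("fatty", 869.0, 1422.0, 5.7),
    ("glandular", 874.0, 1487.0, 10.5),
    ("tumor", 1041.0, 1548.0, 11.28),
    ("fibroadenoma", 1060.0, 1520.0, 10.82),
    ("duct_fluid", 1000.0, 1480.0, 0.025),
)

_SOLIDS = (
    ("HAp", 3180.0, 1374.0, 6.0e9, 0.27),
    ("calcium_carbonate", 2930.0, 5486.0, 88.19e9, 0.32),
    ("calcium_oxalate", 2200.0, 4785.0, 50.38e9, 0.32),
)


def builtin_db() -> MaterialDB:
    """The default material database for the margin phantoms.

    Returns the five soft-tissue/fluid records and three microcalcification
    minerals with their literature properties.
    """
    return MaterialDB(
        fluids={n: FluidMaterial(n, *rest) for n, *rest in _FLUIDS},
        solids={n: SolidMaterial(n, *rest) for n, *rest in _SOLIDS},
    )


def complex_wavenumber(material: FluidMaterial, frequency: float) -> complex:
    """Complex acoustic wavenumber of a lossy fluid at ``frequency`` (Hz).

    Real part ``2 pi f / c``; imaginary magnitude ``alpha * f_MHz`` in Np/m.  The
    package uses the ``exp(-i omega t)`` time convention, under which a plane wave
    ``exp(i k x)`` propagating in +x decays iff ``Im k > 0``; the imaginary part is
    therefore returned positive.
    """
    if frequency <= 0:
        raise ValueError(f"frequency must be positive, got {frequency}")
    k_real = 2.0 * math.pi * frequency / material.sound_speed
    k_imag = material.attenuation * (frequency / 1.0e6)
    return complex(k_real, k_imag)


def lame_constants(material: SolidMaterial) -> tuple[float, float]:
    """Lame constants ``(lambda, mu)`` in Pa from Young's modulus and Poisson ratio."""
    E, nu = material.youngs_modulus, material.poisson_ratio
    if not 0.0 <= nu < 0.5:
        raise ValueError(f"poisson_ratio must lie in [0, 0.5), got {nu}")
    mu = E / (2.0 * (1.0 + nu))
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return lam, mu
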