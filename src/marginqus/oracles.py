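"""Analytic scattering solutions and seeded synthetic spectra.

These are the independent reference solutions used to validate the finite
element solver and the spectral metrics:

* plane-wave scattering from a penetrable (fluid) circular cylinder — classical
  cylindrical-harmonic (Bessel/Hankel) series with pressure and normal
  displacement matched at the interface;
* plane-wave scattering from an elastic circular cylinder in a fluid —
  interior compressional and shear displacement potentials, with continuity of
  normal displacement, normal traction balancing the total fluid pressure, and
  vanishing shear traction at the interface;
* the sound-hard (rigid immovable) cylinder series as a limit check;
* seeded synthetic spectra (sinusoid / random walk / piecewise-constant) with
  known extrema structure for testing the peak-density and MPVD estimators.

All series use the ``exp(-i omega t)`` convention with incident wave
``p0 * exp(i k0 x)``; complex (lossy) wavenumbers are supported throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence, Union

import numpy as np
from scipy import special

from .materials import FluidMaterial, SolidMaterial, complex_wavenumber, lame_constants

__all__ = [
    "CylinderCase",
    "SynthSpectrumSpec",
    "SynthSpectrum",
    "fluid_cylinder_coefficients",
    "fluid_cylinder_field",
    "elastic_cylinder_coefficients",
    "elastic_cylinder_field",
    "layered_cylinder_coefficients",
    "layered_cylinder_field",
    "sound_hard_coefficients",
    "far_field_pattern",
    "attenuated_plane_wave",
    "synth_spectrum",
]


@dataclass(frozen=True)
class CylinderCase:
    """A single centered cylinder in an unbounded ambient fluid."""

    radius: float
    interior: Union[FluidMaterial, SolidMaterial]
    ambient: FluidMaterial
    frequency: float
    amplitude: float = 1.0
    truncation_order: int | None = None

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")

    @property
    def k0(self) -> complex:
        return complex_wavenumber(self.ambient, self.frequency)

    def order(self) -> int:
        """Series truncation order; defaults to ``k0*a + 24`` which is past the
        point where terms decay super-exponentially."""
        if self.truncation_order is not None:
            n = self.truncation_order
        else:
            n = int(math.ceil(abs(self.k0) * self.radius)) + 24
        floor = int(math.ceil(abs(self.k0) * self.radius)) + 10
        if n < floor:
            raise ValueError(f"truncation_order must be >= k*a + 10 = {floor}")
        return n


def _check_converged(coeffs: np.ndarray, rtol: float = 1e-10) -> None:
    scale = np.max(np.abs(coeffs)) or 1.0
    tail = np.max(np.abs(coeffs[-3:])) / scale
    if tail > rtol:
        raise RuntimeError(
            f"cylinder series not converged: tail magnitude {tail:.2e} > {rtol:.0e};"
            " raise truncation_order"
        )


# ---------------------------------------------------------------------------
# penetrable fluid cylinder


def fluid_cylinder_coefficients(case: CylinderCase) -> tuple[np.ndarray, np.ndarray]:
    """Modal coefficients ``(A_n, B_n)`` of the scattered and interior fields.

    With ``eps_n = 1 (n=0) else 2``, the fields are::

        p_s   = p0 sum eps_n i^n A_n H1_n(k0 r) cos(n theta)      (r > a)
        p_int = p0 sum eps_n i^n B_n J_n(k1 r)  cos(n theta)      (r < a)
    """
    if not isinstance(case.interior, FluidMaterial):
        raise TypeError("fluid_cylinder_coefficients needs a fluid interior")
    a = case.radius
    k0, k1 = case.k0, complex_wavenumber(case.interior, case.frequency)
    r0, r1 = case.ambient.density, case.interior.density
    N = case.order()
    n = np.arange(N + 1)
    x0, x1 = k0 * a, k1 * a
    J0, dJ0 = special.jv(n, x0), special.jvp(n, x0)
    H0, dH0 = special.hankel1(n, x0), special.h1vp(n, x0)
    J1, dJ1 = special.jv(n, x1), special.jvp(n, x1)
    # pressure continuity and normal-displacement continuity
    #   J0 + A H0 = B J1
    #   (k0/r0)(dJ0 + A dH0) = (k1/r1) B dJ1
    det = H0 * (k1 / r1) * dJ1 - (k0 / r0) * dH0 * J1
    A = ((k0 / r0) * dJ0 * J1 - J0 * (k1 / r1) * dJ1) / det
    B = (J0 + A * H0) / J1
    _check_converged(A)
    return A, B


def fluid_cylinder_field(case: CylinderCase, points: np.ndarray) -> np.ndarray:
    """Scattered pressure ``p_s = p_total - p_incident`` at the given points.

    Valid both outside and inside the cylinder (inside, the scattered field is
    the interior pressure minus the incident wave, matching the scattered-field
    FEM unknown).
    """
    A, B = fluid_cylinder_coefficients(case)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.hypot(pts[:, 0], pts[:, 1])
    th = np.arctan2(pts[:, 1], pts[:, 0])
    k0 = case.k0
    k1 = complex_wavenumber(case.interior, case.frequency)
    out = np.zeros(len(pts), dtype=complex)
    ext = r >= case.radius
    N = len(A) - 1
    n = np.arange(N + 1)
    eps = np.where(n == 0, 1.0, 2.0) * (1j**n)
    if ext.any():
        rad = special.hankel1(n[None, :], k0 * r[ext, None])
        out[ext] = (rad * (eps * A)[None, :] * np.cos(n[None, :] * th[ext, None])).sum(1)
    if (~ext).any():
        ri, ti = r[~ext], th[~ext]
        p_int = (
            special.jv(n[None, :], k1 * ri[:, None])
            * (eps * B)[None, :]
            * np.cos(n[None, :] * ti[:, None])
        ).sum(1)
        p_inc = np.exp(1j * k0 * ri * np.cos(ti))
        out[~ext] = p_int - p_inc
    return case.amplitude * out


# ---------------------------------------------------------------------------
# elastic cylinder


def _solid_mode_matrix(n: int, a: float, kL: complex, kT: complex, lam: float, mu: float):
    """Interface values (u_r, sigma_rr, sigma_rtheta) of the two interior
    potentials of order n, evaluated at r=a.

    phi = J_n(kL r) cos(n th) (compressional), psi = J_n(kT r) sin(n th) (shear).
    Returns two columns ``(u_r, s_rr, s_rt)``: one per potential.
    """
    JL, dJL, d2JL = (special.jvp(n, kL * a, k) for k in (0, 1, 2))
    JT, dJT, d2JT = (special.jvp(n, kT * a, k) for k in (0, 1, 2))
    # compressional potential
    ur_p = kL * dJL
    srr_p = -lam * kL**2 * JL + 2 * mu * kL**2 * d2JL
    srt_p = 2 * mu * n * (JL / a**2 - kL * dJL / a)
    # shear potential
    ur_s = n / a * JT
    srr_s = 2 * mu * n * (kT * dJT / a - JT / a**2)
    srt_s = mu * (-(kT**2) * d2JT + kT * dJT / a - n**2 * JT / a**2)
    return (ur_p, srr_p, srt_p), (ur_s, srr_s, srt_s)


def elastic_cylinder_coefficients(case: CylinderCase) -> np.ndarray:
    """Modal coefficients ``A_n`` of the pressure scattered by an elastic cylinder."""
    if not isinstance(case.interior, SolidMaterial):
        raise TypeError("elastic_cylinder_coefficients needs a solid interior")
    a = case.radius
    k0 = case.k0
    rho0 = case.ambient.density
    omega = 2 * math.pi * case.frequency
    lam, mu = lame_constants(case.interior)
    rho_s = case.interior.density
    kL = omega / math.sqrt((lam + 2 * mu) / rho_s)
    kT = omega / math.sqrt(mu / rho_s)

    N = case.order()
    A = np.zeros(N + 1, dtype=complex)
    x0 = k0 * a
    for n in range(N + 1):
        Jn, dJn = special.jv(n, x0), special.jvp(n, x0)
        Hn, dHn = special.hankel1(n, x0), special.h1vp(n, x0)
        (ur_p, srr_p, srt_p), (ur_s, srr_s, srt_s) = _solid_mode_matrix(
            n, a, kL, kT, lam, mu
        )
        c = 1.0 / (rho0 * omega**2)  # fluid u_r = grad p / (rho0 w^2)
        if n == 0:
            # unknowns (A, B): displacement and normal-traction continuity
            M = np.array(
                [[c * k0 * dHn, -ur_p], [Hn, srr_p]], dtype=complex
            )
            rhs = np.array([-c * k0 * dJn, -Jn], dtype=complex)
            sol = np.linalg.solve(M, rhs)
            A[n] = sol[0]
        else:
            # unknowns (A, B, C)
            M = np.array(
                [
                    [c * k0 * dHn, -ur_p, -ur_s],
                    [Hn, srr_p, srr_s],
                    [0.0, srt_p, srt_s],
                ],
                dtype=complex,
            )
            rhs = np.array([-c * k0 * dJn, -Jn, 0.0], dtype=complex)
            sol = np.linalg.solve(M, rhs)
            A[n] = sol[0]
    _check_converged(A)
    return A


def elastic_cylinder_field(case: CylinderCase, points: np.ndarray) -> np.ndarray:
    """Scattered pressure at exterior points; NaN inside the solid."""
    A = elastic_cylinder_coefficients(case)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.hypot(pts[:, 0], pts[:, 1])
    th = np.arctan2(pts[:, 1], pts[:, 0])
    out = np.full(len(pts), np.nan, dtype=complex)
    ext = r >= case.radius
    n = np.arange(len(A))
    eps = np.where(n == 0, 1.0, 2.0) * (1j**n)
    if ext.any():
        rad = special.hankel1(n[None, :], case.k0 * r[ext, None])
        out[ext] = (rad * (eps * A)[None, :] * np.cos(n[None, :] * th[ext, None])).sum(1)
    return case.amplitude * out


def layered_cylinder_coefficients(
    radii: Sequence[float],
    materials: Sequence[FluidMaterial],
    ambient: FluidMaterial,
    frequency: float,
    truncation_order: int | None = None,
) -> np.ndarray:
    """Scattered-field modal coefficients of a concentric layered fluid cylinder.

    ``radii`` are the interface radii in strictly decreasing order and
    ``materials[i]`` fills the region just inside ``radii[i]`` (the last one is
    the core).  This is the exact reference solution for the normal-duct and
    ADH phantoms (fluid annulus + core); a single layer reduces to the
    penetrable-cylinder series.
    """
    radii = list(map(float, radii))
    if len(radii) != len(materials) or not radii:
        raise ValueError("need one material per radius")
    if any(r2 >= r1 for r1, r2 in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly decreasing")
    ks = [complex_wavenumber(ambient, frequency)] + [
        complex_wavenumber(m, frequency) for m in materials
    ]
    rhos = [ambient.density] + [m.density for m in materials]
    nlay = len(radii)
    if truncation_order is None:
        N = int(math.ceil(abs(ks[0]) * radii[0])) + 24
    else:
        N = truncation_order
    A = np.zeros(N + 1, dtype=complex)
    nun = 2 * nlay  # A, then (J, Y) per annulus, then core J
    for m in range(N + 1):
        M = np.zeros((nun, nun), dtype=complex)
        rhs = np.zeros(nun, dtype=complex)
        row = 0
        for i, r in enumerate(radii):
            ko, ki = ks[i], ks[i + 1]
            ro, ri = rhos[i], rhos[i + 1]
            Jo, dJo = special.jv(m, ko * r), special.jvp(m, ko * r)
            Ji, dJi = special.jv(m, ki * r), special.jvp(m, ki * r)
            if i == 0:
                Ho, dHo = special.hankel1(m, ko * r), special.h1vp(m, ko * r)
                outer = [(0, Ho, dHo, ko, ro)]
                rhs[row] -= Jo
                rhs[row + 1] -= (ko / ro) * dJo
            else:
                Yo, dYo = special.yv(m, ko * r), special.yvp(m, ko * r)
                outer = [(2 * i - 1, Jo, dJo, ko, ro), (2 * i, Yo, dYo, ko, ro)]
            if i + 1 < nlay:
                Yi, dYi = special.yv(m, ki * r), special.yvp(m, ki * r)
                inner = [(2 * i + 1, Ji, dJi, ki, ri), (2 * i + 2, Yi, dYi, ki, ri)]
            else:
                inner = [(nun - 1, Ji, dJi, ki, ri)]
            for idx, P, dP, kk, rr in outer:
                M[row, idx] += P
                M[row + 1, idx] += (kk / rr) * dP
            for idx, P, dP, kk, rr in inner:
                M[row, idx] -= P
                M[row + 1, idx] -= (kk / rr) * dP
            row += 2
        A[m] = np.linalg.solve(M, rhs)[0]
    _check_converged(A)
    return A


def layered_cylinder_field(
    radii: Sequence[float],
    materials: Sequence[FluidMaterial],
    ambient: FluidMaterial,
    frequency: float,
    points: np.ndarray,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Scattered pressure of the layered cylinder at exterior points."""
    A = layered_cylinder_coefficients(radii, materials, ambient, frequency)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.hypot(pts[:, 0], pts[:, 1])
    if np.any(r < radii[0]):
        raise ValueError("layered_cylinder_field evaluates exterior points only")
    th = np.arctan2(pts[:, 1], pts[:, 0])
    k0 = complex_wavenumber(ambient, frequency)
    n = np.arange(len(A))
    eps = np.where(n == 0, 1.0, 2.0) * (1j**n)
    rad = special.hankel1(n[None, :], k0 * r[:, None])
    return amplitude * (rad * (eps * A)[None, :] * np.cos(n[None, :] * th[:, None])).sum(1)


def sound_hard_coefficients(case: CylinderCase) -> np.ndarray:
    """Rigid immovable cylinder: ``A_n = -J'_n(k0 a)/H'_n(k0 a)``."""
    N = case.order()
    n = np.arange(N + 1)
    x0 = case.k0 * case.radius
    return -special.jvp(n, x0) / special.h1vp(n, x0)


def far_field_pattern(coeffs: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Angular factor ``f(theta) = sum eps_n (-i)^n A_n cos(n theta)`` of the
    far field ``p_s ~ p0 sqrt(2/(pi k r)) e^{i(k r - pi/4)} f(theta)``."""
    n = np.arange(len(coeffs))
    eps = np.where(n == 0, 1.0, 2.0)
    terms = eps * (-1j) ** n * coeffs
    return (terms[None, :] * np.cos(np.outer(theta, n))).sum(axis=1)


def attenuated_plane_wave(material: FluidMaterial, distance: float, f: float) -> float:
    """Amplitude ratio ``exp(-alpha f_MHz d)`` of a plane wave after ``distance`` m."""
    if distance < 0:
        raise ValueError("distance must be nonnegative")
    return math.exp(-material.attenuation * (f / 1e6) * distance)


# ---------------------------------------------------------------------------
# synthetic spectra


@dataclass(frozen=True)
class SynthSpectrumSpec:
    kind: Literal["sinusoid", "random_walk", "piecewise"]
    length: int = 190
    seed: int = 0
    amplitude: float = 1.0
    offset: float = 2.0
    periods: float = 5.0       # sinusoid only
    n_segments: int = 12       # piecewise only

    def __post_init__(self):
        if self.length < 3:
            raise ValueError("length must be >= 3")


@dataclass(frozen=True)
class SynthSpectrum:
    """Spectrum-shaped container carrying the same values on both channels."""

    frequencies: np.ndarray
    front_abs: np.ndarray
    back_abs: np.ndarray


def synth_spectrum(spec: SynthSpectrumSpec) -> SynthSpectrum:
    """Deterministic synthetic spectrum with known extrema structure.

    ``sinusoid`` has an analytically countable number of extrema; ``random_walk``
    is generically plateau-free; ``piecewise`` contains flat runs that exercise
    the plateau rule of ``find_extrema``.
    """
    n = spec.length
    rng = np.random.default_rng(spec.seed)
    x = np.linspace(0.0, 1.0, n)
    if spec.kind == "sinusoid":
        v = spec.offset + spec.amplitude * np.sin(2 * math.pi * spec.periods * x)
    elif spec.kind == "random_walk":
        v = spec.offset + spec.amplitude * np.cumsum(rng.standard_normal(n)) / math.sqrt(n)
        v = v - v.min() + 0.1 * spec.amplitude
    elif spec.kind == "piecewise":
        seg = max(1, n // spec.n_segments)
        levels = spec.offset + spec.amplitude * rng.standard_normal(spec.n_segments + 1)
        v = np.repeat(levels, seg)[:n]
        if len(v) < n:
            v = np.concatenate([v, np.full(n - len(v), v[-1])])
    else:
        raise ValueError(f"unknown kind {spec.kind!r}")
    freqs = 22e6 + 0.1e6 * np.arange(n)
    return SynthSpectrum(frequencies=freqs, front_abs=v.copy(), back_abs=v.copy())
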