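"""Analytic cylinder-scattering series and synthetic spectra."""

import numpy as np
import pytest

from marginqus.materials import FluidMaterial, SolidMaterial, builtin_db, lame_constants
from marginqus.oracles import (
    CylinderCase,
    SynthSpectrumSpec,
    attenuated_plane_wave,
    elastic_cylinder_coefficients,
    elastic_cylinder_field,
    fluid_cylinder_coefficients,
    fluid_cylinder_field,
    far_field_pattern,
    sound_hard_coefficients,
    synth_spectrum,
)

DB = builtin_db()
AMBIENT_LOSSLESS = FluidMaterial("fatty0", 869, 1422, 0.0)


def _fluid_case(**kw):
    base = dict(
        radius=0.4e-3,
        interior=FluidMaterial("tumor0", 1041, 1548, 0.0),
        ambient=AMBIENT_LOSSLESS,
        frequency=5e6,
    )
    base.update(kw)
    return CylinderCase(**base)


class TestFluidCylinderSeries:
    def test_zero_contrast_gives_zero_field(self):
        case = _fluid_case(interior=AMBIENT_LOSSLESS)
        pts = np.array([[0.8e-3, 0.1e-3], [0.1e-3, 0.0], [-0.6e-3, -0.4e-3]])
        assert np.max(np.abs(fluid_cylinder_field(case, pts))) < 1e-14

    def test_converged_beyond_default_truncation(self):
        case = _fluid_case()
        pts = np.array([[0.7e-3, 0.2e-3]])
        a = fluid_cylinder_field(case, pts)
        case2 = _fluid_case(truncation_order=2 * case.order())
        b = fluid_cylinder_field(case2, pts)
        assert abs(a - b)[0] / abs(a)[0] < 1e-10

    def test_lossless_modal_unitarity(self):
        # each mode of a lossless scatterer conserves energy: |1 + 2 A_n| = 1
        A, _ = fluid_cylinder_coefficients(_fluid_case())
        assert np.allclose(np.abs(1 + 2 * A), 1.0, atol=1e-10)

    def test_optical_theorem_for_lossless_case(self):
        A, _ = fluid_cylinder_coefficients(_fluid_case())
        n = np.arange(len(A))
        eps = np.where(n == 0, 1.0, 2.0)
        scattered_power = float((eps * np.abs(A) ** 2).sum())
        # forward amplitude consistency (2D optical theorem)
        extinction = float(-(eps * A.real).sum())
        assert scattered_power == pytest.approx(extinction, rel=1e-6)
        # and the far-field pattern integrates to the same power
        theta = np.linspace(0, 2 * np.pi, 20001)
        f = far_field_pattern(A, theta)
        integral = np.trapezoid(np.abs(f) ** 2, theta) / np.pi
        assert integral == pytest.approx(2 * scattered_power, rel=1e-6)

    def test_pressure_continuity_across_interface(self):
        case = _fluid_case()
        a = case.radius
        th = np.linspace(0, 2 * np.pi, 13)[:-1]
        outside = 1.0000001 * a
        inside = 0.9999999 * a
        p_out = fluid_cylinder_field(case, np.c_[outside * np.cos(th), outside * np.sin(th)])
        p_in = fluid_cylinder_field(case, np.c_[inside * np.cos(th), inside * np.sin(th)])
        # total pressure is continuous; scattered-field jump equals incident jump (tiny)
        assert np.allclose(p_out, p_in, rtol=1e-4, atol=1e-6)

    def test_low_truncation_rejected(self):
        with pytest.raises(ValueError):
            _fluid_case(truncation_order=2).order()


class TestElasticCylinderSeries:
    def test_lossless_modal_unitarity(self):
        case = CylinderCase(
            radius=0.2e-3, interior=DB.solids["HAp"],
            ambient=AMBIENT_LOSSLESS, frequency=5e6,
        )
        A = elastic_cylinder_coefficients(case)
        assert np.allclose(np.abs(1 + 2 * A), 1.0, atol=1e-10)

    def test_fluid_limit_matches_fluid_series(self):
        # a solid with vanishing shear modulus behaves as a fluid with the
        # same density and longitudinal modulus
        rho, c = 1041.0, 1548.0
        lam_target = rho * c**2
        nu = 0.4999
        E = lam_target * (1 + nu) * (1 - 2 * nu) / nu
        soft = SolidMaterial("fluidlike", rho, c, E, nu)
        lam, mu = lame_constants(soft)
        assert mu / lam < 1e-3
        case_s = CylinderCase(0.3e-3, soft, AMBIENT_LOSSLESS, 3e6)
        case_f = CylinderCase(
            0.3e-3, FluidMaterial("f", rho, np.sqrt((lam + 2 * mu) / rho), 0.0),
            AMBIENT_LOSSLESS, 3e6,
        )
        pts = np.array([[0.8e-3, 0.0], [-0.7e-3, 0.3e-3], [0.0, 0.9e-3]])
        ps = elastic_cylinder_field(case_s, pts)
        pf = fluid_cylinder_field(case_f, pts)
        assert np.max(np.abs(ps - pf) / np.abs(pf)) < 0.01

    def test_rigid_limit_approaches_sound_hard_series(self):
        rigid = SolidMaterial("rigid", 869e5, 1374, 1e16, 0.27)
        case = CylinderCase(0.2e-3, rigid, AMBIENT_LOSSLESS, 5e6)
        A = elastic_cylinder_coefficients(case)
        Ah = sound_hard_coefficients(case)
        assert np.max(np.abs(A[:8] - Ah[:8])) < 1e-4

    def test_interior_points_masked(self):
        case = CylinderCase(0.2e-3, DB.solids["HAp"], AMBIENT_LOSSLESS, 5e6)
        out = elastic_cylinder_field(case, np.array([[0.0, 0.0], [0.5e-3, 0.0]]))
        assert np.isnan(out[0])
        assert np.isfinite(out[1])


class TestLayeredCylinderSeries:
    def test_single_layer_reduces_to_penetrable_series(self):
        from marginqus.oracles import layered_cylinder_coefficients

        tum = DB.fluids["tumor"]
        A1 = layered_cylinder_coefficients([0.5e-3], [tum], AMBIENT_LOSSLESS, 8e6)
        A2, _ = fluid_cylinder_coefficients(
            CylinderCase(0.5e-3, tum, AMBIENT_LOSSLESS, 8e6)
        )
        n = min(len(A1), len(A2))
        assert np.max(np.abs(A1[:n] - A2[:n])) < 1e-12

    def test_degenerate_shell_equals_single_cylinder(self):
        from marginqus.oracles import layered_cylinder_coefficients

        tum = DB.fluids["tumor"]
        A1 = layered_cylinder_coefficients(
            [0.5e-3, 0.3e-3], [tum, tum], AMBIENT_LOSSLESS, 8e6
        )
        A2, _ = fluid_cylinder_coefficients(
            CylinderCase(0.5e-3, tum, AMBIENT_LOSSLESS, 8e6)
        )
        n = min(len(A1), len(A2))
        assert np.max(np.abs(A1[:n] - A2[:n])) < 1e-12

    def test_zero_contrast_scatters_nothing(self):
        from marginqus.oracles import layered_cylinder_coefficients

        A = layered_cylinder_coefficients(
            [0.5e-3, 0.46e-3], [AMBIENT_LOSSLESS, AMBIENT_LOSSLESS],
            AMBIENT_LOSSLESS, 8e6,
        )
        assert np.max(np.abs(A)) < 1e-12

    def test_lossless_modal_unitarity(self):
        from marginqus.oracles import layered_cylinder_coefficients

        gla = FluidMaterial("gla0", 874, 1487, 0.0)
        wat = FluidMaterial("wat0", 1000, 1480, 0.0)
        A = layered_cylinder_coefficients(
            [0.5e-3, 0.46e-3], [gla, wat], AMBIENT_LOSSLESS, 8e6
        )
        assert np.allclose(np.abs(1 + 2 * A), 1.0, atol=1e-9)

    def test_nondecreasing_radii_rejected(self):
        from marginqus.oracles import layered_cylinder_coefficients

        with pytest.raises(ValueError):
            layered_cylinder_coefficients(
                [0.3e-3, 0.5e-3],
                [DB.fluids["tumor"], DB.fluids["duct_fluid"]],
                AMBIENT_LOSSLESS, 8e6,
            )


class TestAttenuatedPlaneWave:
    def test_zero_distance_gives_unity(self):
        assert attenuated_plane_wave(DB.fluids["tumor"], 0.0, 31.5e6) == 1.0

    def test_tumor_value_at_center_frequency(self):
        r = attenuated_plane_wave(DB.fluids["tumor"], 1e-3, 31.5e6)
        assert r == pytest.approx(0.7010, rel=1e-3)

    def test_monotone_in_distance_and_frequency(self):
        m = DB.fluids["glandular"]
        d = np.linspace(0, 2e-3, 7)
        vals = [attenuated_plane_wave(m, di, 22e6) for di in d]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        f = np.linspace(22e6, 41e6, 7)
        vals = [attenuated_plane_wave(m, 1e-3, fi) for fi in f]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestSynthSpectrum:
    def test_seed_determinism(self):
        s1 = synth_spectrum(SynthSpectrumSpec(kind="random_walk", seed=9))
        s2 = synth_spectrum(SynthSpectrumSpec(kind="random_walk", seed=9))
        assert np.array_equal(s1.front_abs, s2.front_abs)

    def test_sinusoid_extrema_structure(self):
        s = synth_spectrum(SynthSpectrumSpec(kind="sinusoid", length=400, periods=7))
        from marginqus.qus_metrics import find_extrema

        # 7 full periods sampled densely: 7 peaks + 7 valleys, +/-1 at edges
        assert abs(len(find_extrema(s.front_abs)) - 14) <= 1

    def test_piecewise_contains_plateaus(self):
        s = synth_spectrum(SynthSpectrumSpec(kind="piecewise", length=120, seed=2))
        assert np.any(np.diff(s.front_abs) == 0.0)
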