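# marginqus

Quantitative-ultrasound characterization of breast surgical-margin tissue by
frequency-domain finite-element simulation.

During breast-conserving surgery the excised margin of normal tissue around a
tumor must be judged benign or malignant, ideally in the operating room.
High-frequency quantitative ultrasound (QUS) is a candidate tool: instead of
imaging, it reduces the frequency spectrum of scattered pressure to scalar
response values that track tissue microstructure.  `marginqus` implements a
computational test bed for this idea: 2D numerical phantoms of a breast duct
inside a margin block in six pathological states — normal duct, atypical
ductal hyperplasia (ADH), ductal carcinoma in situ (DCIS), and ducts carrying
hydroxyapatite (malignancy-associated), calcium-carbonate or calcium-oxalate
(benign) microcalcifications — interrogated by a 22–41 MHz plane-wave sweep in
pulse-echo (front-wall) and pitch-catch (back-wall) modes.

## Model

Soft tissues and duct fluid are lossy acoustic fluids obeying the Helmholtz
equation for the total pressure *p*:

    div( (1/ρ) grad p ) + (k²/ρ) p = 0,      k = 2πf/c + i α f_MHz

with density ρ, sound speed *c* and attenuation α in Np/(m·MHz).
Microcalcification minerals are linear elastic solids obeying time-harmonic
Navier's equation for the displacement **u**:

    −ρ_s ω² u = (λ+2μ) grad(div u) − μ curl(curl u)

coupled to the fluid at the mineral boundary by continuity of normal
acceleration, n·((1/ρ) grad p) = ω² n·u, and by the pressure load σ·n = −p n.
The solver uses a scattered-field split p = p_b + p_s about the incident plane
wave p_b = p₀ e^{ikx} (ambient fatty-tissue wavenumber), so material contrast
is the only source; a perfectly matched layer on a mapped-quadrilateral frame
absorbs outgoing waves.  Discretisation is quadratic (P2 triangles in the
tissue, Q2 rectangles in the PML) at λ/6–λ/9 element sizing on an
interface-conforming Delaunay mesh built in-package.

The spectra |⟨p_s⟩_wall|(f) are reduced to the QUS response values

* **peak density** — number of interior peaks plus valleys in the spectrum,
* **MPVD** — mean absolute magnitude difference of adjacent peak/valley pairs,
* spectral features — peak magnitude and its frequency, overall (mean)
  magnitude, jaggedness (mean |Δ| between neighbouring samples),

aggregated as mean ± SD over five duct positions.

Every physics ingredient is validated against an independent analytic
standard: the penetrable-cylinder and elastic-cylinder scattering series
(Bessel/Hankel expansions implemented in `marginqus.oracles`), a zero-contrast
null, PML-placement insensitivity, and brute-force enumeration for the
spectral metrics.

## Worked example

```bash
python examples/validate_against_cylinder_series.py
```

prints (5 MHz, 0.4 mm tumor cylinder in fatty tissue, λ/8 mesh):

```
relative L2 field error vs series: 0.14% (dof 38673)
front-wall |<ps>|: 9.5395e-03 Pa
back-wall  |<ps>|: 3.6899e-01 Pa
```

The 0.14% L2 error is the finite-element solution's disagreement with the
exact Bessel-series field over the inner 80% of the domain — the solver,
interface handling and absorbing layer validated in one number.  The wall
averages are the two measurement channels: the weak front-wall value is the
reflected (pulse-echo) signal, the large back-wall value the transmitted
(pitch-catch) signal of this almost-transparent soft scatterer.

`examples/run_reduced_study.py` runs a two-pathology study at desk scale and
writes spectra, metric tables and plots; `examples/build_and_mesh_phantom.py`
and `examples/spectral_metrics.py` demonstrate the meshing and metrics layers.

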