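# Methods

## Phantoms

Each phantom is a 2 mm × 2 mm block of fatty tissue containing one breast duct
of 1 mm diameter.  The six pathological states are built as a painter's stack
of primitive regions (later entries override earlier ones where they overlap,
so annuli and disks need no boolean geometry):

| state | duct contents |
|---|---|
| normal | water-like duct fluid core (r = 0.46 mm) lined by a 40 µm glandular layer (two 20 µm epithelial cell layers) |
| ADH | tumor-tissue ring of thickness 0.25 mm (half the duct radius) around a fluid core |
| DCIS | duct filled with tumor tissue |
| HAp calcification | DCIS duct plus two clusters of four oval hydroxyapatite deposits |
| CC / CO calcification | fibroadenoma-filled duct plus calcium-carbonate / calcium-oxalate clusters |

Material constants (density, sound speed, attenuation in Np/(m·MHz) for the
five fluids; density, Young's modulus, Poisson ratio for the three minerals)
live in `marginqus.materials.builtin_db()`.

The oval deposits' sizes and positions are not constrained by anatomy beyond
"clustered microcalcifications of tens of µm": the default layout places two
clusters symmetrically at ±r/2 on the horizontal axis, each a 2×2 grid of
50 µm × 30 µm ovals separated by 30 µm gaps, all parameters overridable via
`CalcLayoutConfig`.  Layout validity (containment in the duct with one
semi-axis of clearance, pairwise separation) is enforced by a 256-point
boundary sampling check.  The ADH model carries no residual glandular layer
(the proliferative tissue replaces it entirely).

Computational variation comes from five duct positions: centered and ±0.4 mm
along each axis.

## Governing equations and conventions

Time convention e^{−iωt}.  Fluids: Helmholtz with complex wavenumber
k = 2πf/c + i·α·f_MHz; the imaginary part is taken positive so e^{ikx} decays
along +x, and α is used in Np/(m·MHz) exactly as tabulated (applying an extra
dB→Np factor of ln10/20 would double-convert).  Solids: time-harmonic Navier
with Lamé constants from (E, ν); minerals are lossless.  Coupling at mineral
boundaries: n·((1/ρ)∇p) = ω²·n·u and traction −p·n with the *total* pressure
p = p_b + p_s.

The incident wave is p_b = p₀·e^{ik₀x} with k₀ the **full complex** ambient
(fatty) wavenumber.  With this choice the contrast source
(1/ρ − 1/ρ₀, k²/ρ − k₀²/ρ₀) vanishes identically wherever the material equals
the ambient — in particular throughout the PML — and an all-fatty phantom
scatters exactly nothing.  A lossless background would instead leave a
residual source of order α·f·L ≈ 0.2·p₀ spread over the whole domain.

## Discretisation

* Interface-conforming Delaunay meshing (distmesh-style): fixed nodes on the
  square boundary and on every material curve, hexagonal-lattice interior
  seeding per region, spring relaxation, Laplacian smoothing with a
  curve-clearance guard, crowding merge, and long-edge splitting.  Per-region
  element-size cap c_region/(f_max·divisor), with the solid shear speed
  defining the cap in minerals; thin annuli (ring gap below the cap) get
  phase-aligned sampling on both circles so ring-crossing diagonals stay under
  the cap.  The generator targets sizes ~15% below the cap so the cap is a
  true maximum after smoothing; minimum triangle angle in practice ≥ 20°.
* P2 (quadratic) triangles for pressure and displacement; geometric edges are
  straight (the sagitta of a λ/8 chord on the duct circle is nanometers).
* PML: a frame of axis-aligned Q2 rectangles extruded from the boundary nodes
  (8 layers by default), with diagonal complex stretching
  s = 1 + i·(β/(k₀·d))·((|x|−L/2)/d)², β = 30, giving a frequency-independent
  one-way damping of β/3 = 10 Np.  The outer rim is clamped.
* One mesh is built at the sweep's top frequency and reused for all lower
  frequencies.
* Direct sparse LU per frequency (`scipy.sparse.linalg.splu`), residual bound
  1e−10.  Frequency sweeps use a sweep-aware linear solver: the LU of an
  anchor frequency preconditions GMRES at neighbouring frequencies (refactor
  window 0.3 MHz, warm-started by the previous solution), with a 1e−8
  residual bound — roughly 2–3× faster than factoring every frequency and far
  below the accuracy of the wall-average observables.  Results agree with the
  direct path to better than 1e−6 normwise.

Mesh-convergence checks hold the physical PML thickness roughly constant
across divisors (layer count scaled with the divisor) so that successive
response changes isolate discretisation error; on the normal-duct phantom the
changes across divisors 6→7→8→9 decrease monotonically to below 1%.

## Verification standards

* Penetrable fluid cylinder: modal coefficients from pressure and
  normal-displacement continuity.  FEM vs series, 0.4 mm tumor cylinder at
  5 MHz, λ/8: relative L2 field error ≈ 0.14% over the inner 80% of the
  domain.
* Elastic cylinder: interior compressional + shear potentials, continuity of
  normal displacement, normal traction balancing total pressure, zero shear
  traction.  Checked against modal unitarity (|1+2Aₙ| = 1 lossless), the
  sound-hard limit, the fluid limit (μ→0), and FEM wall averages (≤ 0.7%
  disagreement for a 0.2 mm HAp cylinder at 5 MHz).
* Optical theorem and far-field power integral agree to 1e−6 for lossless
  scatterers.
* Spectral metrics against brute-force enumeration on 1000 seeded spectra
  (exact agreement), with plateau runs collapsing to their midpoint and
  endpoints excluded.

## Sweep and response values

Grid 22–41 MHz in 100 kHz steps, half-open (190 frequencies; the inclusive
191-point convention is selectable).  Incident amplitude follows a Gaussian
bell pinned at 1 Pa at 31.5 MHz and 50% at both band edges (the functional
form is the unique Gaussian through those three constraints; a raised-cosine
alternative would differ by < 2% inside the band).  Both wall averages are
length-weighted line integrals of complex p_s, exact for the quadratic trace
(Simpson per edge); spectra store their moduli.

Peak density counts strict interior extrema; MPVD averages |Δ| over adjacent
extrema and is reported as undefined (never silently 0) when fewer than two
extrema exist.  Group summaries use the sample (n−1) standard deviation over
duct positions.  "Jaggedness" is operationalised as the mean absolute
successive difference of the spectrum.

## Fidelity presets and what the scaled study shows

The full study (190 frequencies × 6 pathologies × 5 positions at λ/8) is many
CPU-hours with this solver stack.  Three presets are provided:

* `full` — the study settings above;
* `reduced` — 22–41 MHz, 0.5 MHz step, divisor 6, three positions;
* `desk` — the band compressed ×4 (5.5–10.25 MHz, 100 kHz step, 48
  frequencies), divisor 6, geometry unchanged.  A desk sweep of one phantom
  runs in ~2 minutes; the tests and the acceptance script use this preset.

### Which pathology contrasts the model reproduces

The package's own verification gives a sharp picture of what the
wall-averaged scattered-pressure spectra of these phantoms can and cannot
discriminate.  Because the three non-calcified phantoms are concentric
layered cylinders, their spectra can be computed *exactly* (to series
truncation) by a layered Bessel expansion, independent of the FEM; at the
compressed band the two routes agree to three digits (e.g. normal duct
pulse-echo peak density 11 and MPVD 0.0074 Pa by both), which validates the
whole sweep pipeline end to end.  Evaluating the same series at the full
22–41 MHz, 190-point setting shows:

* **pulse-echo** spectra carry strong interference structure at every scale
  (duct-wall reflections with ~0.75 MHz period: peak density ≈ 48 at the full
  band, ≈ 11–13 at desk scale).  Their MPVD separates the phantoms, ordering
  ADH > DCIS > normal at both scales: the tumor ring of ADH is the strongest
  reflector, while the nearly-water normal duct reflects least.
* **pitch-catch** wall averages of the non-calcified phantoms are smooth in
  frequency at *every* band scale (peak density 1–2 even at the full
  setting): the transmitted scattered field is dominated by the slowly
  varying forward lobe, and phase-coherent averaging over the 2 mm wall
  suppresses what little interference structure remains.  This conclusion is
  robust to the measurement convention (averaging |p_s| instead of the
  complex average, point values, offset ducts, or the total field p_b + p_s
  all stay smooth).  Pitch-catch peak density therefore cannot rank the
  non-calcified phantoms under this measurement model.
* **calcification** produces genuine resonant structure in both channels
  (elastic deposits scatter resonantly): calcified ducts show elevated peak
  density, MPVD and jaggedness relative to DCIS already at desk scale, and
  the two benign minerals remain close to each other while separating from
  hydroxyapatite.

The trend acceptance tests encode the clinically expected orderings (normal
epithelium most spectrally structured, carcinoma smoothest, calcification
structured again) and are run at desk scale; the assertions that depend on
pitch-catch structure or on the normal duct dominating pulse-echo MPVD fail
under this model at every scale — an honest negative result of the
implementation, documented rather than patched.  Candidate explanations are
an unmodelled measurement/post-processing step in comparable
commercial-solver studies, or spectral structure contributed there by
discretisation error (which would naturally rise with the amount of
scattering and thus mimic a scattering-tracking peak density).  Resolving
this requires information beyond the stated model.

## Known limitations

* 2D plane-strain phantoms; no 3D duct geometry or elevation scattering.
* Attenuation strictly linear in frequency; no dispersion.
* Solids lossless; no shear viscosity or thermoviscous boundary layers in
  fluids.
* Wall averages are taken on the physical-domain edges (x = ±1 mm), which is
  also the PML inner boundary.
* The mesher is a general-purpose simplex smoother, not a guaranteed-quality
  Delaunay refinement; quality floors are asserted, not proven.
* The `pipeline` module exposes functions plus `examples/` scripts rather
  than a console CLI; the study runner, metrics recomputation and validation
  entry points are `run_study`, `mesh_sensitivity_study` and
  `scripts/acceptance.py`.
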