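# Methods

This note documents the model, the numerical choices, and the limits of
what the test suite demonstrates.

## Scattering model

A particle that is rotationally symmetric in *d* dimensions has the
volume-normalized amplitude F_d(x) = ₀F₁((d+2)/2; −x²/4), x = qR, which
equals sin(x)/x (d = 1), 2J₁(x)/x (d = 2) and 3(sin x − x cos x)/x³
(d = 3).  All densities are uniform: a radial profile would only rescale
the contrast factor Δb.  The intensity of an assembly is computed in the
decoupling approximation

    I(q) = (Δb)² ρ_N ⟨P(q)⟩ [1 + β(q)(⟨Z(q)⟩ − 1) G(q)],

with β = ⟨F⟩²/⟨P⟩ clipped to [0, 1], Z ≥ 0 the lattice factor and
G = exp(−σ_DW² q²) the Debye–Waller damping, so the bracket is
non-negative by construction.  The decoupling approximation assumes
particle positions are uncorrelated with their sizes and orientations; it
degrades for strongly coupled systems (e.g. size-segregated crystals).

## Size averaging: the Schulz–Zimm law

Sizes follow the Schulz–Zimm (Gamma) density h(R) ∝ R^z e^{−(z+1)R/R̄}
with z = 1/σ² − 1.  This family is the one whose moments are exactly the
Pochhammer ratios ⟨R^k⟩/R̄^k = (z+1)_k/(z+1)^k that appear in the series
coefficients, and whose averages of damped trigonometric terms have
closed forms,

    ⟨(R/R̄)^{−k} cos(cqR + φ)⟩ =
        ⟨(R/R̄)^{−k}⟩ (1+y²)^{−(z+1−k)/2} cos((z+1−k) arctan y + φ),
    y = cqR̄/(z+1),

which is what makes the high-q regimes analytic.  σ = 0 is accepted as
the monodisperse limit (every average degenerates to the plain
trigonometric value; the Porod regime then does not exist because the
oscillations never damp out).

Averaging is number-weighted on the volume-normalized P (each particle's
amplitude is normalized by its own volume).  Intensity (V²) weighting is
not applied; users who need it can fold the extra R⁶ moment into a
modified distribution.

**Per-dimension convention.**  Shapes whose amplitude factorizes carry an
independent Schulz factor per characteristic dimension: cylinder radius ⊥
length, disk diameter ⊥ thickness, parallelepiped edges.  Ellipsoids are
polydispersed by a single shape-preserving scale factor (one Gamma law
multiplying all semi-axes): independent semi-axis laws would break the
single-profile rescaling R_eff(θ,φ) that keeps the per-q work elementary,
and a shape-preserving ensemble is the physically common description of
grown nanoparticles.  The integration oracle implements exactly the same
convention, so the 10⁻⁴ comparison is a statement about the numerics, not
about model choices.

## The three regimes

* **Regime I** — the squared-amplitude single sum
  P_d(x) = Σₙ Aₙ (−x²/4)ⁿ with
  Aₙ = (d+n+1)ₙ / (n! ((d+2)/2)ₙ²); polydispersity multiplies term n by
  (z+1)₂ₙ/(z+1)²ⁿ.  Coefficients, Pochhammer ratios and moments all
  advance by two-term recursions.  Summation stops after two consecutive
  terms fall below tol·|sum| (a single small term of an alternating
  series can be accidental); a dynamic-range guard (default 10¹²) aborts
  the series when cancellation would destroy the result.
* **Regime II** — F_d's Hankel-type asymptotic expansion with
  coefficients c_k = (−1)^k Π_{i≤k}(d² − (2i−1)²)/(k!8^k), squared and
  averaged term by term with the closed-form damped cosines.  Two terms
  are kept for d = 1, 3 (the expansion terminates: c₂ = 0, so Regime II
  is *exact* there), three for d = 2, where the k = 2 term
  (c₂ = −15/128) is required to push the envelope-relative error to
  ~0.2/x³ and open an overlap window with the cancellation-limited
  series at the 10⁻⁴ level.
* **Regime III** — the non-oscillating terms of Regime II only.  For
  spheres the leading term is the classic polydisperse Porod constant
  9(z+1)⁴/(2z(z−1)(z−2)(z−3))·(qR̄)⁻⁴; subleading non-oscillating
  corrections (e.g. (qR̄)⁻⁶) are kept as well.

Switch points are found at build time by scanning a logarithmic grid:
q₁₂ is the largest point where series and asymptotic evaluations agree
within the boundary tolerance (default 10⁻⁵) with the cancellation guard
silent; q₂₃ is the smallest point beyond which Regime II and the Porod
part stay within tolerance over the following decade.  At the boundary
the lower regime wins.  If no window exists at the tolerance the search
retries at 10× with a warning.  The achieved mismatches are recorded in
`RegimeBoundaries.precision`.

Domain of validity: the Regime II term table needs inverse size moments
up to order d+1+2(n_terms−1), so the polydispersity must satisfy z > 5
for spheres and z > 6 for the d = 2 cross-section — i.e. σ ≲ 0.38.
Wider distributions are rejected at construction.

**Precision.** In double precision the series matches the closed forms to
10⁻¹⁰ only while the dynamic range of the alternating sum stays below
~10⁶ (x ≲ 3–7 depending on d); beyond that, rounding grows as
(max term/sum)·ε and reaches ~10⁻⁶ at the top of Regime I.  The
agreement criterion that places q₁₂ automatically restricts the series to
where it is still accurate at the boundary-tolerance level, which is what
keeps the end-to-end error of the regime-switched evaluator below 10⁻⁴
(measured: ≤ 7·10⁻⁶ on all six benchmark shapes at σ = 0.1).

## Shape assembly

Anisometric bodies are products of 1D profiles evaluated at
direction-dependent arguments and averaged over a fixed Gauss–Legendre
orientation grid (96 nodes for one angle, 80×80 for two), built once:

| shape                | factors                         | orientation nodes |
|----------------------|---------------------------------|-------------------|
| sphere               | (d=3, R)                        | —                 |
| cylinder             | (d=2, R) × (d=1, L/2)           | cos α ∈ [0,1]     |
| disk                 | (d=2, D/2) × (d=1, T/2)         | cos α             |
| lamella (1 size)     | (d=1, T/2)                      | — (layer normal)  |
| biaxial ellipsoid    | (d=3, 1) at q·R_eff(θ)          | cos θ             |
| triaxial ellipsoid   | (d=3, 1) at q·R_eff(θ,φ)        | (cos θ, φ) octant |
| cube/parallelepiped  | three (d=1, edge/2) at q·|μ_i|  | (cos θ, φ) octant |

The cylinder length convention: the d = 1 profile's characteristic size
is the *half*-length, so its n = 1 series term matches the sinc²
expansion of a rod of full length L.  The Gauss–Legendre orders were
fixed by a convergence study against the oracle (errors ≤ 2·10⁻⁶ at the
chosen orders on 30-decade grids); endpoint clustering of the nodes
resolves the facet-normal peaks of the cube integrand at high q.

The single-size "disk_lamella" is the layer-normal form factor of a
lamellar stack, not an orientational average; it decays as q⁻² and has no
q⁻⁴ Porod constant (porod_limit refuses it).

## Oriented assemblies

For a uniaxial orientation distribution h(δ) about a director along x,
the q-independent moments H_{2l,2m} = ⟨cos^{2l}δ sin^{2m}δ⟩ are
quadratured once (analytic for perfect alignment).  The longitudinal
phase average of a cylinder is available as the pre-computed double
series Σₙ aₙ Σ_l b_{l,n}(q_x²)^l(q_y²)^{n−l} with
b_{l,n} = 4^l H_{2l,2n−2l} / ((2l)!((n−l)!)²); it converges in the
low-to-intermediate phase region and is tested against the direct node
average.  The full oriented evaluator `pq_oriented` uses a joint average
over pre-computed (δ, χ) Gauss–Legendre/trapezoid nodes of the *product*
of the two analytically size-averaged factors (longitudinal phase
q_x cos δ − q_y sin χ sin δ per unit half-length; transverse argument
√(q² − (q·L̂)²)).  A strictly factorized longitudinal × transverse form
was rejected because ⟨AB⟩ ≠ ⟨A⟩⟨B⟩ over orientations: it would break the
exact reduction of the isotropic orientation distribution to the 1D
powder average, which the joint form satisfies to ≤ 1.5·10⁻⁵.
The gaussian cone density is h(δ) ∝ exp(−δ²/2w²) on [0, π/2]; the order
parameter S = (3⟨cos²δ⟩ − 1)/2 spans 1 (delta) → 0 (isotropic) and
decreases strictly with the cone width.

## Lattice factor

Reciprocal vectors use the 2π convention and are built by inverting the
rotated real-space basis (duality residuals < 10⁻¹⁰); the requested (uvw)
cell direction is rotated onto the beam axis, which is how (hk0)-fiber
patterns arise for beam ∥ (001).  Reflections are enumerated with the
standard extinction rules (FCC: uniform parity; BCC: h+k+l even; custom
basis: explicit |Σ e^{iq*·r}|²), with f² normalized to 1 for allowed
reflections.  Peaks are unit-integral 3D profiles (Gaussian, Lorentzian
or pseudo-Voigt mix) with a finite support radius (8.5σ Gaussian, 60σ
when a Lorentzian fraction is present) used both to skip far reflections
in the 2D evaluator and, *consistently*, as the integration bound of the
analytic powder line shape — so the 1D powder factor is the exact
spherical average of the truncated 3D factor (verified to 1%
against numeric orientation averaging).  Z is normalized to baseline 1
far from all peaks so the decoupling term (⟨Z⟩ − 1) vanishes there; the
overall peak-height scale is a peak-width-dependent convention, adequate
for pattern simulation but not for absolute Bragg intensities.  The
Debye–Waller factor is G = exp(−σ_DW²q²).

## Detector, PSF, GISAS

Pixel centers sit at (index + 0.5 − beam_center)·pixel size; the
small-angle map is q = 2π/(λd)(x, y, 0) and the exact map uses the unit
scattered direction (transverse components ∝ cos ϑ, q_z ∝ 1 − cos ϑ).
Isotropic ⟨P⟩, ⟨F⟩ and powder Z are tabulated on a 4096-point radial grid
and interpolated onto pixels (interpolation error far below the 10⁻⁴
budget at this density).  PSF convolution is direct summation with edge
replication and requires a unit-sum kernel.

GISAS uses the four-channel DWBA: channels share in-plane momentum and
take the four sign combinations ±k_z,f ∓ k_z,i; T_i, R_i are scalars,
T_f, R_f vary per detector row; rows below the horizon are dark.
Fresnel amplitudes use n = 1 − δ + iβ in the grazing approximation
k_z,t = k√(sin²α − 2δ + 2iβ), giving |T|² = 4 at the critical angle
(the Yoneda band) and total external reflection as α → 0.  A single film
on a substrate is modelled; multilayers and the incident-plane
specular/diffuse terms are out of scope.

## The oracle

The reference implementation evaluates the nested size/orientation
integrals directly: converged Gauss–Legendre panels on the 8σ size window
(weights from the Schulz density, renormalized) and order-doubled
Gauss–Legendre for the orientation angles, with only the closed-form
amplitudes inside the integrand — none of the series, asymptotic or
closed-form-average machinery.  Its nested dimensionalities are 1
(sphere), 2 (biaxial ellipsoid), 3 (cylinder, disk, triaxial ellipsoid)
and 5 (parallelepiped: three edges + two angles).  A stratified
Monte-Carlo estimate over the joint space cross-checks the 5D case with a
reported standard error.  The oracle is the slow reference by design;
`compare()` reports per-regime deviations, wall times and the speedup.

## Problem sizes and defaults

Validation grids are 200 points spanning qR ∈ [0.05, 30] (Guinier to
Porod); benchmark polydispersity σ = 0.1 and moderate axial ratios 3–8;
reference 2D patterns 256×256 (2k/4k supported).  Default tolerances:
series build 10⁻⁶, boundary overlap 10⁻⁵, end-to-end target 10⁻⁴,
oracle 10⁻⁶.  Fixture presets: spheres R = 3 nm σ = 0.08; triaxial
ellipsoid a,b,c = 2,4,6 nm; oriented cylinders spanning S ≈ 1 → 0;
FCC-ordered spheres R = 14 nm, a = 35 nm; BCC film R = 10 nm, a = 22 nm,
beam ∥ (001), critical scattering vector q_z,c ≈ 0.23 nm⁻¹
(α_c ≈ 0.33° at λ = 0.1 nm).

## What the tests do and do not show

The synthetic fixtures exercise ideal particles: uniform density, exact
Schulz size laws, uncorrelated size/orientation/position, noise-free
detectors.  Passing tests demonstrate numerical correctness of the
averaging machinery against an independent integration route — they do
not validate the decoupling approximation itself against strongly
correlated real samples, instrument resolution beyond a PSF kernel,
absolute intensity calibration, or multiple scattering.  Timing
assertions are trend-only (plateau at low N, growing speedup); absolute
factors depend on hardware.

## Known limitations

* Polydispersity domain σ ≲ 0.38 (z > 6); very narrow distributions
  (σ ≲ 0.03) push the Porod regime beyond the boundary scan and fall
  back to Regime II evaluation everywhere above q₁₂ (correct, merely
  slower per point).
* Superballs, superellipsoids, dumbbells, lenses, octahedra, polymer
  chains and core–shell profiles are out of scope.
* The oriented evaluator covers cylinders/disks; oriented ellipsoids and
  parallelepipeds would need their own phase tables.
* Lattice disorder is a single peak-width parameter plus Debye–Waller
  damping; no paracrystalline models or Scherrer size analysis.
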