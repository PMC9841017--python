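# hyperscat

Fast computation of small-angle scattering (SAXS/SANS) curves and 2D
detector patterns for assemblies of geometrical particles — spheres,
cylinders, disks and lamellae, biaxial and triaxial ellipsoids, cubes and
parallelepipeds — with size polydispersity, uniaxial orientation
distributions, crystalline order (SC/BCC/FCC lattice factors) and a
grazing-incidence (GISAS/DWBA) extension.  A brute-force
numerical-integration oracle ships alongside the fast engine and verifies
its 10⁻⁴ relative precision.

## Who this is for

Scattering practitioners who need per-pixel model intensities fast: fitting
large 1D data sets, simulating 2D patterns for anisotropic or ordered
samples, or generating synthetic training data — cases where the
conventional route (nested numerical integration of the orientation and
size averages for every q-point) is the bottleneck.

## The method

The volume-normalized scattering amplitude of a body that is rotationally
symmetric in *d* dimensions is a confluent hypergeometric limit function,

    F(q) = ₀F₁((d+2)/2; −q²R²/4),

which reduces to sin(x)/x (d=1, lamellae), 2J₁(x)/x (d=2, cylinder
cross-sections) and 3(sin x − x cos x)/x³ (d=3, spheres) with x = qR.
Because ₀F₁ has both a power series and a rapidly convergent asymptotic
(Hankel-type) expansion, the size- and orientation-averaged form factor

    ⟨P(q)⟩ = ⟨|F(q)|²⟩_{R, Ω}

can be evaluated without any per-q integration:

* **Regime I (low q):** a single-sum power series Σₙ cₙ q²ⁿ whose
  coefficients cₙ absorb the Schulz–Zimm size moments
  (z+1)₂ₙ/(z+1)²ⁿ (z = 1/σ² − 1) and are generated once by recursion —
  no special functions.
* **Regime II (high q):** the squared asymptotic expansion averaged term
  by term over the Gamma size law in closed form (damped cosines and
  arctan terms).  The expansion terminates for d = 1, 3, so this regime
  is exact there.
* **Regime III (very high q):** the non-oscillating part only — the
  Porod q⁻⁴ tail, which for polydisperse spheres is
  9(z+1)⁴ / (2z(z−1)(z−2)(z−3)) · (qR̄)⁻⁴.

The switch points q₁₂, q₂₃ are located automatically where the regimes
overlap within tolerance.  Anisometric bodies are assembled from one to
three such 1D profiles evaluated at direction-dependent arguments, with
the orientation average on a fixed Gauss–Legendre node set that is also
q-independent.  Full detector intensities follow the decoupling
approximation

    I(q) = (Δb)² ρ_N ⟨P⟩ [1 + (⟨F⟩²/⟨P⟩)(⟨Z⟩ − 1) G(q)],

with Z(q) the lattice factor (normalized Bragg peaks over the reciprocal
lattice, baseline 1) and G the Debye–Waller factor.  Grazing-incidence
patterns use the four-channel distorted-wave Born approximation with
Fresnel transmission/reflection factors.

## Worked example

```python
import numpy as np
import hyperscat as hs

# polydisperse spheres, R̄ = 3 nm, σ = 0.08
model = hs.precompute(hs.ShapeSpec("sphere", (3.0,)),
                      [hs.SizeDistribution(3.0, 0.08)])
print("q12 =", round(model.boundaries.q12, 3),
      " q23 =", round(model.boundaries.q23, 3))
for q in (0.0, 0.5, 2.0, 6.0, 12.0):
    print(f"P({q}) = {hs.pq_iso(model, q):.6e}")

from hyperscat.oracle import compare, OracleConfig
rep = compare(model, OracleConfig(), np.geomspace(0.0167, 10.0, 100))
print(rep.to_text())
```

prints

```
q12 = 4.52  q23 = 10.478
P(0.0) = 1.000000e+00
P(0.5) = 6.274687e-01
P(2.0) = 5.933062e-03
P(6.0) = 4.496243e-05
P(12.0) = 2.860407e-06
form-factor validation report
  points            : 100
  q-range (nm^-1)   : 0.0167 .. 10
  max rel deviation : 5.976e-06
  mean rel deviation: 7.021e-08
  fast route time   : 0.0003 s
  oracle time       : 0.0021 s
  speedup           : 7.3x
  regime I    max dev: 5.976e-06
  regime II   max dev: 6.653e-12
  regime III  max dev: 0.000e+00
```

The switch points (nm⁻¹) are found at build time; P(q) is the normalized
averaged form factor (1 at q = 0, decaying through the Guinier region into
the Porod tail), and the report shows the fast engine agreeing with the
brute-force integration oracle to a few parts in 10⁶ across all three
regimes — well inside the 10⁻⁴ design tolerance.  The speedup grows
steeply for anisometric shapes, where the oracle needs up to five nested
integrations per point.

## Command line

```
scatter curve1d   --preset sphere_r3        --out curve.dat
scatter pattern2d --preset fcc_spheres      --out fcc        # .tif/.txt/.meta.txt
scatter gisas     --preset bcc_film_gisas   --out film
scatter validate  --preset sphere_r3                         # engine vs oracle
scatter benchmark --shapes sphere,cylinder,cube --n-points 100,1000,10000
```

Configuration is a flat TOML file with units in the key names
(`radius_nm`, `wavelength_nm`, `distance_mm`, ...); any key can be
overridden with `--set key=value`.

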