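# Methods

## Morphoelastic model

Tissue loss is prescribed, not predicted: a retention factor υ(x, t) ∈
(0, 1] gives the fraction of original volume each material point keeps.
The deformation gradient splits multiplicatively, F = Fᵉ·Fᵃ with
Fᵃ = υ^{1/3} I, so the atrophy part is an isotropic, stress-free shrink
and only the elastic accommodation Fᵉ = F/υ^{1/3} is penalized by the
stored energy. Stress follows from a compressible neo-Hookean energy

W(Fᵉ) = μ/2 (tr bᵉ − 2 − 2 ln Jᵉ) + κ/2 (ln Jᵉ)²,

giving the Cauchy stress σ = (1/Jᵉ)[μ(bᵉ − I) + κ ln Jᵉ · I]. The elastic
response is quasi-incompressible through the bulk-to-shear ratio κ/μ
(default 100, configurable); the atrophy shrink itself changes volume by
design. Equilibrium is div σ = 0 with the brainstem boundary fixed, every
other boundary traction-free, and ventricles modeled as interior voids.

### Plane reduction

All tensors are in-plane 2×2. The per-direction atrophy stretch υ^{1/3} is
applied in-plane, hence Jᵃ = det Fᵃ = υ^{2/3} and Jᵉ = J/υ^{2/3}. Under
this convention a free body shrinks linearly by υ^{1/3}, exactly as each
direction of a 3D body would, and a focal υ = 0.5 predicts a free-shrink
cortical thinning of ≈ −21%. The alternative reading — carrying the 3D
relation Jᵉ = J/υ into the plane, so in-plane area shrinks by the full υ —
over-shrinks a 2D slice (every free length by υ^{1/2}) and is not used.
Whether the plane problem should be viewed as plane strain or plane stress
is deliberately left open; the model is a pure 2D continuum, and the von
Mises stress is evaluated on the 3×3 embedding of σ with zero out-of-plane
components. Note this convention makes an in-plane hydrostatic state carry
a nonzero von Mises value equal to |p|; a plane-strain σ₃₃ = ν(σ₁₁+σ₂₂)
alternative would reduce it, but the fixed zero-σ₃₃ convention is simple
and testable and is what all reported numbers use.

### Material parameters

| parameter | default | units | note |
|---|---|---|---|
| μ_gray | 2.07 | kPa | triaxial human-tissue data |
| μ_white | 1.15 | kPa | triaxial human-tissue data |
| κ/μ | 100 | – | quasi-incompressible elastic response |

## Atrophy schedules

Generalized atrophy targets the whole brain: default endpoints
υ_gray(48 mo) = 0.80, υ_white = 0.90. Endpoint mode interpolates υ
geometrically, υ(t) = υ_end^{t/T}, so each increment applies the same
relative shrink and the endpoint is exact for any increment count; rate
mode accumulates linearly (υ = 1 + rate·t) from the reported monthly rates
(−0.4%/−0.2% per month). The two parameterizations are mutually
inconsistent at the endpoint (linear −0.4%/mo over 48 mo gives −19.2%, not
−20%); endpoint mode is the default because the endpoint values are the
ones the headline figures are tied to. Focal schedules atrophy a single
tissue or named subregion (cortical-ribbon, deep-gray, callosal-band) and
leave υ ≡ 1 elsewhere.

## Discretization and solver

Linear triangles with one-point (centroid) quadrature — exact for
constant-strain elements. Each increment is solved by Newton's method with
the consistent tangent ∂P/∂F (first Piola-Kirchhoff form), full steps plus
a backtracking line search (halving, ≤8), and recursive increment
bisection (≤3 levels) on non-convergence. Linear solves use a sparse
direct LU factorization; Dirichlet constraints are eliminated by
row/column reduction, so the unconstrained problem size is two unknowns
per node. Default tolerances: residual norm ≤ max(1e−10, 1e−8 × the first
iterate's norm). Inverted elements during assembly raise immediately with
the element index; a singular tangent (typically missing constraints) is
reported as such.

Pure-displacement linear triangles are known to lock volumetrically as
κ/μ grows. At the default κ/μ = 100 the displacement field is accurate
(verified against the analytic free shrink and the annulus oracle), but
the raw element pressure carries a spatially oscillating (checkerboard)
mode. Output stresses therefore use a standard recovery: the in-plane
pressure is projected to nodes by area-weighted averaging and
re-interpolated to centroids, while the element-wise deviator is kept.
The recovery is exact for constant stress fields (the patch test passes
unchanged) and does not alter the equilibrium solution; pointwise
`mechanics.cauchy_stress` remains the unmodified constitutive formula.
The annulus verification runs at κ/μ = 1000 on a crossed (union-jack)
polar mesh, the standard locking-free triangle arrangement, and matches
the incompressible-limit kinematic solution r(R)² = υc^{2/3}A² + R² − A²
to well under 2%.

## Synthetic slice generator

The generator emulates what the simulator needs from an adult brain slice,
not anatomy per se:

* an oval envelope (sagittal 165×120 mm, coronal 140×120 mm);
* a folded pial surface with slit-like sulci: inward notches of depth
  profile A·exp(−k(1+cos φ)) along the envelope arclength (depth A = 15 mm,
  pitch 18 mm, sharpness k = 6, giving sulcal gaps of ≈1.5–3.5 mm across
  the sampled depths) with a random phase drawn from the `SliceSpec` seed
  and a taper to zero near the brainstem;
* a cortical gray ribbon of constant thickness (4 mm) inward of the pial
  curve, with mesh nodes inserted along the ribbon offset curve so the
  gray/white interface is crisp;
* lateral ventricles as slender slit voids (coronal: two 13×4 mm tilted
  ellipses; sagittal: one 22×5 mm) surrounded by an 8 mm deep-gray shell
  (caudate/thalamus analog, subregion `deep-gray`);
* a brainstem region: an inferior stub (sagittal) or a chord recessed
  18 mm between the temporal lobes (coronal — coronal sections cut the
  midbrain well above the temporal poles, which is what makes coronal
  endpoint displacements roughly half the sagittal ones at equal atrophy).

Meshing: boundary and interface curves are sampled at the target edge
length, interior points come from a hexagonal lattice, the triangulation
is a Delaunay tessellation filtered by centroid containment with Laplacian
smoothing, and boundary edges are classified by nearest boundary curve.
Default edge length 1.6 mm yields ≈10k (coronal) and ≈13k (sagittal)
elements. Generation is deterministic for a fixed spec including its seed.
Sulcal landmark pairs (opposing wall points at 25/50/75% of each fold's
depth) are snapped to pial nodes at build time and advected with the
deformation, so sulcal width needs no registration.

What the generator does **not** emulate: hemispheric asymmetry, named
gyri/sulci, subcortical nuclei beyond a generic periventricular shell, CSF
as a material, and — most importantly — the rigid skull. Consequences are
discussed under Limitations.

## Morphometry

* **Cortical thickness** — ≥256 points uniform in arclength on the
  deformed pial boundary (excluding 10% of arclength at each brainstem
  end), each measured as the distance to the nearest point of the deformed
  gray/white interface; the mean is reported, and thinning is the percent
  change of the mean against the undeformed mesh. A normal-ray definition
  was considered and rejected: nearest-distance is unambiguous at fundi.
* **Ventricle area** — shoelace area of the deformed ventricular loops;
  self-intersecting deformed loops set a warning flag rather than raising.
* **VBR** — ventricular area / (tissue area + ventricular area).
* **Sulcal width** — distances between the advected landmark pairs.
* **Maxima** — max nodal |u| and max element von Mises per increment
  ("deformation up to x mm" is read as the maximum displacement
  magnitude).

All metrics are rigid-motion invariant (tested to 1e−9).

## Verification battery

1. free shrink: homogeneous square, uniform υ, rigid modes pinned →
   side ratio υ^{1/3} ± 1e−4, von Mises ≤ 1e−6 μ;
2. patch test: affine boundary displacement, υ ≡ 1 → constant stress to
   1e−8 kPa (with a deliberately corrupted gradient operator as the
   negative control);
3. finite differences: residual vs energy gradient (≤1e−6 relative),
   tangent vs residual Jacobian (≤1e−5);
4. Newton rate: observed convergence order > 1.5 over the final
   contractions above the round-off floor;
5. annulus oracle (above), plus a three-level mesh-convergence study with
   monotonically decreasing error.

## Design choices in brief

* υ is uniform within each labeled region per increment; no spatial
  grading inside a region.
* Endpoint schedules are the default stepping (see Schedules).
* Geometric υ stepping means every increment is equally severe, which is
  why 48 increments run robustly even at focal υ = 0.5.
* The generator's fold and ventricle defaults were set from adult anatomy
  (sulcal depth/pitch, slit-like ventricle cross-sections, periventricular
  gray) after sinusoidal open sulci and elliptical ventricles proved
  unable to reproduce the directional behavior of the clinical patterns;
  the mechanism is documented under Limitations.

## Limitations

* **Free outer boundary.** With a traction-free pial surface the slice
  contracts globally toward the fixed brainstem by ≈5% linear at the
  generalized endpoint. An interior void encircled by shrinking tissue
  then shrinks with it: absolute ventricular enlargement cannot emerge in
  this model class, because every mechanism available (uniform shrink,
  a shrinking periventricular ring, cortical shell tension) compresses
  interior holes. Clinically, enlargement is enabled by the rigid skull
  and CSF replacement, both outside scope. The simulated ventricles
  accordingly shrink slightly less than — or comparably to — the
  surrounding tissue; relative (per-volume) enlargement is geometry
  dependent. Sulcal widths sit on a knife edge between gray wall
  recession (widening) and global gyral convergence (narrowing), and
  individual sulci go either way.
* **Thinning under focal atrophy.** The quasi-incompressible substrate
  blocks part of the ribbon's tangential contraction, so focal gray
  υ = 0.5 thins the cortex by ≈ −27% rather than the free-shrink −21%;
  the balance depends on fold depth relative to gyral pitch.
* **Maximum-of-field statistics.** Max von Mises is the most
  mesh- and seed-sensitive reported number (±10% across fold phases at
  the reference resolution); percentile summaries are stabler.
* Sulcal walls may interpenetrate at extreme focal atrophy; contact is
  detected (self-intersection warnings) but not resolved.
* No dynamics, viscoelasticity, anisotropic atrophy along fiber
  directions, or damage-driven atrophy coupling; 2D only.
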