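# Methods

## The lifted field

A diffusion tensor D(y) (symmetric positive-definite, mm²/s) is converted to a
spherical profile per voxel using the solid-angle orientation density function
obtained by radially integrating the Gaussian diffusion propagator:

    psi_y(n) = (4π √det D)⁻¹ (nᵀ D⁻¹ n)^(−3/2),   ∫_{S²} psi_y dσ = 1.

Multiplying by a spatial density μ(y) ∝ √det D(y) (the tensor-ellipsoid
volume) cancels the determinant, so the lifted field is simply
U(y, n) = (4π)⁻¹ (nᵀ D⁻¹ n)^(−3/2).  The global constant is irrelevant: the
pathway score only uses U relative to its global maximum.  The diffusion-time
constant of the Gaussian propagator cancels in the same step and is not a
parameter.

Orientations are unit vectors sampled on a geodesic icosphere; order k uses
edge frequency k+1, i.e. 10(k+1)²+2 vertices (92 at order 2, the default used
for processing and scoring).  Per-vertex quadrature weights are one third of
the incident spherical-triangle areas (l'Huilier), summing to 4π exactly.
Angular derivatives are mesh-based: a cotangent Laplacian lumped with the
quadrature weights (Laplace–Beltrami; the degree-1 eigenvalue −2 is
reproduced to 4% at order 3), and a tangent-plane least-squares gradient for
the erosion.  No spherical-harmonic machinery is used anywhere.

### Accuracy limit of the vertex quadrature

For tensors with eigenvalue ratio ≳ 14 the ODF peak (half-width ≈ 0.14 rad) is
narrower than the order-3 vertex spacing (≈ 0.28 rad) and the quadrature sum
of psi deviates from 1 by up to ~3%; for ratios < 10 it is within 1%.  This is
a resolution limit, not a weight defect (spherical-Voronoi weights are
slightly worse), and it converges away by order 5.  The tests assert exactly
these bounds.

## Contour enhancement

The linear contour-enhancement evolution on R³ × S²,

    ∂W/∂t = D³³ (A₃)² W + D⁴⁴ Δ_{S²} W,

transports mass along each orientation's own spatial direction (A₃ is the
spatial derivative along n, taken in the frame attached to n so the operator
commutes with rigid motions) and diffuses isotropically on the sphere.  The
discretization follows forward Euler with centered second differences: the
samples at y ± h·n (h = one voxel; anisotropic voxel sizes scale the offset
per axis) are obtained by trilinear interpolation with replicate-edge
boundaries, and the angular term is the mesh Laplacian.  The time step is
0.4 × min(h²/2D³³, positivity bound of the angular update), which keeps the
explicit update matrix non-negative — the evolution is then exactly linear,
mass-conserving on interior-supported fields (measured: < 10⁻⁵ relative
drift), positivity-preserving, and antipodally-symmetry-preserving.  With
D⁴⁴ = 0 a point source spreads as the closed-form 1-D heat kernel along its
own axis (< 1% relative L2 at t = 1).

### Green's kernel and shift–twist convolution

Because the evolution is left-invariant, running it equals group (shift–twist)
convolution with its impulse response.  The kernel is computed numerically by
evolving a unit-mass delta (placed at the box center on the vertex nearest
+z; the kernel's reference axis is that vertex itself, since +z is not a
vertex at every order).  Convolution rotates the kernel with each source
orientation: spatial lookup by nearest voxel, angular lookup by nearest
vertex.  Nearest (rather than interpolating) lookups keep a rotated delta a
delta; the residual identity error of a pure delta kernel is the quadrature
weight-class ratio between pentagonal and hexagonal vertices, which the tests
assert exactly.  On an order-1 field with D³³ = 1, D⁴⁴ = 0.4, t = 1 the two
routes agree to 4–5% relative L2, improving with tessellation order; for
kernels much narrower than the vertex spacing the rotation resampling
dominates and agreement degrades, so the cross-validation runs in the
resolved regime.

## Erosion

Sharpening uses the morphological (Hamilton–Jacobi–Bellman) evolution

    ∂W/∂t = −(2η)⁻¹ [ D¹¹ (|∇_{e1}W|² + |∇_{e2}W|²) + D⁴⁴ |∇_{S²}W|² ]^η,

which shrinks level sets inward, spatially in the plane perpendicular to each
orientation and angularly on the sphere.  Spatial gradients use the
Rouy–Tourin upwind selection max(backward, −forward, 0) per axis, projected
onto the plane perpendicular to n; the angular term is the squared
least-squares mesh gradient.  The step size is adaptive (per-step decrement
capped at 5% of the initial maximum); values are clipped at zero.  Erosion is
pointwise non-increasing, fixes constant fields exactly, preserves antipodal
symmetry, and strictly increases the peak/mean ratio of single-bump profiles.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| tessellation order | 2 (92 dirs) | – | orientation resolution |
| D³³ | 1.0 | voxel²/time | spatial transport of enhancement |
| D⁴⁴ (enhancement) | 0.02 | rad²/time | angular diffusion |
| t_end (enhancement) | 0.25 | time | stopping time |
| D¹¹ | 0.4 | – | spatial erosion weight |
| D⁴⁴ (erosion) | 1.0 | – | angular erosion weight |
| η | 1.0 | – | Hamiltonian homogeneity (≥ ½) |
| t_end (erosion) | 1.0 | time | erosion time |
| FA mask | ≥ 0.25, or ≥ 0.15 with MD ≤ 1.5·10⁻³ mm²/s, dilate 1 | – | white-matter mask |
| λ | 0 | – | internal-energy weight |
| ε | 0.05 | – | length penalty |
| floor | 10⁻⁶ | – | lower clip on u/U_max |
| resampling step | 1 mm | mm | pathway arclength spacing |

The PDE defaults were calibrated on the default synthetic phantom by
maximizing the plausibility-discrimination margin of approach B over the
unprocessed field — the same role the healthy-control data plays in a clinical
deployment of this pipeline, where processing parameters are optimized on
training subjects before being applied to patients.  At 2 mm voxels the
enhancement defaults correspond to ≈ 1.4 mm of spatial smoothing along each
orientation and ≈ 6° of angular smoothing; the erosion is predominantly
angular (D¹¹/D⁴⁴ = 0.4).

## Scoring and evaluation

The data term is the length-normalized sum of log(u/U_max) over interior
samples with Δs = L/N_interior, i.e. exactly the mean log-support: a pathway
with constant support c scores log c regardless of length, and the score is
invariant under global scaling of the field.  Endpoints are excluded (they
typically sit in grey matter).  The internal term Σ(κ² + ε)Δs is *not*
length-normalized; with ε > 0 it penalizes length, and λ weights it against
the data term (default 0: data only).  The angular lookup is antipodal, since
tensor-derived fields are symmetric and streamline orientation is arbitrary.

Critical-threshold evaluation: the threshold is the smallest cut retaining no
implausible pathway (specificity 1); sensitivity is the plausible fraction
retained.  If the top-scoring pathway is implausible the method is flagged
inadequate (sensitivity 0).  An exhaustive sweep over all distinct cuts is
used as the test oracle.  ML-TP / ML-IH anterior-extent metrics measure the
signed gap between the bundle's most anterior point and the temporal-pole /
inferior-horn landmarks along a given anterior axis; ML-IH is negative when
the bundle edge lies posterior to the landmark (ML-TP is positive in the
same configuration, matching the anatomical convention).

## The synthetic phantom

The phantom emulates the geometry that defeats tractography of the optic
radiation on a 24×24×12 grid of 2 mm voxels: a C-shaped bundle (straight leg →
half-turn arc of 6 mm radius → straight leg, tube radius 4 mm) of prolate
tensors whose principal axis follows the local centerline tangent and whose
eigenvalues realize FA 0.8 at trace 2.1·10⁻³ mm²/s; a straight crossing
bundle through both legs, averaged tensor (planar, reduced FA) in the
overlap; isotropic background (MD 0.7·10⁻³); and seeded noise on the tensor
eigen-parameters — multiplicative log-normal on the eigenvalues *and* a random
rotation of the eigenvectors with angle ~ N(0, σ) rad, σ = 0.15.  The
orientation jitter matters: clinical DTI never has exact principal
directions (direction uncertainty is why bootstrap dispersion maps exist),
and without it the unprocessed field is a near-oracle that contextual
processing cannot improve.

Candidate tracts (200 plausible + 200 implausible by default, seed 42):
plausible ones perturb the centerline smoothly and are verified to stay in
the tube; implausible ones (40% bend-shortcuts, 30% background wanderers, 30%
crossing-switches) are verified to leave it.  What the phantom does *not*
emulate: raw DWI signal and Rician noise, partial-volume averaging of tensors
within voxels, CSF compartments, real anatomical variability, and
probabilistic-tracker sampling density.  Passing the end-to-end test
therefore shows that the processing chain improves plausibility
discrimination under direction noise, crossings, and a sharp bend — not that
it reproduces clinical effect sizes.

On the default phantom, sensitivity at specificity 1 is 0.915 on the
unprocessed field and 0.960 after approach B (the acceptance script recomputes
both).  Across other noise realizations the margin varies (positive in 5 of 8
seeds tried; it can be negative when a crossing-switch candidate draws a
particularly favorable realization) — consistent with a method whose
parameters are tuned per study on training data.

## Numerical choices and degenerate inputs

- Vertex deduplication tolerance 10⁻¹⁰; nearest-direction ties break to the
  lowest index.
- Min–max normalization maps constant profiles to zero (degenerate
  denominator).
- Pathways shorter than 4 points fall back to a lower-order spline; endpoint
  curvatures are copied from the nearest interior sample (Frenet–Serret is
  unstable at boundaries).
- Consecutive duplicate points are merged on input; single-point streamlines
  are dropped with a warning.
- Out-of-grid pathway samples contribute zero with a warning; a pathway
  entirely outside the field is an error.
- Enhancement uses replicate-edge (Neumann) boundaries, convolution zero
  padding; mass statements therefore hold on interior-supported fields.

## Known limitations

- The vertex-sampled quadrature under-resolves ODF peaks at eigenvalue ratios
  ≳ 14 on order-3 tessellations (see above).
- The discrete group convolution carries a per-weight-class factor for
  kernels at the angular resolution limit; use the direct finite-difference
  evolution (approach B) when the kernel would be near-singular.
- Erosion's adaptive step is conservative; very long erosion times are slow.
- The phantom's end-to-end improvement is realization-dependent at the
  default noise level; the default conditions are fixed and reported, not
  searched per run.
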