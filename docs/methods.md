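# Methods

## Model

`tmsbem` computes the quasistatic electric field induced in a
piecewise-homogeneous volume conductor (a surface-based head model) by a
time-varying external coil.  The coil's primary field is the inductive
field of its elementary current elements,

    E_p(r) = -(mu0 / 4 pi) (dI/dt) sum_j m_j / |r - p_j|,

where `p_j` is an element position and `m_j` its oriented length vector
(direction x length x winding weight).  The conductor responds with a
surface charge density on every conductivity interface; working with the
scaled density `c = rho / eps0` (units V/m), the total field anywhere off
the interfaces is

    E(r) = E_p(r) + (1/4 pi) int_S c(r') (r - r') / |r - r'|^3 dS'.

Approaching an interface, the local charged sheet adds a discontinuous
`-/+ n c/2` on the inner/outer side of the principal-value field, so the
normal field jumps by exactly `c`.  Substituting these limits into the
current-continuity condition `sigma_in n.E_in = sigma_out n.E_out` yields a
second-kind Fredholm equation for `c`,

    c(r)/2 - K(r) n(r) . (1/4 pi) pv-int_S c(r') (r - r')/|r - r'|^3 dS'
        = K(r) n(r) . E_p(r),

with the conductivity contrast `K = (sigma_in - sigma_out) /
(sigma_in + sigma_out)`, `|K| <= 1`.  Any number of closed interfaces is
allowed; each carries its own `(sigma_in, sigma_out)`, so nested shells,
disjoint compartments (eyes, ventricles) and interfaces to air
(`sigma_out = 0`, `K = 1`) are all treated uniformly.

### Assumptions

* Quasistatics: capacitive and propagation effects neglected; tissue is
  piecewise homogeneous and isotropic.  Anisotropy is out of scope.
* Interfaces are closed, orientable 2-manifolds; the outward normal points
  from the "in" medium to the "out" medium.
* Coil models are tables of straight current elements; any table is
  accepted per solve, so deformable coils simply supply a new table (no
  interpolation cache exists anywhere in the pipeline).

## Discretization

The charge density is piecewise constant per triangular facet (zero-order
collocation).  The system matrix is

    A_mn = delta_mn / 2 - (K_m / A_m) n_m . II_{t_m t_n} k(r, r') dr' dr,
    b_m  = K_m n_m . <E_p>_{t_m},

where the inner integral over the source facet is evaluated in closed form
(solid-angle plus edge-potential terms of the uniformly charged triangle;
the self facet's principal value has zero normal component, so
`A_mm = 1/2` exactly for flat facets) and the outer integral is a facet
average by symmetric triangle quadrature.  Defaults and options:

* `quadrature_order` (1, 3, or 7; default 1 = centroid collocation) sets
  the base outer rule.
* Facet pairs closer than `2 (rho_m + rho_n)` (`rho` = facet circumradius)
  refine the observation facet 1:4 recursively, up to depth 3, with the
  centroid rule on the children.  These nearly-touching pairs — e.g.
  across the 2 mm CSF–brain gap of the four-layer sphere phantom, which is
  thinner than a facet edge at the default resolutions — dominate the
  discretization error if integrated naively; the adaptive rule reduced
  the four-layer interior-field error at level 3 from tens of percent to a
  few percent at negligible extra cost.

### Near/far splitting and the precision knob

The matrix-free operator treats far facets as centroid point charges
`q_n = c_n A_n` and replaces pairs with centroid distance below
`eta (rho_m + rho_n)` by the analytic facet averages above.  The base
radius `eta = 5` keeps the monopole far-field error near 1e-4 (the error
falls off as `(rho/d)^2`); for tighter requested precisions the near zone
grows as `eta = 5 sqrt(1e-4 / precision)`, so matrix-free and dense
operator applications agree to the requested precision (verified to 1e-6
against the assembled matrix).  The default operator precision is 1e-4.
Supported levels are 1e-1 … 1e-6.

Far sums run through pluggable backends: an exact pairwise compiled kernel
(always available, default), and a Barnes–Hut treecode
(monopole+dipole+quadrupole node expansions over an octree; the opening
angle is `0.5 precision^(1/3)`, calibrated so the measured global 2-norm
error stays comfortably below the request).  At precisions <= 1e-4 the
opening angle becomes so small that the treecode approaches direct
summation — correct but not faster; the exact backend is recommended
there.

## Solution paths

* **Iterative**: full (unrestarted, unpreconditioned) GMRES on the
  matrix-free operator, relative-residual tolerance 1e-6 by default.  The
  second-kind operator is well conditioned; the four-layer sphere at
  20480 facets converges in ~35 iterations.
* **Direct**: factorize once, solve for many right-hand sides (one per
  coil placement).  `method="dense"` is LU with partial pivoting
  (N <= 20000 by default).  `method="compressed"` is a block-low-rank LU:
  facets are ordered by recursive coordinate bisection into spatial blocks
  (<= 512 facets each); off-diagonal blocks of the L and U factors are
  truncated by SVD at the requested precision as the elimination proceeds,
  so the result is exactly the LU of a block-low-rank approximation of A.
  The claim is a precision-tunable direct solve, not asymptotic
  complexity.  At precision 1e-4 the compressed solution differs from the
  dense one by a few 1e-4 relative.  Factorizations serialize to a
  versioned `.npz` container; solves are bitwise reproducible across a
  save/load round trip (factor layouts are normalized so BLAS/LAPACK take
  identical code paths), and multi-RHS solves process columns
  independently, making them bitwise identical to single solves.

## Field reconstruction and audits

Off-surface fields use the same near/far machinery as the operator, with a
distance guard (points closer than 0.1 circumradius to a facet are
rejected and directed to the two-sided interface evaluation).  On-surface
values are two-sided: `E_in/out = Ec -/+ n c/2` about the continuous part,
so the jump identity `n.(E_out - E_in) = c` holds to machine precision by
construction.  The normal component of the continuous part uses the same
facet-averaged near quadrature as the operator; consequently the
continuity-residual audit `|sigma_in n.E_in - sigma_out n.E_out|`
(normalized by `(sigma_in + sigma_out)` times the RMS surface-field
magnitude) tracks the solver residual: tolerance 1e-4 vs 1e-8 changes the
RMS residual by about four orders of magnitude.

Solution-vs-solution comparisons use the relative 2-norm vector error and
magnitude error over a point set (optionally area-weighted; optional
trimming of a fraction of the largest local errors, default off).  ROI
selection is a closed ball, conventionally 2 cm around the stimulation
target.

## Analytic ground truth

For any spherically symmetric conductivity profile the interior total
field is `E = E_p - grad phi`, where `phi` is harmonic inside the outer
radius R with Neumann data `d phi / d r = r_hat . E_p` at r = R.  The
interior field is independent of the radial profile and has zero radial
component — the classical spherically-symmetric-conductor result — which
makes the homogeneous-sphere solution the ground truth for multilayer
sphere phantoms as well.

`phi` is expanded in real, fully (4 pi) normalized spherical harmonics:
boundary data is sampled on a Gauss–Legendre x uniform-azimuth grid
(2x oversampled by default), projected per degree/order, and the regular
solid-harmonic series is differentiated term by term with stable Legendre
recurrences (`lmax = 60` default).  Numerical safeguards:

* `sin(theta)` is computed from `hypot(x, y)/r`, not `sqrt(1 - cos^2)`,
  which would lose ~8 digits near the poles.
* Within `sin(theta) < 1e-6` of the polar axis (and at the origin) the
  spherical-component synthesis is replaced by central finite differences
  of `phi` (step `1e-5 R`), which is pole-free; the interior radial
  component then vanishes to ~1e-14 of the RMS field at all tested points.
* The spectral tail is estimated at the outermost evaluation radius; a
  tail fraction above 1e-6 raises an error suggesting a larger `lmax`
  (points hugging the surface converge slowly and are caught here).

The solution was validated against two independent oracles: dense BEM on
refined icospheres, and a finite-volume Laplace solve on an axisymmetric
`(r, theta)` grid for a coaxial loop (both in the test suite).

## Synthetic study conditions

The generator produces what the validation needs, so no external data is
required:

* **Head models**: nested icospheres.  The four-layer phantom has outer
  radii 92 / 86 / 80 / 78 mm (scalp, skull, CSF, brain) with
  SimNIBS-style conductivities 0.465 / 0.010 / 1.654 / 0.275 S/m and air
  outside — a standard sphere-phantom layup for TMS solver validation.
  The radii and conductivities are configuration, not ground truth.
  Subdivision level 4 gives 5120 facets per interface (edge ~7 mm).
* **Coils**: a parametric figure-8 (two coplanar 35 mm wings with
  opposite circulation, 64 segments per turn) at `dI/dt = 9.4e7 A/s`,
  placed 1 cm above the pole; and a circular loop for axisymmetric tests.
  Real-data features *not* emulated: anatomical geometry (gyri, thin CSF
  sheets of varying thickness), vendor coil winding details and skin
  effect, segmentation noise, and non-closed or defective meshes.  Passing
  the sphere validation therefore demonstrates correctness of the
  formulation, integration, and solvers — not robustness to segmentation
  artifacts.

Observation points for interior-field comparisons sit on a mid-radius
sphere (r = 50 mm, well inside the innermost interface and outside the
near-surface guard band).

## Problem sizes and measured behavior

The shipped validation uses levels 3 and 4 of the four-layer phantom
(5120 and 20480 facets).  Representative measurements (one CPU core):
GMRES at level 4 converges in 35 iterations; the interior field matches
the analytic solution to ~1.1% (vector) at level 4 and ~3.4% at level 3,
decreasing under refinement as expected of a low-order collocation method
on coarse meshes; iterative and dense-direct fields agree to ~0.03%;
matrix-free and assembled operators agree to the requested precision.

## Known limitations

* Zero-order collocation converges at low order; high accuracy needs fine
  meshes (the adaptive near quadrature removes the thin-gap penalty but
  not the baseline O(h) charge error).
* The dense and compressed direct paths assemble the full matrix first;
  they are capped (default 20000 facets) and make no O(N log N) claim.
* The treecode gains nothing at precisions <= 1e-4 (see above).
* No mesh repair: defective inputs are reported, not fixed.
* Tissue anisotropy, EEG forward extensions, and neuron-activation
  post-processing are out of scope.
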