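# Methods

## Model

The package treats the scalar Amari neural field

    u_t(x, t) = -u + ∫_Ω w(|x - y|) H[u(y, t) - κ] dy,

on an interval `[-L, L]`, a square `[-L, L]²`, or a disc of radius `D`,
with a Heaviside firing rate `H` and threshold `κ`.  The synaptic kernel
`w` is radially symmetric and of Mexican-hat type: a difference of
Gaussians

    w(r) = (1/√(cπ)) [a₁/√b₁ e^{-r²/b₁} - a₂/√b₂ e^{-r²/b₂}],

a top hat (`w₊` for `r ≤ σ`, `w₋ < 0` beyond), or a piece-wise constant
Mexican hat (`w₊` up to `σ₁`, `w₋` up to `σ₂`, zero beyond).  The `c`
parameter of the difference of Gaussians is a pure normalisation and is
kept as given.

A Dirichlet condition `u|∂Ω = u_BC` (constant) is *not* natural for the
integro-differential Cauchy problem; it is imposed by evolving the
gradient `z = ∇u` instead,

    z_t = -z + ∫_Ω ∇ₓ w(|x - y|) H[u(y) - κ] dy,

and defining `u(x) = u_BC + ∫_Γ(x) z · dl` along a path from the domain
boundary to `x`.  The boundary value therefore enters through the
reconstruction anchor.

## Interface reduction

Because `H` is a step function, the right-hand side depends on the state
only through the active region `Ω₊ = {u > κ}`.  The drive
`ψ(x) = ∫_{Ω₊} w(|x-y|) dy` is converted to a contour integral using the
radial antiderivative field `F(y) = φ(|y - x|) (y - x)/|y - x|` with
`∇·F = w`:

    ψ(x) = ∮_{∂Ω₊} φ(|γ(s) - x|) ((γ(s) - x)/|γ(s) - x|) · n(s) ds + K C,

where `φ(r) = (1/r)∫_∞^r s w(s) ds`, `K = ∫_{R²} w`, `n` the outward
normal, and `C ∈ {0, ½, 1}` the winding indicator (the excised
singularity of `F` when `x ∈ Ω₊`).  The sign convention is fixed by the
divergence theorem with *outward* normals and was validated against
direct area quadrature; the integrand direction is `γ(s) − x`, and its
finite limit when `x` is itself a contour point is `−K·curv/(4π)`.

The contour then evolves with normal speed
`c_n = (-κ + ψ)/|z|` on the free plane and
`c_n = (u_BC - κ + ψ(x) - ψ(ζ(x)))/|z|` under clamping, where `ζ(x)` is
the boundary anchor of the reconstruction path through `x`, and `z` on
the contour is recovered from the contour *history*:

    z(x, t) = e^{-t} z₀(x) + ∫₀^t e^{-(t-t')} ∇ψ(x, t') dt',
    ∇ψ(x, t) = -∮_{∂Ω₊(t)} n(s) w(|x - γ(s)|) ds.

The same reduction in 1D gives the classical bump width equation
(`κ = ∫₀^Δ w` on the free interval; `κ = u_BC + P(-Δ/2) - P(-L)` with
clamping, `P` the stationary drive in error-function form), the bump
profile `q(x)`, and a 2×2 edge-perturbation eigenproblem for the
spectrum `λ±`.

A structural fact worth recording: for a *symmetric* bump the 2×2 edge
matrix always has `w(0) − w(Δ)` as an eigenvalue — with or without the
Dirichlet boundary terms — so one eigenvalue of `λ± = -1 + eig` is
exactly zero on every branch.  "Stable" therefore means the remaining
mode is negative (tolerance 1e-10 on `max Re λ`).  The analogous planar
statement is `λ₁ = 0` for spots on the plane, which this implementation
satisfies exactly by construction (below).

## Spots and azimuthal stability

A spot of radius `R` satisfies `κ = u_BC + ψ(R) - ψ(D)` on a clamped
disc (`κ = ψ(R)` on the plane).  For the difference of Gaussians,
`ψ(r)` is an angular quadrature of the ring representation (midpoint
rule, 2048 nodes by default, nodes offset from `θ = 0` where the
integrand has an integrable `1/Q²` structure at `r = R`); accuracy
degrades within `|r - R| ≲ 10 R/n_θ` of the edge, where the integrand
peak narrows below the node spacing — callers needing near-edge values
pass a larger `n_theta`.  For piece-wise constant kernels `ψ` is exact
circle-overlap ("lens") geometry:
`A₊(r; R, σ) = R²(φ₀ - sin φ₀)/2 + σ²(φ₁ - sin φ₁)/2` between the
containment and disjoint regimes.

Azimuthal perturbations `cos(mθ)` of the edge have explicit eigenvalues

    λ_m = -1 + (R/|q'(R)|) [J_m(R, R) - J_m(R, D)],
    J_m(R, r) = ∮ cos(mθ) w(√(r² + R² - 2 r R cos θ)) dθ,

(the `D` term only on the disc).  The edge slope is computed from the
gradient line-integral identity evaluated on the spot edge,

    q'(R) = -R · J₁(R, R),

which is exact, reduces analytically to the top-hat closed form
`σ(w₋ - w₊)√(4R² - σ²)/R`, and makes the planar translation mode
`λ₁ = 0` an identity rather than a numerical coincidence.  (A finite
difference of the angular-quadrature `ψ` across `r = R` is *not* a
viable alternative: the near-edge quadrature error pollutes the
difference at any affordable node count.)  For the top hat at `m = 0`
the angular weight integral keeps the constant inhibitory background
`2π w₋`, which the excitatory-arc closed form alone omits; the term
cancels between the two evaluation radii of the disc spectrum.

## Numerics

**Grid simulators.**  Exponential Euler in time (the linear decay is
integrated exactly), with the convolutions computed spectrally on a grid
zero-padded to the next power of two at least twice the box — adequate
for kernels that decay inside the domain.  The Heaviside uses the
midpoint convention `H(0) = ½`.  In the gradient formulation `u` is
rebuilt each step by cumulative trapezoidal integration of `z₁` row-wise
from the left edge (so `u(-L, y) = u_BC` holds to machine precision
there), or radially inward from the rim on a disc.  The reconstruction
pins `u_BC` only along the path anchors; the residual `max |u - u_BC|`
on the rest of the boundary is exposed as a diagnostic rather than
forced (in the clamped test runs it stays below 1e-4).  Level sets are
extracted by marching squares with linear interpolation.  Default steps:
`dt = 0.05` for production runs, `dt = 0.01` in cross-validation tests.

**1D simulator.**  The drive is evaluated *through the interface*:
threshold crossings of `u` are located to sub-grid accuracy with a cubic
spline, and `ψ` over each active interval uses the kernel's closed-form
odd antiderivative.  This keeps constructed bumps stationary to ~1e-6 on
a 16384-point grid (the residual is the O(h²) offset between the
continuum bump and the discrete fixed point of the cumulative-trapezoid
reconstruction).

**Contour engine.**  Contours are closed polylines (≥ 16 vertices), CCW
around the active region.  Line integrals use the periodic trapezoid
with arc-length node weights; chord lengths are promoted to arc lengths
through the local curvature (`ds = c(1 + κ²c²/24)`), and tangents use a
5-point (4th-order) periodic stencil — with 2-point tangents the O(h²)
normal error dominates the `ψ` budget on strongly curved contours.  On
smooth, uniformly sampled contours the resulting quadrature error decays
at least as O(n⁻²) and in practice much faster; at 512 vertices the
line-integral `ψ` agrees with the independent area quadrature to ~1e-6
(circle/ellipse) and ~1e-5 (five-lobed star).  Evaluation *at* a vertex
replaces the 0/0 node by its finite limit `-K·curv/(4π)` and uses
`C = ½`.  Vertex positions advance by explicit Euler (`dt ≤ 0.01`) along
the outward normals, with uniform arc-length resampling whenever the
spacing leaves the configured band; a self-intersecting step raises a
topology-change event carrying the offending contour (contour surgery is
out of scope — long labyrinth runs belong to the grid simulator).

**Area-integral oracle.**  `psi_area` integrates `w` over the polygon
exactly in the radial direction: for each angular direction the ray from
the evaluation point is intersected with the polygon edges and the
radial integral over each inside interval is the difference of the
kernel's cumulative moment `W(r) = ∫₀^r s w(s) ds` (closed form for all
three families).  The angular integral uses Gauss–Legendre panels split
at the vertex bearings, so it is exact up to the panel rule on every
smooth piece.  This is the production path for piece-wise constant
kernels and the independent oracle for the line-integral path.  Note it
is exact *for the polygon it is given*: comparing it against the
line-integral `ψ` of the same vertex set at equal resolution measures
the O(n⁻²) polygon-versus-smooth-curve area mismatch, so oracle tests
evaluate it on a 4×-refined sampling of the same smooth curve.

**Memory convolution.**  `z` on the moving contour is assembled from the
stored history with exponentially weighted interval quadrature — exact
when the forcing is piecewise linear between snapshots, and exact in the
stationary-contour limit (the plain trapezoid leaves an O(dt²) ≈ 1e-6
residual there).  All history nodes are stacked into one weighted
pairwise sum per step; the exponentially damped tail beyond
`e^{-(t-t')} < 1e-12` is dropped.

**Root finding.**  Width/radius equations are scanned on 2000 uniform
candidates and polished by bisection to 1e-12; duplicate roots merged at
1e-8.  Residuals are stored on every branch and checked below 1e-10.

**ζ policy.**  On a disc the boundary anchor is the radial projection.
On a rectangle two policies are provided: nearest boundary point (ties
toward the left edge) and `left_edge` (the same-ordinate point on the
left edge).  The second matches the row-wise reconstruction path of the
grid simulator exactly and is used in the clamped cross-validation runs;
on the test geometry the two differ negligibly because `ψ` is already
small at the boundary.

## Synthetic data

All initial conditions are generated programmatically.  The standard
seed is a spot of radius `R` with edge modulation
`r(θ) = R(1 + ε cos mθ)`, realised as (i) a polygonal contour with
vertices exactly on the curve at uniform arc length, and (ii) a
smoothed-indicator field `u₀ = κ + a·tanh((R f(θ) - r)/δ)` with analytic
gradient, whose `κ`-level set is exactly the modulated circle.  Defaults:
contrast `a = 2κ`, smoothing width `δ = R/6`.  The test conditions are
the published parameter sets: the 1D kernel `(14, 13, 24, 150, 5)` on
`[-10π, 10π]`, the planar kernel `(3.55, 3, 2.4, 3.2, 10)` with
`κ = 0.03` (free labyrinth, full box `L = 12π`, scaled to `L = 4π` on a
128² grid for cross-validation), `κ = 0.05` with `u_BC = 0` (clamped
rectangle, scaled to `L = 2.5π`; disc of radius `5π` for spots).  The
seeds emulate localised activity with a controlled azimuthal content;
they do not emulate measurement noise, heterogeneous kernels or
non-constant boundary data, so passing tests speak to the correctness of
the reduction and its numerics, not to robustness against those factors.
Perturbation sizes in grid-based stability runs are chosen so the
level-set displacement spans a few grid cells (`ε = 0.07`); the Heaviside
evaluated on a grid simply cannot see displacements below one cell, a
discretisation floor of the full model that the (sub-grid) 1D spline
crossings and the contour engine do not share.

## Known limitations

- The contour engine evolves a single closed contour; disconnected
  contours are supported in the `ψ` evaluations but merging/splitting
  halts the evolution (by design — the reduction has no surgery rule).
- `psi_line` requires an integrable smooth kernel (difference of
  Gaussians); piece-wise constant kernels go through `psi_area`.
- The memory convolution cost grows linearly with the stored history, so
  the per-step cost of a contour run grows linearly in time (quadratic
  overall); the scaled cross-validation runs (T = 3, 128 vertices,
  dt = 0.01) take tens of seconds each.
- Whether the full-boundary Dirichlet condition can be enforced exactly
  by a reconstruction path family — rather than only at the path
  anchors — is left open; the boundary residual diagnostic quantifies
  the gap on any given run.
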