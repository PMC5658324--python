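# neuralfield

Interface dynamics for Amari-type neural fields on bounded domains with
Dirichlet boundary conditions.

Continuum neural field models describe coarse-grained cortical activity
`u(x, t)` through a nonlocal integro-differential equation

```
u_t(x, t) = -u(x, t) + ∫_Ω w(|x - y|) H[u(y, t) - κ] dy,
```

where `w` is a radially symmetric ("Mexican hat") synaptic kernel, `H` a
Heaviside firing rate and `κ` the firing threshold.  With a Heaviside
nonlinearity, the whole state is determined by the *interface* — the
boundary `∂Ω₊` of the active region `{u > κ}` — and the model reduces,
without approximation, to a normal-velocity law for that contour:

```
c_n = (-κ + ψ(x)) / |∇u(x)|,     ψ(x) = ∫_{Ω₊} w(|x - y|) dy,
```

where `ψ` collapses to a one-dimensional line integral over `∂Ω₊` via
the kernel's ring potential `φ(r) = (1/r)∫_∞^r s w(s) ds` and total mass
`K`.  Clamping the activity on the domain boundary to a value `u_BC`
(a Dirichlet condition, modelling the functional separation of cortical
areas) is handled by reformulating the dynamics in terms of the gradient
`z = ∇u` and reconstructing `u` by a line integral from the boundary;
the velocity rule acquires a boundary term:

```
c_n = (u_BC - κ + ψ(x) - ψ(ζ(x))) / |z(x, t)|,
```

with `ζ(x)` the boundary anchor of the reconstruction path.  The package
provides, for difference-of-Gaussians and piece-wise constant kernels:

- **`kernels`** — kernel families with their ring potentials, total
  masses and radial moments;
- **`bump1d`** — 1D stationary bumps (free and clamped), their implicit
  width equation, edge (Evans-function) spectra, an edge-only evolution
  rule with exponential memory, and a full-grid cross-check simulator;
- **`field2d`** — spectral full space–time simulators for both the
  classical and the gradient formulation, plus sub-pixel level-set
  extraction;
- **`interface2d`** — the contour-only engine: line-integral `ψ`,
  `∇ψ`, the memory convolution for `z`, free and Dirichlet velocity
  rules, and contour stepping with arc-length resampling;
- **`spots`** — circular spots on the plane and on a clamped disc,
  circle-overlap ("lens") geometry for piece-wise constant kernels, and
  azimuthal (Evans-function) eigenvalues `λ_m`;
- **`fixtures` / `experiments` / `cli`** — programmatic seeds (perturbed
  spots, labyrinth seeds), YAML-configured experiment runs and a
  `neuralfield` command-line tool.

It is intended for researchers in mathematical neuroscience and pattern
formation who want quantitative bump/spot bifurcation diagrams, azimuthal
stability boundaries, or contour-level simulations of labyrinthine
growth under boundary clamping.

## Worked example

Bump branches of the 1D model on `[-10π, 10π]` with the kernel
`w(x) = (1/√(cπ))[a₁/√b₁ e^{-x²/b₁} - a₂/√b₂ e^{-x²/b₂}]`,
`(a₁, a₂, b₁, b₂, c) = (14, 13, 24, 150, 5)` at threshold `κ = 0.7`:

```python
import numpy as np
from neuralfield import DoGKernel, solve_bump_widths

k = DoGKernel(a1=14, a2=13, b1=24, b2=150, c=5)
for bc in ("none", "dirichlet"):
    for b in solve_bump_widths(k, kappa=0.7, L=10 * np.pi, bc_mode=bc):
        print(f"{bc:9s} width={b.width:8.4f}  "
              f"lambda={b.lambda_plus.real:+.4f},{b.lambda_minus.real:+.4f}  "
              f"stable={b.stable}")
```

```
none      width=  1.6317  lambda=+10.7673,+0.0000  stable=False
none      width= 12.0405  lambda=+0.0000,-0.3620  stable=True
dirichlet width=  1.6301  lambda=+10.8022,+0.0000  stable=False
dirichlet width= 12.1402  lambda=+0.0000,-0.3509  stable=True
dirichlet width= 38.7504  lambda=+0.2209,+0.0000  stable=False
dirichlet width= 59.5685  lambda=+0.0000,-0.8433  stable=True
```

Without a boundary condition the classical picture appears: a narrow
unstable and a wide stable bump (the `+0.0000` eigenvalue is the
marginal translation mode).  Clamping `u(-L) = 0` induces two further
branches whose active region spans most of the domain — one of them
stable, i.e. a genuinely boundary-induced persistent state.

Spots of the planar model (kernel `a₁=3.55, a₂=3, b₁=2.4, b₂=3.2,
c=10`) at `κ = 0.05`:

```python
from neuralfield import solve_spot_radius
for b in solve_spot_radius(DoGKernel(a1=3.55, a2=3, b1=2.4, b2=3.2, c=10),
                           kappa=0.05, domain="plane"):
    print(f"R={b.radius:.4f}  lambda_0..4 = {np.round(b.eigenvalues[:5], 4)}")
```

```
R=0.4170  lambda_0..4 = [ 6.7905  0.     -0.9519 -0.9986 -1.    ]
R=6.8084  lambda_0..4 = [-0.0109  0.      0.0294  0.0682  0.1038]
```

The narrow spot is unstable to uniform dilation (`λ₀ > 0`); the wide
spot is unstable to azimuthal modes `m ≥ 2` — the seed of labyrinthine
growth — while `λ₁ = 0` is the exact translation mode.

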