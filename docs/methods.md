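# Methods

## Model overview

`fibergel` couples two scales. The macroscopic gel is a Galerkin FE model
of an 8 × 8 × 0.8 mm fibrin slab on a regular grid of trilinear hexahedra.
The microscopic scale is a set of representative volume elements (RVEs):
cross-linked fiber networks in the unit cube, one per network quadrature
point.  Volume averaging couples the scales: the RVE's boundary nodes are
displaced affinely by the local macroscopic deformation gradient
`x = c + F (X − c)` about the cube center `c`; after the interior
cross-links re-equilibrate, the macroscopic Cauchy stress at the quadrature
point is the symmetrized boundary dyadic average

    sigma_net = sym( (1/V) * sum_b x_b (x) f_b ) / a^2 ,

with `f_b` the external reactions at the boundary nodes, `V = J V0` the
current RVE volume, and `a` the physical RVE edge length.  An additive
compressible neo-Hookean term

    sigma_nH = G/J (B - I) + 2 G nu / (J (1 - 2 nu)) ln(J) I

(`B = F Fᵀ`, `J = det F`) limits distortion and compressibility of the
otherwise very soft network.  Cell traction in the explant ("cellular")
elements is modeled by multiplying every fiber reference length in their
networks by `(1 − s)` per increment; the composed total shortening is 24 %.

### Fibers

Each fiber is a pin-jointed axial element (ball-joint cross-links, no
bending) with force `F(λ) = EfAf/B (exp(B ε) − 1)`, `ε = (λ² − 1)/2`.
Defaults `EfAf = 3·10⁻¹⁰ N` and `B = 4` (fitted elsewhere to a uniaxial
fibrin test and taken as given); `B → 0` reduces to the linear law
`EfAf·ε` and is implemented as an explicit small-`B` branch below 10⁻⁸.
Fibers resist compression with the same smooth law (the force saturates at
`−EfAf/B·(1 − e^{−B/2})` as λ → 0), which mildly stabilizes the networks.

### Network generation

The generation procedure (not prescribed by the underlying experiments;
chosen here as the simplest construction meeting "nearly isotropic,
cross-linked, ~337 fibers") samples random chords of the unit cube — a
uniform interior point plus a uniform direction, extended to the faces —
and creates a cross-link node wherever two chords pass within a capture
radius (default 0.03), at the midpoint of their closest approach.  Chord
endpoints on the faces become boundary nodes; the chord segments between
consecutive nodes become fibers.  Cross-links closer than 0.02 in chord
parameter are rejected greedily (closest pairs first) to avoid degenerate
stubby fibers.  Candidates whose largest connected component does not touch
all six faces, or whose planar orientation tensor has α ≥ 0.15, are
regenerated from the next sub-seed, keeping the output a deterministic
function of the seed.

The chord count is planned from the target fiber count through
`fibers = chords + 2·crossings` with `E[crossings] ≈ 1.105 · C(S,2) · r`
(the coefficient measured empirically for this sampler).  At the default
target of 337 fibers this yields ~88 chords, ~124 cross-links, ~300 nodes
(~900 interior + boundary degrees of freedom), mean fiber count 336–340
over seeds 1..100 with an SD of ~28.

### RVE equilibrium

Interior nodes are equilibrated by Newton's method on nodal positions with
an analytic stiffness (axial + geometric terms), Cholesky with LU fallback
for indefinite tangents (compressed fibers), Levenberg-style regularization
if both fail, and a backtracking Armijo line search on total strain energy.
Convergence is declared when the max interior net-force norm falls below
`max(tol, rel_tol · max|F_fiber|, 10⁻⁸·EfAf)` — defaults `tol = 10⁻²⁰ N`,
`rel_tol = 10⁻⁶`.  Two numerical facts shaped this criterion:

- the closed-form fiber energy (an `erfi` antiderivative) is a difference
  of same-order terms and cancels catastrophically at small strain, so the
  line search treats energy changes below an explicitly estimated round-off
  scale as noise and then accepts the full Newton step if it reduces the
  residual;
- the force evaluation itself has an absolute round-off floor near
  `10⁻⁸·EfAf`; residuals below it carry no mechanical information, and a
  stagnation guard accepts them.

A fixed absolute tolerance of order 10⁻¹⁰ N would exceed the pN-scale
forces of weakly strained matrix networks, so the criterion is
force-scale-relative by design.

### Scale coupling and units

Lengths inside RVEs are dimensionless (unit cube); forces are in newtons.
One documented factor converts the dyadic average to physical stress:
`1/a²` with `a = rve_side` (default 20 µm, a plausible fibrin pore-scale
RVE size).  Macro lengths are mm and stresses Pa, so assembled nodal forces
are in Pa·mm² consistently.  The dyadic sum is insensitive to the origin
choice because the boundary reactions of an equilibrated network sum to
zero; its small asymmetry for finite networks is removed by
symmetrization and the asymmetry norm is logged per solve.

The right-hand coupling term of the macroscopic averaged-equilibrium
equation (the surface integral of `(σ − ⟨σ⟩) u_k,i n_k`) is implemented as
a discrete boundary-node sum, `t_j = (1/V) Σ_b f_j^b (n·∇u·n)_b`, behind
the `include_coupling` switch.  Its quadrature is not prescribed by the
source formulation and published analyses of this framework find it small;
it is **off by default**, and when enabled its magnitude relative to the
averaged stress divergence is logged so the choice is observable.

### Macroscopic solve

Total-Lagrangian assembly with nominal stress `P = J σ F⁻ᵀ` (for the
network part `P = sym(S) F⁻ᵀ / a²`, the `J` cancelling).  The neo-Hookean
term uses full 2 × 2 × 2 Gauss quadrature; the network term uses the
configured RVE quadrature (8 points at full scale, the element centroid in
the scaled-down preset — the full-quadrature neo-Hookean term then
provides partial hourglass control).  The consistent tangent of the
network term comes from linear sensitivity of the equilibrated RVE: with
the interior stiffness factored, nine back-substitutions give
`dS/dF` exactly (verified against finite differences to ~10⁻⁶ relative);
the neo-Hookean tangent is finite-differenced on its closed form
(perturbation 10⁻⁷).  Newton iterations use residual-based backtracking,
a relative convergence tolerance of 10⁻⁴ on the max residual with an
absolute floor, and stagnation acceptance at the micro-solve noise floor
(≤ 10⁻³ of the increment's initial residual).  Failed increments are cut
in half (multiplicatively, up to depth 3) and retried.

Boundary cases: *Fixed* clamps all faces except the top; *Free* clamps
only bottom-face nodes inside a centered 1.74 × 1.74 mm anchor square.
Explant areas are measured as the area of the deformed top-surface patch
polygon (union of deformed element top faces); centroid distances from the
polygon centroids.

### Increment schedule

`n` equal multiplicative steps with per-step shortening
`1 − (1 − 0.24)^{1/n}` compose to exactly 24 % (defaults: n = 24 at full
scale, 8 in the desk preset).  Equal 1 % steps would compose to only
21.4 %, so the schedule is defined by its composed total.

## Image analysis

**Bead tracking.** Sequential template matching: for each bead, a
(2·10+1)² template around the current position is matched by normalized
cross-correlation (gain/offset invariant) inside a (2·20+1)² search window
of the next frame; the peak is refined by 1D quadratic interpolation in
each axis and the template is re-sampled from the new frame at the found
position.  A peak correlation below 0.5 marks the bead lost from that
frame (mirroring out-of-focus exclusions).  Quadratic peak interpolation
has a texture-dependent sub-pixel bias (~0.05 px per step) which compounds
slowly under sequential re-templating; recovered displacement fields are
accurate to ~0.2 px RMS over ten frames in the synthetic benchmarks.

**FFT alignment.** A Hann-windowed tile's power spectrum is masked to an
annular band (default 0.02–0.4 cycles/px, DC removed), binned into 180
orientation bins over [0, π), rotated a quarter turn from spectral to
fiber space, and condensed into the orientation tensor and
`α = 1 − ω₁/ω₂`.  Band and window are package defaults, declared rather
than inferred from any reference data.  The finite length of real fibers
convolves the angular energy distribution with a heavy-tailed kernel, so
recovered α carries a small negative bias (~0.03 at α ≈ 0.8 for 60 px
fibers); principal angles are recovered within a few degrees.

**Displacement statistics.** Cumulative displacement is net displacement
from the first frame (not path length) — with this definition the 6-hour
period-average rates telescope exactly to the final cumulative
displacement; path-length accumulation is available behind a flag.
Regions 1–4 (above / lateral / axial-central / below the explant triangle)
are assigned from a configurable 6 × 6 tile map; the shipped default
follows that spatial description.

## Synthetic data

Bead scenes place Gaussian-profile beads (σ = radius/2, dark background)
at sub-pixel positions advected by uniform, radial-contraction, or
simulation-exported displacement fields, with additive Gaussian noise on
the 8-bit scale; ground-truth positions are co-emitted, and beads advected
into the frame margin are flagged.  Fiber textures draw anti-aliased line
segments with orientations from a von Mises distribution on the doubled
angle; the sampled-angle orientation tensor is returned as truth, and the
population value has the closed form `α = 2R/(1+R)`,
`R = I₁(κ)/I₀(κ)`.  The generators emulate localizable blobs and oriented
texture — not DIC/confocal image formation, shading, or depth effects — so
passing tests certify the operators' contracts, not instrument-specific
robustness.

## Problem sizes used in the tests

The full-resolution configuration (46 × 46 × 4 mesh, 8 RVEs per element,
337-fiber networks) is exposed as `reference_config()` and its geometry is
verified exactly (element/node/RVE counts, patch area and spacing), but
coupled full-scale solves are cluster-scale work (the reference runs were
hundreds of CPU-hours).  The package's own simulations run the
`desk_config()` preset — 12 × 12 × 1 elements over the same physical gel,
one ~60-fiber RVE per element, 8 increments — which preserves geometry
ratios and reproduces the boundary-condition orderings (Free matrix
displacement ≫ Fixed; Fixed fiber forces > Free; alignment and Δα
concentrated axially and around explants; areas non-increasing).  Element
region classes (near-explant / axial / far-field) are geometric, scale
with the explant spacing, and may overlap near/axial.

## Known limitations

- The network generator is one plausible realization of "nearly isotropic
  cross-linked networks"; topology statistics other than fiber count,
  node count and isotropy were not matched to data.
- Fiber bending/torsion mechanics, fiber plasticity or degradation, and
  periodic RVEs are out of scope; cross-links are ideal ball joints.
- The desk-scale explant patches are single elements, so explant-shape
  effects (triangular outlines) are not resolved there.
- Tracker drift under sequential re-templating grows with sequence length;
  for very long sequences an anchored-template or drift-corrected variant
  would be preferable.
- The reference experiments show displacement rates decreasing over time
  while this traction model (constant incremental shortening) produces
  near-constant-to-increasing rates; this is a known model-form limitation
  and no attempt is made to tune it away.
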