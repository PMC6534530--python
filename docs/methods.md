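# Methods

## Model

`ridgesim` simulates the second phase of fingerprint development: the
rearrangement of Merkel cells into ridge lines along the directions of
smallest compressive stress in the epidermis.  N particles (cells) with
positions x_j on the unit torus T² = [0,1)² evolve by the first-order
dynamics

    dx_j/dt = (1/N) Σ_{k≠j} F(x_j − x_k, T(x_j)),

where the pair force acts along the local orthonormal stress frame
(s(x_j), l(x_j)) — s the direction of smallest stress, l of largest:

    F(d, T) = f_s(|d|) (s·d) s + f_l(|d|) (l·d) l.

The stress field enters only through the line field s (defined mod π) and
the anisotropy tensor T = χ s⊗s + l⊗l, χ ∈ [0, 1].  All forces vanish
identically for separations ≥ the cutoff radius (default 0.5, the torus
diameter bound), which is what makes exactly equidistant line patterns
exact steady states.

### Coefficient families

* **kc_original** — exponential kernels
  f_R(r) = (α r² + β) e^(−e_R r) (repulsion) and
  f_A(r) = −γ r e^(−e_A r) (attraction), combined as
  f_s = χ·δ·f_A + f_R and f_l = δ·f_A + f_R.
  Canonical parameters: α = 270, β = 0.1, γ = 35, e_A = 95, e_R = 100,
  χ = 0.2 (preset `kc2012`).  The attraction scale δ (`delta_scale`,
  default 1) multiplies f_A in *both* components, so at χ = 1 the total
  force is the radially symmetric δF_A + F_R used in the ring-collapse
  experiment; δ is a dial for the aggregate strength of attraction, and
  the stationary pattern changes from space-filling (δ = 0.1) through
  complex intermediate patterns (δ = 0.3) to a single thin ring (δ ≥ 0.5).
* **kc_adapted** — same kernels, but the attraction along l is damped by a
  fixed 0.3 (f_l = 0.3 f_A + f_R, f_s = χ f_A + f_R), turning the
  long-range tail along l repulsive so that multi-ridge patterns survive
  as stationary states instead of coarsening into a single cluster.
* **kc_reparam** — the observation that 0.3·35 = 10.5 lets the adapted
  l-force be obtained in the original functional form by setting γ = 10.5
  (preset `kc-reparam`).  The s-coefficients of the two presets differ
  slightly (χ·35 vs χ·10.5 in the attraction) but both remain purely
  repulsive along s.
* **piecewise** — starts from kc_reparam's f(r, χ) = χ f_A + f_R and
  flips the sign of the l-coefficient beyond an outer cutoff c2 = 0.07
  (linear bridge from c1 = 0.06), making the far tail attractive; this
  keeps line patterns intact under range rescaling η > 1.
* **oscillator** — damped-harmonic-oscillator ansatz
  f_s = c e^(e_s1 r) + c_s sin(πr/a_s) e^(e_s2 r),
  f_l = c cos(πr/a_l) e^(e_l1 r) + c_l sin(πr/a_l) e^(e_l2 r),
  with c = 0.1, c_s = −0.05, c_l = 0.005, e_s1 = −65, e_s2 = −100,
  e_l1 = −160, e_l2 = −40, a_s = 0.03, a_l = 0.022 (preset
  `oscillator2014`): a closed-form family with the same short-range
  repulsive / medium-range attractive / long-range weakly repulsive
  structure.

The rescaling factor η evaluates F(η d, T) — coefficients at η|d| *and*
projections of η·d, following the literal composition — so η > 1 shrinks
the effective interaction range to cutoff/η and with it the stationary
ridge spacing; η < 1 enlarges both.

### Orientation fields

Analytic fields come from quadratic differentials: a delta (three-ridge
junction) at ζ contributes line angle −arg(x−ζ)/2, a core (single ridge
ending) +arg(x−ζ)/2; a general field with several singular points is
φ(z) = Π(z−ζ_delta)/Π(z−ζ_core) with φ dz² > 0, giving the additive
argument rule implemented in `composite_orientation`.  Sampled fields are
angle grids in [0, π) over the unit square; interpolation and hole-filling
operate on the doubled-angle embedding (cos 2θ, sin 2θ) so that averaging
is correct across the π wrap.  Hole-filling solves the discrete Laplace
system on the embedding exactly (sparse direct solve, 4-neighbor stencil,
Neumann edges) rather than by fixed-count relaxation sweeps: the cost is
negligible at the grid sizes used and the harmonic-extension properties
(constant data → constant fill, single valid cell → constant grid) then
hold to machine precision on any grid.

Angles are measured from the *horizontal* axis with s = (cos θ, sin θ).
(A vertical-axis reading of θ would be inconsistent with that
reconstruction formula; the reconstruction is taken as normative.)

Analytic singular fields are not periodic; the simulator still uses torus
displacements for forces.  Sampled-grid lookups wrap periodically, so
near the domain seam a sampled non-periodic field and its analytic source
disagree — evaluations there are the grid's periodic reading.

## Numerics

* Displacements use the minimum-image convention, componentwise in
  [−0.5, 0.5); positions are wrapped to [0, 1) after every step.
* The reference right-hand side is a vectorized O(N²) sum; the cell-list
  right-hand side hashes particles into a grid with cell edge ≥
  cutoff/η and scans the 3×3 periodic neighborhood, and agrees with the
  reference to ≲1e−20 per component (same arithmetic, different summation
  order).
* Integrators: explicit Euler with Δt = 0.2 (default) and a fixed-step
  Dormand–Prince 5(4) alternative.  An adaptive-step Euler mode takes
  Δt_k = min(Δt_cap, max_move / max_j |v_j|, 1/λ̂): the first cap bounds
  the per-step displacement at `max_move` (default 0.002, well below a
  ridge spacing), the second keeps the step inside the Euler stability
  region using the cheap Jacobian over-estimate
  λ̂ = 4 max_j Σ_k (|f_s| + |f_l|) / N accumulated during the force pass.
  The pattern-forming dynamics of these kernels are extremely slow —
  typical speeds are 1e−6 to 1e−3 in domain units — so stationary
  patterns live at times t ~ 1e7, far beyond fixed-Δt budgets.  Because
  steady states are fixed points of the Euler map for *any* Δt, the
  adaptive mode reaches genuine stationary patterns at a small fraction
  of the step count (verified: final states evolved for 2000 further
  steps at Δt = 0.2 move by τ ≈ 1e−6 per step, i.e. ~2e−9 per particle);
  without the stability cap, converged dense ridges slowly churn and
  artificially coarsen.  Δt = 0.2 remains the default for
  trajectory-accurate integration.
* The production right-hand side is a numba-compiled cell-list kernel
  (scalar coefficient formulas duplicated in `_kernels.py`); the
  vectorized numpy cell-list and O(N²) paths are kept as references and
  all three agree to ≤1e−12 per velocity component in the tests.
* Stationarity is tracked by τ(t) = Σ_j ‖x_j(t+Δt) − x_j(t)‖₁, computed
  with minimum-image displacements so seam crossings do not spike the
  statistic.
* Hard truncation at the cutoff is deliberate (no smoothing): the exact
  steady-state argument needs F ≡ 0 at separation 0.5 exactly.  At
  cutoff 0.1 the retained discontinuity is ≤ 2e−4 in the coefficients.

## Experiments and their scales

* **Steady-state residuals** — the explicit n-line configurations give
  residuals at rounding level (~1e−18; ~1e−11 for the oscillator family
  whose coefficients are not yet fully decayed at the line spacing), far
  below the 1e−10 acceptance bound.  Non-equidistant counterexample
  spacings are {0.1, 0.3, 0.2, 0.2, 0.2}: the exponential kernels decay
  so fast that milder asymmetries give residuals below 1e−6 without
  contradicting the exact-arithmetic statement.
* **Ring collapse (δ sweep)** — χ = 1, N = 600, equiangular circle init
  (center (0.5, 0.5), radius 0.005), Δt = 0.2, 2000 steps, cutoff 0.5.
  δ = 0.5 contracts to a thin ring (radius ≈ 0.0037, radial std/mean
  ~1e−13); δ = 0.1 expands monotonically (mean radius ≈ 0.05 at t = 400
  and growing).  The equiangular initial data is perfectly rotationally
  symmetric, and the symmetric expanding circle is dynamically unstable
  for the δ = 0.1 force but only rounding noise seeds the instability, so
  at this horizon "spreading" manifests as a mean radius an order of
  magnitude beyond the δ = 0.5 ring plus a radial spread orders of
  magnitude above rounding, not yet as a space-filling cloud.
* **Ridge spacing vs η** — oscillator preset, homogeneous vertical field,
  N = 600, cutoff 0.1, adaptive stepping to t = 2e7 (by which the final
  states are stationary: τ ≈ 1e−6 over further Δt = 0.2 steps); spacing
  measured by circular gap clustering of the x-projections.  The
  stationary pattern emerges through a slow, seed-dependent coarsening
  cascade; the expected ordering (larger η → more, closer ridges) is
  asserted as a majority vote over seeds.
* **Alignment with the stress field** — kc_reparam, N = 600, cutoff 0.1,
  delta / core-plus-delta fields, adaptive stepping to t = 1e7; the
  rendered pattern (splat σ = 0.012, comparable to the intra-ridge
  particle spacing so dotted ridges merge into lines; structure-tensor
  σ = 8 px ≈ half a ridge period at 256²) is re-estimated and compared
  (mod π) with the input field.  A homogeneous control reaches ~94% of
  cells within 0.15 rad; on singular fields the discrete ridge pattern
  straightens between defects and cannot follow the prescribed continuous
  rotation everywhere (~80% for a single delta, less for a core+delta
  pair), and past t ≈ 1e7 continued ridge merging trades field-following
  for larger spacing, so the agreement is evaluated at that horizon.

## Synthetic data

The fixture generators emulate the *inputs* of the pipeline: canonical
angle maps (homogeneous, single core/delta, core+delta, two-region),
sinusoidal stripe images with known wavelength and orientation for
validating the estimator, and Gaussian-splat renderings of particle
states.  They do not emulate the gray-level statistics, noise, or partial
occlusion of inked fingerprint images, so passing tests demonstrate
correctness of the geometry pipeline, not robustness to real scan
artifacts.  The orientation estimator is a plain structure-tensor method
(σ = 2 px smoothing by default, mask where the tensor trace is below
1e−6 of its maximum); the line-sensor estimation and published
extrapolation methods used for real images are out of scope, and the
harmonic hole-filling is a deliberately minimal stand-in for the latter.

## Known limitations

* No second-order (inertial) dynamics and no macroscopic PDE solver.
* Stability of line patterns is asserted numerically (perturb-and-relax
  smoke tests), not spectrally.
* Ridge-spacing estimation assumes an essentially axis-aligned line
  pattern; arbitrary ridge orientations are handled only through the
  axis_angle parameter.
* The adaptive-step mode is for reaching stationary patterns; transient
  trajectories at large Δt are not time-accurate.
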