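# Methods

This note documents the models implemented in `airspectra`, the conventions
and defaults they use, and the numerical choices behind them.

## Tree model and conventions

An airway network is a rooted oriented tree: every branch points from its
proximal to its distal node, the root is the entry from the upper airway, and
terminal nodes represent the transitional bronchioles feeding the acini.
Nodes are canonically ordered root → internal → terminal (breadth-first from
the root, siblings in input order) and branch *j* is identified with its
unique distal node *j* + 1. This ordering makes the block structure of every
operator (root / internal / terminal) a plain index slice, and it is
deterministic, so spectra are bit-reproducible across runs. n-furcations are
allowed everywhere; nothing in the theory requires dyadic branching.

Units: geometry in mm; pressure in cmH₂O; volume in l; time in s; resistance
in cmH₂O s l⁻¹; elastance in cmH₂O l⁻¹.

Branch resistance defaults to Poiseuille's law, r = (8/π) μ l / a⁴, with the
dynamic viscosity of air μ = 1.93 × 10⁻⁵ Pa s and the standard prefactor
8/π. Both constants are configurable and recorded in the tree's metadata.
Any global prefactor rescales all resistances uniformly, which leaves
eigenvectors, mode ordering, reduced-order mode counts, and σ_V at fixed
κτ scaling unchanged; only absolute resistances and eigenvalues shift.
An explicit `resistance` column in a tree CSV overrides the computed values.

## Flow solves

Under fixed pressure drops at the terminals, interior pressures satisfy the
sparse SPD system L_int ΔP_int = B Γ_term ΔP_term, factorized once by
SuperLU and verified against a 10⁻¹⁰ relative residual. The Maury route
(R Q_term = −ΔP_term) is never used as a direct solver — R is dense with
|T|² entries — but its spectrum is computed matrix-free through the sparse
factors R = T diag(r) Tᵀ, where T maps branches to their terminal
descendants. Three independent constructions of R (sparse factors,
shared-path resistance sums, Schur-complement inversion of the Laplacian
blocks) cross-validate each other in the test suite to 10⁻¹⁰.

## Spectral truncation diagnostics

δ_L(M) and δ_R(M) measure how well M modes reconstruct the *inverse* of
each operator, as the normalized Frobenius distance between the inverse and
its truncated spectral expansion. By orthonormality both reduce to
√(Σ_excluded λ⁻² / Σ_all λ⁻²). The smallest-eigenvalue modes carry the
largest inverse weights, so they are the ones kept. Both quantities are
monotone nonincreasing in M, equal 1 at M = 0 and 0 at the full spectrum.

## Reduced-order flux reconstruction

The minimum number of modes needed to reconstruct a flow solution to a given
accuracy depends on the accuracy metric, which is a genuine design choice.
The default metric is the **energy (dissipated power) norm**: mode k of the
Maury operator carries power (ΔP_termᵀ v̂_k)² / μ_k — for a uniform unit
pressure drop, exactly its share of the total root flow — and accuracy is
the captured fraction of total power, with modes ranked by that contribution
(the greedy ranking is optimal because mode contributions are orthogonal in
this norm, so the count is the true minimum subset size). This is the
physically natural norm for a resistive network, in which the modes act as
independent parallel resistors. A Euclidean variant (relative L2 error of
Q_term, modes ranked by coefficient magnitude |q_k|) is selectable via
`metric="l2"`; it is substantially more conservative because it weights the
many small-flux terminals equally. Ties in any ranking are broken stably
toward the conventional eigenvalue order, so mode counts are deterministic
even on degenerate (symmetric-tree) spectra, where all assertions are made
on rotation-invariant quantities only.

## Ventilation model

Each terminal feeds an elastic unit with uniform elastance κ (per-unit
vectors are rejected: the model's purpose is to isolate the effect of airway
resistance, so compliance heterogeneity is out of scope). All units see the
same sinusoidal pleural pressure P_pl = P_pl0 + P_s sin(2πt/τ). The volumes
obey R V̇ + κV = −P_pl e.

Defaults follow adult physiology: total lung elastance κ/|T| = 5 cmH₂O l⁻¹
(configurable 5–30, the paediatric-to-adult range), breath period τ = 4 s,
amplitude P_s = 1 cmH₂O, offset 0. σ_V is exactly invariant to P_s
(linearity) and to P_pl0 (volume shift), so the amplitude and offset choices
are cosmetic for heterogeneity studies.

Two independent solution routes are implemented and held to agreement:

* **Direct**: fixed-step BDF2 (L-stable, second order, backward-Euler
  startup) on the monolithic sparse block system in (ΔP_int, V). The system
  matrix is constant, so one LU factorization serves the whole run; each
  step costs two sparse triangular solves and R is never formed. The system
  is stiff — fast modes decay at rate κ/μ_k — which is why an L-stable
  implicit scheme with a fixed step is used instead of an explicit or
  trapezoidal one. Defaults: 512 steps per cycle (amplitude sampling error
  ~(2π/512)²/8 ≈ 8 × 10⁻⁵ relative), 5 cycles, with the first n−1 cycles
  discarded as transient. Tidal volumes are max − min over the final cycle;
  the last two cycles are compared and a relative discrepancy above 10⁻⁴
  triggers a warning to increase `n_cycles` (the slowest transient decays on
  the timescale μ₁/κ, which approaches the breath period only on severely
  constricted trees — the bundled experiments use 10–12 cycles for those).
* **Modal**: the closed-form periodic solution in the Maury eigenbasis, one
  RC compartment per mode. Truncation keeps the largest-μ modes; omitted
  modes contribute only the uniform elastic term, so zero modes give exactly
  homogeneous ventilation. A third path evaluates the convolution integral
  for *generic* pressure waveforms with an exponential-trapezoidal recursion
  (exact for piecewise-linear Ṗ, stable for arbitrarily stiff modes, series
  fallback for small exponents); for sinusoidal input it converges to the
  closed form once transients decay.

σ_V is the coefficient of variation of ΔV with population normalization
(sample normalization selectable). "Large" eigenvalues are those with
μ_k > 0.1 κτ; their count is the reduced-order predictor of heterogeneity,
and an unconstricted tree has none.

## Generators

**Asymmetric Weibel trees.** Dyadic, N divisions, 2^N terminals. Each parent
spawns a major and a minor child with radius and length scaled by
(1 ± A/2)^(1/3); the cube root makes the daughters' combined Poiseuille
resistance and volume equal to the parent's generation for every asymmetry
A ∈ [0, 1). Consequently the root-to-terminal equivalent resistance has the
A-independent closed form r_trachea(2 − 2⁻ᴺ), which the tests use as an
oracle. All airways have length = 3 diameters; the trachea radius defaults
to 9 mm. Absolute scale is irrelevant to every dimensionless result.

**Horsfield-order recursion trees.** Branches carry orders counted up from
the periphery (terminals are order 1; a parent is 1 + max of its children).
A morphometry table maps each order to its children's orders and mean
dimensions; recursion proceeds from a root order down to a termination
order, with child orders clamped at the termination order so a table need
only cover the recursion range. Radius and length are drawn independently
per branch as Gaussians with σ = noise_fraction × mean (10–20% emulates
healthy inter-airway variability); draws at or below 5% of the mean are
resampled rather than truncated, preventing nonphysical geometry without
biasing the bulk of the distribution (the threshold is configurable). The
shipped demonstration table (orders 1–10, children (g−1, g−2), geometric
radius progression) is synthetic: its Fibonacci-like terminal counts give an
exact recursion oracle, but it is not measured human morphometry, and
reproducing published cast-based models requires transcribing such a table.

**Distal diameter assignment.** For image-based trees whose periphery is
generated algorithmically, diameters below an anchor order follow
log D(g) = (g − N) log R_dH + log D_N with R_dH = 1.15 by default; anchored
branches keep measured diameters, and existing resistances are rescaled by
the fourth power of the radius change.

**Constrictions.** A fraction f of the branches at one Horsfield order is
selected uniformly at random and each selected radius is multiplied by
(1 − u), u ~ Uniform(0.50, 0.95) — i.e. "reduced by 50–95%", leaving 5–50%
of the original lumen (the multiply-by-u reading is selectable in config).
For one seed, the selection permutation and the per-branch draws are
generated once and f only chooses a prefix, so fraction sweeps are *nested*:
resistance perturbations only accumulate, and every Maury eigenvalue — hence
the large-mode count — is provably nondecreasing along the sweep (Weyl's
inequality applied to R = T diag(r) Tᵀ). Topology, lengths and unselected
radii are never touched.

## What the synthetic data does and does not show

The generators reproduce the *structural* features that drive flow
asymmetry and VH — branching asymmetry, order-dependent dimensions,
heterogeneous path resistance, localized constriction — under exactly linear,
rigid-airway resistance. They do not emulate inertial or nonlinear pressure
losses, airway compliance, dynamic bronchoconstriction, or patient-specific
geometry from imaging, so passing tests demonstrate correctness of the
operators and of the reduced-order machinery, not predictive accuracy for
any specific lung.

## Problem sizes and caps

Dense eigendecomposition is only attempted below configurable caps (5000
internal nodes for the Laplacian, 4096 terminals for the Maury operator);
partial spectra use matrix-free Lanczos (largest/smallest ends) or
shift-invert and never assemble a dense matrix. The bundled experiments use
trees of 512–1024 terminals with full or 1% spectra, which keeps the whole
suite and the headline computation in the seconds-to-a-minute range while
preserving the scale separation (many compliance-dominated modes, few
resistive ones) that the reduced-order method exploits.

## Known limitations

* Linear, time-invariant resistances only; no flow-rate-constrained boundary
  condition at the mouth.
* Uniform unit elastance; κ heterogeneity is rejected by design.
* The Maury operator loses its meaning if airway compliance dominates.
* The direct ODE integrator uses a fixed step; severely constricted trees
  need more cycles for the periodic orbit (the periodicity check reports
  this) rather than a smaller step.
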