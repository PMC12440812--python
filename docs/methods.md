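# Methods

This note records the models implemented in `celliq`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic
benchmarks do and do not demonstrate.

## Electrostatics

Charges are spherical Gaussians of width γ_i [Å]. The pair interaction
`erf(α_ij r)/r` with `α_ij = [2(γ_i²+γ_j²)]^(−1/2)` is finite at contact;
each charge carries the self energy `(2α_ii/√π)Q_i²`. All energies are
evaluated in Gaussian form and scaled once by `k_e = 14.399645 eV·Å·e⁻²`,
so electronegativities and hardnesses are learned directly in eV/e and
eV/e². The charge-space matrix M (with the self coefficient doubled on the
diagonal so that `U = ½QᵀMQ`) is the Hessian used by the equilibration
solver. A factor-of-two ambiguity exists in the literature for the Gaussian
self term; this package consistently uses the `(2α_ii/√π)Q_i²` convention
everywhere (energy, matrix diagonal, Ewald self term), so the solver, its
oracle, and the labels are mutually consistent.

Periodic systems use classic Ewald summation rather than a mesh method:
at the system sizes this package targets (≲ a few hundred atoms) the
O(N²)-ish classic sum is exact to tolerance and much simpler. The splitting
width defaults to `max(min γ, L_min/8)`; real- and reciprocal-space cutoffs
are derived from the requested accuracy via the Gaussian tail parameter
`s = √(−ln acc) + 2.5`, where the margin covers O(100) pair prefactors. The
real-space decay estimate uses the *largest* Gaussian radius pair (the
smallest α), which is the slowest-decaying term. Net-charged cells receive
the uniform-background (jellium) regularization; it is folded into M as a
constant `−πk_e/(Vκ²)` on every entry, which reproduces the standard
`−πk_e/(2Vκ²)Q_tot²` energy for any charge vector and makes the matrix
splitting-parameter independent. Absolute energies of charged periodic
cells are convention-dependent (tin-foil boundary); energy *differences*
at fixed Q_tot are not. Partial (1D/2D) periodicity is not supported.

## Charge equilibration

The constrained minimizer of `U_Qeq = ½QᵀMQ + χᵀQ + ½QᵀJQ` is obtained from
the dense bordered KKT system; the multiplier λ is returned (it is the
negative equalized electronegativity). Batches of independent structures
share one solve: the Coulomb matrix is assembled only over within-structure
atom pairs, and one constraint row per structure borders the system.
Positive definiteness is not pre-checked; the solver reports the smallest
eigenvalue of `M + diag(J)` on failure. The softplus constructions upstream
keep J and γ positive, which makes failures rare in practice.

Three independent routes validate the solve: a constraint-eliminated
steepest-descent oracle with exact (Cauchy) steps on the reduced quadratic;
the closed-form two-atom solution; and implicit-function Jacobians
(dQ/dχ, dQ/dJ, dQ/dR) checked against central finite differences. The
model path differentiates through the solve with the same
implicit-function adjoint, implemented as a `solve` primitive whose
backward is again a solve; because the adjoint references the solution
node, second-order chains (force-matching gradients) are exact. The
envelope-theorem shortcut (dropping dQ/dR) is *not* used for the model:
equilibrated charges feed the charge embedding, so their position
sensitivity contributes to forces. For the synthetic reference labels,
whose energy is a pure function of (R, Q*), the charge-response term
vanishes exactly at the constrained optimum (dU/dQ is constant on the
constraint surface and 1ᵀdQ/dR = 0), so reference forces are evaluated at
fixed Q and verified by finite differences.

## Backbone

The network is a strictly local scalar GNN: per-directed-edge features,
initialized from a learned species-pair embedding concatenated with
envelope-damped Bessel radial features (8 functions, standard smooth
polynomial envelope with p = 6), then updated through interaction layers
`w_ij = Σ_{k∈N(i)} W(x_ij, x_ik)`, `x^{l+1} = x^l ⊕ U(w_ij, x_ij)` with a
variance-preserving weighted residual `⊕: (x + βu)/√(1+β²)`, β learnable
and initialized at 0 (layers start as identities). Tensorial/equivariant
feature tracks are deliberately omitted: with scalar distance-based
features, rotation/translation invariance is structural, and desk-scale
tests stay cheap. This is the major simplification relative to full
equivariant architectures, and it bounds the geometric expressiveness of
the backbone (angular information enters only indirectly through
environment sums). MLPs have two hidden layers with SiLU activations; the
energy readout is a small MLP over final edge features, envelope-damped
and zero-initialized so an untrained model predicts exactly ΔU = 0.

A node-feature mode provides a minimal message-passing backbone plus the
adapter used to couple the charge layer to MPNN architectures: edge inputs
`(p_env(r_ij)·h_i ‖ e_rbf,ij)`, output aggregated as a residual
`h_i ← h_i + ε Σ_j x_ij` with learnable ε.

## The charge-equilibration layer

One block sits between interaction layers (default placement: the middle,
⌊L/2⌋). Per directed edge, MLP_R (final layer zero-initialized) predicts
(χ̃_ij, J̃ᴿ_ij); summing over edges leaving atom i and scaling by a global
learnable f gives χ_i. Hardness is `σ₊(J̃ᶻ_i)` per species, optionally
`σ₊(J̃ᶻ_i, Σ_j J̃ᴿ_ij)` with environment contributions (off by default).
Radii scale tabulated single-bond covalent radii by `σ₊(s̃_i)/log 2`, which
is exactly 1 at s̃ = 0. After the solve, `y_ij = MLP_Q(Q_i, Q_j, c_i, c_j)`
embeds the charges (c is a separate per-species context vector, kept
independent of the backbone's species embedding to avoid coupling), and
`x^{l+1} = MLP_x(y_ij, x^l)·p_env(r_ij)` replaces the edge features.

Initialization was chosen for a predictable and *trainable* cold start:
with MLP_R's final layer at zero, χ = 0 and the charges are determined by
the constraint and the hardness/Coulomb terms alone; f is initialized at 1,
not 0, because f = 0 together with the zero final layer is a gradient
saddle from which the electronegativity path cannot escape. Raw species
hardness initializes at 8 (σ₊(8) ≈ 8 eV/e², a typical atomic hardness).
Note that a cold-started model does not generally give uniform charges:
even with equal χ, J, γ the Coulomb off-diagonals make the equilibrated
charges geometry-dependent; uniformity holds only for symmetric
arrangements. Isolated atoms (no edges) get χ = 0 and species-only J; the
solver still assigns them charge through the conservation constraint.

## Training

Force matching minimizes
`(1/D)Σ_i [γ_U‖ΔU_i‖² + γ_F/(3N_i)‖ΔF_i‖² + γ_Q/N_i‖ΔQ_i‖²]` on
shifted energies `Û = U − Σ_s U_s N_s` with per-species shifts from a ridge
fit. Optimization is Adam with a polynomial step-size schedule
`lr(t) = lr₀(c + (1−c)(1−t/T)^κ)`, decoupled weight decay, and global-norm
gradient clipping as a NaN guard. Batch graphs are assembled once and
reused across epochs (fixed membership, shuffled visiting order) — with
per-structure geometry fixed, this trades gradient-noise diversity for a
large constant-factor speedup. The checkpoint with the lowest validation
loss is returned. An optional Polyak-averaging mode exists but is off in
the shipped protocols: without bias correction it is dominated by the
initialization at these step counts and degrades accuracy.

Defaults: γ_U = 1, γ_F = 10, γ_Q = 1 (the loss weights are
problem-specific by nature; these are generic). All in the config file.

## Synthetic reference data

The generator stands in for quantum-mechanical reference data with an
*exactly solvable* model: per-species Qeq parameters (two fictitious
species A/B mapped to Z = 11/17 so radius and mass lookups work;
χ = 2.0/6.0 eV/e, J = 8.0/10.0 eV/e², γ equal to the tabulated covalent
radii 1.55/0.99 Å) plus an envelope-damped Morse pair sum
(A–B: D 1.2 eV, a 1.7 Å⁻¹, r_e 2.4 Å; like pairs shallower and longer).
The χ contrast drives ~0.1–0.3 e of charge transfer, typical of ionic
compounds. Geometry families mirror classic charge-transfer benchmarks:
jittered alternating chains of 4–8 atoms, rock-salt fragments (pristine
cube, anion vacancy, extra cation) emitted as geometry-identical twins
with Q_tot = 0 and +1, and single-atom displacement scans. Labels are
exact: charges from the reference solve, energies from U_Qeq + Morse,
forces analytic. Gaussian label noise is available but defaults to zero.

Because the reference lives inside (or very near) the model family —
short-ranged smooth pair terms, per-species Qeq parameters with radii equal
to the covalent-radius initialization — the parameter-recovery benchmark
tests *mechanism*, not chemistry: passing it shows the layer can learn and
invert the charge-equilibration map from data, that gradients through the
solver are correct, and that a local model without the layer cannot
resolve charge states. It does not show DFT-level accuracy, transferability
across chemistries, many-body short-range physics, or robustness to label
noise.

## Benchmark protocol and problem sizes

The shipped protocol (`celliq.protocols`) trains on 2000 structures
(half chains, half clusters, both charge states mixed), validates on 250,
tests on 250, with a compact model (2 interaction layers, width 16, hidden
16, cutoff 4.5 Å) for 110 epochs of Adam (lr 1.2e-2, κ = 1.5, batch 32),
supervising energies and charges (γ_U = 3, γ_F = 0, γ_Q = 100). The strong
charge weight balances the e²-scale charge residuals against eV²-scale
energy residuals; the force term is omitted in this protocol because its
metrics are charge RMSE and energy MAE and the double-backward cost buys
no accuracy on those at this scale. Typical results (median of seeds
0–2): test charge RMSE ≈ 2 me, energy MAE ≈ 1.9 meV/atom, twin-gap error
≈ 0.2% of the ~6 eV gap. MD stability uses the trained model on four
clusters for 20,000 BAOAB steps (dt 0.5 fs, 300 K, friction 100 ps⁻¹).

## Molecular dynamics

Langevin dynamics uses the BAOAB splitting (exact Ornstein–Uhlenbeck
velocity update), chosen for its configurational accuracy; with zero
friction and temperature it reduces exactly to velocity Verlet (total
energy drift of a Morse dimer < 1e-4 eV over 10,000 steps at dt = 0.5 fs,
and the thermostatted kinetic temperature matches the target within 5%).
Masses come from a shipped standard-atomic-weight table. Bonds for the
stability diagnostics are the initial-frame pairs within 1.25× the
covalent-radius sum (floored at 2.6 Å so ionic contacts count as bonds);
a trajectory fails on any non-finite value, any distance below 0.5 Å, or
any bond stretched beyond 2×. Diagnostics are tracked every step, not just
at reported frames. Ensembles of independent systems can be propagated
jointly, sharing one batched force evaluation per step; they remain
physically non-interacting (block-masked Coulomb, separate constraints).

## Numerical choices and degenerate inputs

- Near-coincident pairs (r < 1e-6 Å) use the series limit `2α/√π` of the
  screened interaction; truly coincident atoms (r < 1e-8 Å) are rejected.
- Neighbor lists use a strict `r < cutoff` test, so the envelope (zero at
  the cutoff) never multiplies an edge at exactly zero; lists are rebuilt
  every evaluation (no Verlet skin).
- Periodic neighbor lists require cutoff ≤ half the minimum cell width and
  use the minimum image; at most one image per pair can then be inside the
  sphere.
- The extended-XYZ writer prints 17 significant digits, so write→read round
  trips are bit-identical.
- Deterministic everywhere: parameter initialization, batch shuffling, MD
  noise, and data generation all derive from explicit integer seeds;
  environment sums accumulate in a fixed edge order.

## Scope and limitations

- The potential model (forces, training, MD) supports open boundaries;
  the electrostatics and Qeq modules additionally support fully periodic
  cells through the Ewald operator. Differentiable periodic forces are not
  implemented.
- Scalar features only; no equivariant tensor track.
- Dense O(N³) KKT solve; appropriate for ≲10³ atoms. Iterative solvers and
  mesh Ewald are out of scope.
- One charge-equilibration block per model (validated in config).
- External electric fields, charge-dependent dispersion, and
  charge-constrained subregions are not modeled.
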