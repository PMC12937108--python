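# Methods

## Model and conventions

All internal quantities are Hartree atomic units with ħ = 1 over
mass-weighted normal coordinates, so the kinetic operator of each mode is
T(Q_i) = −½ ∂²/∂Q_i² and a harmonic mode of frequency ω (hartree) has
potential ω²Q²/2.  Converters for cm⁻¹, eV and fs live in
`vibromps.units`.  The vibronic Hamiltonian is the block operator with
vibrational Hamiltonians T + v_α on the diagonal and real coupling
surfaces V_αβ off the diagonal; couplings are stored once per unordered
state pair and applied Hermitianly, and complex couplings are rejected
(all integral formulas assume a real-valued modal basis).

Surfaces are n-mode expansions.  Although the pure many-body expansion
starts at the one-body level, every container carries a zeroth-order
constant F0: diagonal surfaces need it for vertical electronic energies
and couplings for constant (Condon-like) interaction terms.  Three-body
terms are accepted structurally (F3, term-list format) but not evaluated;
the synthetic models used here carry at most two-body terms.

## Modal bases

Two constructions:

- `harmonic_basis(ω, N)` — analytic Hermite functions on a Gauss–Hermite
  grid scaled by 1/√ω, with the Gaussian weight factored back in so stored
  weights implement a plain ∫dQ rule.  Default rule order max(2N+16, 48);
  a rule of order ≥ 2N already reproduces the Gram identity to 1e−10.
  The kinetic matrix is the analytic pentadiagonal form.
- `relaxed_basis(v1, N, ...)` — lowest N eigenfunctions of T + v1 from an
  exact sine-DVR discretization on a uniform grid (default 401 interior
  points).  Default bounds are ±7 classical turning points of the
  reference frequency (±7/√ω), configurable.  This reproduces harmonic
  levels to ~1e−13 at 201 points on [−8, 8] and the closed-form Morse
  spectrum to ~1e−12 on an adequate box.

The default production basis is the *electronic-ground-state* eigenbasis
per mode (relaxed basis on the state-0 one-body potential): in it the
Condon wavepacket is exactly the occupation-zero product state, and the
ground-surface one-body blocks are diagonal.  Displaced-oscillator or
Morse eigenbases can be supplied instead where large Huang–Rhys factors
make the ground-state basis inefficient.  Eigenfunction signs are fixed
deterministically (positive at the leftmost antinode, operationally the
first grid point reaching half the function's max magnitude) so integrals
are bit-reproducible across runs.

## Integrals and screening

One-body blocks are quadratures of φ_k (T + v1) φ_h on the basis grid
(potential-only for coupling surfaces); two-body blocks use the tensor
product of the 1D rules — no sparse/Smolyak grids, which is adequate at
desk scale.  An optional convergence check recomputes the potential part
on a doubled grid and raises if any entry moves more than a tolerance
(default 1e−8).  During term-list assembly, coefficients below a
screening threshold (default 1e−12 hartree) are dropped; the threshold is
an explicit argument.

## Second-quantized term list and MPO

Terms have the form coeff · a†_α a_β · Π_i (b†_{k_i} b_{h_i}) with at most
one composite factor per mode, modes strictly increasing.  Because factors
on distinct modes commute, the operator string of a two-body term is
stored as per-mode composites — this is what removes the auxiliary vacuum
level and keeps vibrational local operators at exactly N_i × N_i (the
matrix units E_kh).  Electronic sites are hard-core bosonic: with total
electronic charge fixed at one and only single-transfer terms a†_α a_β, no
exchange-statistics strings are observable, so none are used.

The plain-text term-list file (`coeff alpha beta [i k h [j k h]]` with a
header naming N_el, M and the N_i) is the bit-exact interchange format
between integral generation and MPO compilation.

MPO compilation proceeds by (1) grouping terms per (electronic pair, mode
tuple) and SVD-factorizing each two-mode coefficient block into a short
sum of one-site operator products (shared-factor merging), then (2)
assembling the formal sum-of-strings MPO left to right with an SVD
compression at every bond (relative cutoff 1e−14) plus one right-to-left
rebalancing sweep.  The compressed MPO's dense reconstruction matches the
term-by-term matrix to ≤1e−10 on every instance tested (it is typically at
1e−14), and bond dimensions come out near-minimal (≤5 for the two-body
models used here).

## U(1) bookkeeping

Electronic particle number is conserved, so each MPS bond carries integer
charge labels (cumulative electronic occupation).  Tensors are stored
densely, but *every* split — canonicalization, truncation, the two-site
TDVP/DMRG SVDs — is performed blockwise per matched charge sector;
entries outside matched sectors carry no singular value and are projected
out.  Consequently charge-violating entries are exactly zero after any
split (asserted by a block-structure audit in the tests), and states in
different total-charge sectors are exactly orthogonal.  Truncation pools
singular values across sectors, keeps at most m_max of them per bond
(descending, stable keep-first tie-break — deterministic and seedless) and
additionally discards σ with σ²/Σσ² < 1e−12; the summed discarded squared
weight is returned, and 1 − discarded equals the fidelity to the
untruncated state.

## Ground-state DMRG

Standard two-site sweeps.  Each local eigenproblem is restricted to the
U(1) sector of the current block (the complementary sectors of the
two-site product space are not part of the variational state) and solved
densely below dimension 500, otherwise by restarted Lanczos with full
reorthogonalization (residual tolerance 1e−9), started from the current
block.  A cheap Hermiticity spot-check (⟨x|Hy⟩ vs ⟨Hx|y⟩ on a random
pair) guards every microiteration.  Convergence is declared when the
inter-sweep energy change drops below tolerance; energies are variational
upper bounds and non-increasing across sweeps.

## Two-site TDVP

One time step = one full sweep (forward then backward), the symmetric
second-order scheme: each two-site block evolves by exp(−i H_eff dt/2) and
each intermediate single-site center back-evolves by exp(+i K_eff dt/2) in
both directions, with the state truncated back to the fixed-m manifold at
every two-site split.  Local exponentials use Lanczos with tolerance
1e−10 and Krylov dimension capped at 30; if the cap is hit (large ‖H‖dt),
the step is split recursively into half-steps rather than failing.  An
imaginary-time flag replaces −i → −1 with per-sweep renormalization for
variational cooling checks.  Default run settings are dt = 0.5 fs with
one sweep per step (800 steps = 400 fs); all configurable.

Without a bond cap the propagation conserves the norm and ⟨H⟩ to ~1e−12
over hundreds of steps; with truncation the reported populations are
normalized, and their sum stays at 1 to machine precision because the
electronic number operators commute with the U(1) structure.

On a fully resolvable (oracle-sized) lattice the integrator without a
bond cap is exact up to Krylov tolerance — one sweep can grow every bond
to the required rank — while under aggressive truncation the manifold
projection error, O(dt) per step, dominates.  The dt³ local splitting
error is therefore audited on an instance designed to expose it: a weakly
coupled two-state/two-mode model whose bond cap (m = 4) sits just below
the rank the step requires.  There `step_error_probe` observes local
order 3.0 over three successive dt-halvings.

## Observables and spectra

The Condon initial state copies the ground vibrational wavepacket onto the
target surface — in the ground-state modal basis, the occupation-zero
product state with the target electronic site occupied; the constant
transition dipole μ0 only scales overall intensity and is reported
separately rather than baked into the normalized state.  Spectra use the
half-line transform I(ω_k) = Σ_n w_n e^{iω_k t_n} C(t_n) with trapezoid
end weights; the magnitude |I| is reported and the axis may be shifted to
place the 0–0 line.  Zero-padding and Gaussian windowing exist as flags
but default off.  Peak picking takes local maxima above a configurable
floor (default 1% of the global maximum) with quadratic sub-grid
refinement.

## Synthetic models

`random_coupled_model(M, seed, ...)` emulates a vibronically coupled pair
of excited states of a rigid organic chromophore: mode frequencies drawn
from 800–1800 cm⁻¹, a harmonic lower surface, an upper surface displaced
by Huang–Rhys factors 0.05–0.35 with ±10% frequency scaling and Morse
distortion (D between 15 and 40 vibrational quanta) on about half the
modes, a bilinear two-body term on the first mode pair, a vertical gap of
0.02 hartree (~0.54 eV) and a constant-plus-linear diabatic coupling of
scale 0.004 hartree (~0.1 eV) — magnitudes typical of mid-size
chromophores.  Everything is drawn from an explicit seed; fixtures are
deterministic.

What the generator does *not* emulate: real normal-mode Duschinsky
rotations beyond one bilinear term, coordinate-dependent transition
dipoles, more than two coupled states, and solvent/finite-temperature
broadening.  Passing tests therefore demonstrate correctness of the
Hamiltonian construction, the tensor-network algebra and the integrator —
not quantitative spectroscopy of any specific molecule.

Two instances are frozen as named study cases:

- *Integrator-order audit*: seed 7, coupling scale 5e−4, two modes,
  N = 10, m_max = 4 (see the TDVP section for why a weakly coupled,
  just-under-resolved instance is the right probe).
- *Convergence morphology*: seed 11, coupling scale 1e−3, three modes.
  At the generator's default coupling the dynamics is not basis-converged
  by N_max = 12 (max_t |C_12 − C_16| ≈ 0.5), so a basis-size stabilization
  study would be undefined; the weaker-coupling instance is verified to be
  in the convergent regime.  Its weakest-peak metric is evaluated on
  Gaussian-windowed spectra (30 fs width) because undamped |I| peaks are
  grid-sensitive; the window is applied identically at every basis size.

## Numerical choices and limitations

- SVD tie-breaks: stable descending sort, keep-first; no randomness
  anywhere in the tensor algebra.
- Dense-oracle cap: 20 000 basis states by default (explicit override),
  eigendecomposition rather than Krylov — exactness over speed; the
  oracle is a verification device, not a production propagator.
- Degenerate inputs: zero states/modes are supported (an M = 0 model is a
  bare multi-level system); empty Hamiltonians are rejected at MPO
  compilation.
- Problem sizes in the shipped tests and the acceptance script are
  desk-scale by design: dense dimensions ≤ 3456, bond dimensions ≤ 24,
  propagations of 100–640 steps — sizes at which every quantity can be
  cross-checked against the dense oracle or a closed form on a single CPU
  in about a minute each.
- Not implemented: time-dependent Hamiltonians, finite-temperature
  propagation, tree tensor networks, excited-state (orthogonality-
  constrained) DMRG, VSCF-style coupled-mode basis optimization,
  derivative (kinetic) nonadiabatic couplings, non-Condon excitation
  operators, automatic PES fitting, and the one-site-per-basis-function
  lattice layout.
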