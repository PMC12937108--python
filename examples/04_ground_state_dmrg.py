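"""Variational ground state with two-site DMRG.

Optimizes a random charge-1 MPS on a seeded two-state, two-mode vibronic
model and compares the converged energy with the exact lowest eigenvalue
from the dense oracle, demonstrating the variational bound and sweep
convergence.
"""

import numpy as np

from vibromps import (
    Lattice,
    assemble_hamiltonian,
    build_dense,
    compile_mpo,
    harmonic_basis,
    optimize,
    random_coupled_model,
    random_mps,
)

model = random_coupled_model(2, seed=3)
bases = [harmonic_basis(model.frequencies[i], 6, mode=i) for i in range(2)]
ham = assemble_hamiltonian(model, bases)
mpo = compile_mpo(ham)
e_exact = np.linalg.eigvalsh(build_dense(ham).H)[0]

psi0 = random_mps(Lattice(2, (6, 6)), m=8, seed=1)
psi, report = optimize(psi0, mpo, m_max=None, n_sweeps=30)

print("sweep   energy (hartree)")
for i, e in enumerate(report.energies, 1):
    print(f"  {i}     {e:.12f}")
print(f"\nexact ground energy: {e_exact:.12f}")
print(f"variational gap:     {report.energies[-1] - e_exact:.2e}")
print("Energies decrease monotonically sweep over sweep and close the gap "
      "to the exact result at full bond dimension.")
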