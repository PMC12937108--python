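"""Shared fixtures: small seeded models, bases and compiled Hamiltonians."""

import numpy as np
import pytest

from vibromps.basis import harmonic_basis
from vibromps.mpo import compile_mpo
from vibromps.mps import Lattice
from vibromps.nmode import (
    NModeFunction,
    VibronicModel,
    random_coupled_model,
)
from vibromps.oracle import build_dense
from vibromps.sqham import assemble_hamiltonian


@pytest.fixture(scope="session")
def coupled_2x2():
    """Random anharmonic 2-state 2-mode model with N=6 harmonic bases,
    its term list, MPO, dense oracle and lattice (dense dim 72)."""
    model = random_coupled_model(2, seed=3)
    bases = [harmonic_basis(model.frequencies[i], 6, mode=i) for i in range(2)]
    ham = assemble_hamiltonian(model, bases)
    mpo = compile_mpo(ham)
    dense = build_dense(ham)
    return {
        "model": model,
        "bases": bases,
        "ham": ham,
        "mpo": mpo,
        "dense": dense,
        "lattice": Lattice.from_sqham(ham),
    }


@pytest.fixture(scope="session")
def rabi_two_level():
    """Degenerate two-level model with constant coupling c (no modes)."""
    c = 0.003
    model = VibronicModel(
        N_el=2,
        M=0,
        frequencies=np.zeros(0),
        diag={0: NModeFunction(M=0, F0=0.0), 1: NModeFunction(M=0, F0=0.0)},
        offdiag={(0, 1): NModeFunction(M=0, F0=c)},
    )
    ham = assemble_hamiltonian(model, [])
    return {"model": model, "ham": ham, "mpo": compile_mpo(ham), "c": c,
            "lattice": Lattice.from_sqham(ham)}
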