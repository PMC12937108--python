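"""Dense reference implementation (exact oracle).

Builds the full direct-product vibronic Hamiltonian matrix from the same
second-quantized term list the tensor-network path consumes, and propagates
exactly by eigendecomposition.  Basis enumeration is lexicographic in
(electronic state gamma, n_1, ..., n_M): exactly one electronic state is
occupied, so the dimension is D = N_el * prod_i N_i.

Exactness over speed: this is the acceptance reference for every
tensor-network result at desk scale, not a production propagator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product as _iterproduct

import numpy as np
import scipy.sparse as sp

from .sqham import SQHamiltonian

__all__ = ["DenseSystem", "build_dense", "dense_propagate", "single_occupation_indices"]

DEFAULT_CAP = 20_000


@dataclass
class DenseSystem:
    N_el: int
    Ns: tuple
    H: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def D(self) -> int:
        return self.H.shape[0]

    def state_index(self, gamma: int, occ) -> int:
        idx = gamma
        for i, n in enumerate(occ):
            idx = idx * self.Ns[i] + n
        return idx

    def populations_of(self, v: np.ndarray) -> np.ndarray:
        """Per-electronic-state probability content of a normalized vector."""
        block = int(np.prod(self.Ns)) if self.Ns else 1
        p = np.abs(v) ** 2
        return np.array(
            [p[g * block : (g + 1) * block].sum() for g in range(self.N_el)]
        )


def build_dense(ham: SQHamiltonian, cap: int = DEFAULT_CAP) -> DenseSystem:
    """Assemble the dense vibronic matrix term by term from matrix units."""
    Ns = tuple(ham.Ns)
    block = int(np.prod(Ns)) if Ns else 1
    D = ham.N_el * block
    if D > cap:
        raise ValueError(
            f"dense dimension {D} exceeds the cap {cap}; pass cap= explicitly "
            "to override"
        )
    strides = np.empty(len(Ns), dtype=np.int64)
    acc = 1
    for i in range(len(Ns) - 1, -1, -1):
        strides[i] = acc
        acc *= Ns[i]
    rows, cols, vals = [], [], []
    for t in ham.terms:
        a, b = t.elec
        fixed = {i: (k, h) for i, k, h in t.bos}
        free = [i for i in range(len(Ns)) if i not in fixed]
        base_r = a * block + sum(k * strides[i] for i, (k, _) in fixed.items())
        base_c = b * block + sum(h * strides[i] for i, (_, h) in fixed.items())
        if free:
            offs = np.zeros(1, dtype=np.int64)
            for i in free:
                offs = (offs[:, None] + (np.arange(Ns[i]) * strides[i])[None, :]).ravel()
        else:
            offs = np.zeros(1, dtype=np.int64)
        rows.append(base_r + offs)
        cols.append(base_c + offs)
        vals.append(np.full(offs.size, t.coeff))
    Hs = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(D, D),
    )
    return DenseSystem(N_el=ham.N_el, Ns=Ns, H=np.asarray(Hs.todense()))


def dense_propagate(sys: DenseSystem, v0: np.ndarray, times_au: np.ndarray):
    """Exact propagation by eigendecomposition.

    Returns ``(states, autocorr, populations)`` where ``states`` has one
    column per time, ``autocorr[n] = <v0|v(t_n)>`` and populations has shape
    (n_times, N_el).  ``times_au`` are in atomic units of time.
    """
    v0 = np.asarray(v0, dtype=complex)
    n0 = np.linalg.norm(v0)
    if not np.isclose(n0, 1.0, atol=1e-8):
        raise ValueError("initial vector must be normalized")
    evals, U = np.linalg.eigh(sys.H)
    c = U.conj().T @ v0
    phases = np.exp(-1j * np.outer(evals, np.asarray(times_au)))
    states = U @ (phases * c[:, None])
    autocorr = states.conj().T @ v0
    autocorr = np.conj(autocorr)  # <v0|v(t)>
    pops = np.array([sys.populations_of(states[:, n]) for n in range(states.shape[1])])
    return states, autocorr, pops


def single_occupation_indices(N_el: int, Ns: tuple) -> np.ndarray:
    """Indices of the charge-1 subspace inside the full MPS product space.

    The MPS product space enumerates all electronic occupation patterns
    (site 0 slowest); the oracle keeps only patterns with exactly one
    occupied electronic site, ordered by which site is occupied and then by
    modal occupations - this function returns that embedding, so dense MPS /
    MPO reconstructions can be compared entrywise with the oracle matrix.
    """
    block = int(np.prod(Ns)) if Ns else 1
    out = []
    for g in range(N_el):
        pattern = 0
        for l in range(N_el):
            pattern = pattern * 2 + (1 if l == g else 0)
        out.append(pattern * block + np.arange(block))
    return np.concatenate(out)
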