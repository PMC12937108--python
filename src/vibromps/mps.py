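"""Vibronic matrix product states with U(1) electronic-number bookkeeping.

Lattice layout: the N_el electronic sites come first (physical dimension 2,
occupation 0 or 1, encoding which diabatic state is populated), followed by
one site per vibrational mode with physical dimension N_i (the modal basis
functions, occupations 0 .. N_i - 1).  Because the bosonic operators only
ever appear as composite matrix units b^dag_k b_h, the vibrational local
dimension is exactly N_i - no auxiliary vacuum level exists anywhere.

Electronic particle number is conserved, so every bond carries integer
charge labels (cumulative electronic occupation to the left).  Tensors are
stored densely but all splits (QR/SVD, truncation) are performed blockwise
per charge sector; entries that violate charge conservation are projected
out by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Lattice",
    "VibronicMPS",
    "product_state",
    "random_mps",
    "truncate",
    "overlap",
    "norm",
    "expectation_mpo",
    "local_expectation",
]


@dataclass(frozen=True)
class Lattice:
    """Site layout: N_el electronic sites then one site per mode."""

    N_el: int
    Ns: tuple

    @property
    def L(self) -> int:
        return self.N_el + len(self.Ns)

    @property
    def dims(self) -> tuple:
        return (2,) * self.N_el + tuple(self.Ns)

    def phys_charges(self, site: int) -> np.ndarray:
        if site < self.N_el:
            return np.array([0, 1])
        return np.zeros(self.dims[site], dtype=int)

    @classmethod
    def from_sqham(cls, ham) -> "Lattice":
        return cls(N_el=ham.N_el, Ns=tuple(ham.Ns))


def _block_svd(mat, row_q, col_q, m_max=None, cutoff=0.0, return_info=False):
    """Charge-sector SVD of a 2D matrix with global truncation.

    Singular values are pooled across sectors, sorted descending (stable,
    keep-first on ties), capped at ``m_max`` and filtered by the relative
    discarded-weight criterion sigma^2 / sum sigma^2 >= cutoff.  Entries of
    ``mat`` outside matched charge sectors carry no singular value and are
    therefore projected out; their weight counts toward the discarded
    weight.

    Returns ``(U, s, Vh, new_q, discarded)`` with ``discarded`` the total
    squared weight removed from ``mat``.
    """
    row_q = np.asarray(row_q)
    col_q = np.asarray(col_q)
    norm2 = float(np.sum(np.abs(mat) ** 2))
    sectors = sorted(set(row_q.tolist()) & set(col_q.tolist()))
    svals, owners = [], []
    pieces = {}
    for q in sectors:
        ri = np.flatnonzero(row_q == q)
        ci = np.flatnonzero(col_q == q)
        U, s, Vh = np.linalg.svd(mat[np.ix_(ri, ci)], full_matrices=False)
        pieces[q] = (ri, ci, U, Vh)
        for p, sv in enumerate(s):
            svals.append(sv)
            owners.append((q, p))
    svals = np.asarray(svals)
    if svals.size == 0:
        raise ValueError("no charge sector matches between row and column spaces")
    total = float(np.sum(svals**2))
    order = np.argsort(-svals, kind="stable")
    keep = []
    for rank, idx in enumerate(order):
        if m_max is not None and rank >= m_max:
            break
        sv = svals[idx]
        if total > 0 and cutoff > 0 and sv**2 / total < cutoff:
            break
        if sv == 0.0 and keep:
            break
        keep.append(idx)
    if not keep:
        keep = [int(order[0])]
    k = len(keep)
    U_full = np.zeros((mat.shape[0], k), dtype=complex)
    Vh_full = np.zeros((k, mat.shape[1]), dtype=complex)
    s_keep = np.empty(k)
    new_q = np.empty(k, dtype=int)
    for c, idx in enumerate(keep):
        q, p = owners[idx]
        ri, ci, U, Vh = pieces[q]
        U_full[ri, c] = U[:, p]
        Vh_full[c, ci] = Vh[p, :]
        s_keep[c] = svals[idx]
        new_q[c] = q
    discarded = max(norm2 - float(np.sum(s_keep**2)), 0.0)
    if return_info:
        info = {"n_sv": int(np.sum(svals > 0)), "norm2": norm2}
        return U_full, s_keep, Vh_full, new_q, discarded, info
    return U_full, s_keep, Vh_full, new_q, discarded


class VibronicMPS:
    """MPS over the vibronic lattice with per-bond charge labels.

    ``tensors[l]`` has shape (D_l, d_l, D_{l+1}); ``bond_q[l]`` labels bond
    l (length D_l).  ``center`` is the canonical-center site: tensors left
    of it are left-canonical, tensors right of it right-canonical.
    """

    def __init__(self, lattice: Lattice, tensors, bond_q, center=None):
        self.lattice = lattice
        self.tensors = [np.asarray(t, dtype=complex) for t in tensors]
        self.bond_q = [np.asarray(q, dtype=int) for q in bond_q]
        self.center = center
        if len(self.tensors) != lattice.L or len(self.bond_q) != lattice.L + 1:
            raise ValueError("tensor/bond count does not match lattice")

    # -- basics ------------------------------------------------------------

    def copy(self) -> "VibronicMPS":
        return VibronicMPS(
            self.lattice,
            [t.copy() for t in self.tensors],
            [q.copy() for q in self.bond_q],
            self.center,
        )

    def bond_dims(self) -> list:
        return [t.shape[0] for t in self.tensors] + [self.tensors[-1].shape[2]]

    @property
    def total_charge(self) -> int:
        return int(self.bond_q[-1][0])

    def norm(self) -> float:
        return float(np.sqrt(np.real(overlap(self, self))))

    def normalize(self) -> "VibronicMPS":
        c = self.center if self.center is not None else 0
        n = self.norm()
        if n == 0:
            raise ValueError("cannot normalize the zero state")
        self.tensors[c] = self.tensors[c] / n
        return self

    def charge_violation(self) -> float:
        """Max |entry| breaking charge conservation (0 for a clean state)."""
        worst = 0.0
        for l, A in enumerate(self.tensors):
            ql = self.bond_q[l]
            qr = self.bond_q[l + 1]
            c = self.lattice.phys_charges(l)
            bad = ql[:, None, None] + c[None, :, None] != qr[None, None, :]
            if np.any(bad):
                worst = max(worst, float(np.max(np.abs(A[bad]))))
        return worst

    # -- canonicalization --------------------------------------------------

    def _shift_right(self, l: int, m_max=None, cutoff=0.0) -> float:
        """Left-orthogonalize site l, absorbing the remainder into l+1."""
        A = self.tensors[l]
        Dl, d, Dr = A.shape
        row_q = (self.bond_q[l][:, None] + self.lattice.phys_charges(l)[None, :]).ravel()
        U, s, Vh, new_q, disc = _block_svd(
            A.reshape(Dl * d, Dr), row_q, self.bond_q[l + 1], m_max, cutoff
        )
        self.tensors[l] = U.reshape(Dl, d, -1)
        carry = s[:, None] * Vh
        self.tensors[l + 1] = np.tensordot(carry, self.tensors[l + 1], axes=(1, 0))
        self.bond_q[l + 1] = new_q
        return disc

    def _shift_left(self, l: int, m_max=None, cutoff=0.0) -> float:
        """Right-orthogonalize site l, absorbing the remainder into l-1."""
        A = self.tensors[l]
        Dl, d, Dr = A.shape
        col_q = (
            self.bond_q[l + 1][None, :] - self.lattice.phys_charges(l)[:, None]
        ).ravel()
        U, s, Vh, new_q, disc = _block_svd(
            A.reshape(Dl, d * Dr), self.bond_q[l], col_q, m_max, cutoff
        )
        self.tensors[l] = Vh.reshape(-1, d, Dr)
        carry = U * s[None, :]
        self.tensors[l - 1] = np.tensordot(self.tensors[l - 1], carry, axes=(2, 0))
        self.bond_q[l] = new_q
        return disc

    def canonicalize(self, center: int = 0) -> "VibronicMPS":
        """Bring to mixed-canonical form with the given center (in place)."""
        for l in range(center):
            self._shift_right(l)
        for l in range(self.lattice.L - 1, center, -1):
            self._shift_left(l)
        self.center = center
        return self

    def canonical_deviation(self) -> float:
        """Max deviation from the canonical conditions on the center flanks."""
        dev = 0.0
        c = self.center if self.center is not None else 0
        for l in range(c):
            A = self.tensors[l]
            m = A.reshape(-1, A.shape[2])
            dev = max(dev, float(np.max(np.abs(m.conj().T @ m - np.eye(A.shape[2])))))
        for l in range(self.lattice.L - 1, c, -1):
            A = self.tensors[l]
            m = A.reshape(A.shape[0], -1)
            dev = max(dev, float(np.max(np.abs(m @ m.conj().T - np.eye(A.shape[0])))))
        return dev

    def to_dense(self) -> np.ndarray:
        """Contract to a full state vector over prod(dims) (test-scale only)."""
        v = np.ones((1, 1), dtype=complex)
        for A in self.tensors:
            v = np.tensordot(v, A, axes=(1, 0))
            v = v.reshape(-1, A.shape[2])
        return v[:, 0]


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------


def product_state(lattice: Lattice, gamma: int, occupations=None) -> VibronicMPS:
    """Bond-dimension-1 product state: electronic state ``gamma`` occupied,
    mode i in modal basis function ``occupations[i]`` (default 0).

    With the ground-state modal basis this is the Condon initial wavepacket
    for excitation into state ``gamma``.
    """
    if not (0 <= gamma < lattice.N_el):
        raise ValueError(f"electronic state {gamma} out of range")
    occ = list(occupations) if occupations is not None else [0] * len(lattice.Ns)
    if len(occ) != len(lattice.Ns):
        raise ValueError("need one occupation per mode")
    tensors, bond_q = [], [np.array([0])]
    q = 0
    for l in range(lattice.L):
        d = lattice.dims[l]
        if l < lattice.N_el:
            idx = 1 if l == gamma else 0
        else:
            idx = occ[l - lattice.N_el]
            if not (0 <= idx < d):
                raise ValueError(f"occupation {idx} out of range for mode {l - lattice.N_el}")
        t = np.zeros((1, d, 1), dtype=complex)
        t[0, idx, 0] = 1.0
        tensors.append(t)
        q += int(lattice.phys_charges(l)[idx])
        bond_q.append(np.array([q]))
    return VibronicMPS(lattice, tensors, bond_q, center=0)


def random_mps(
    lattice: Lattice, m: int, seed: int, total_charge: int = 1
) -> VibronicMPS:
    """Charge-respecting random MPS (fixed seed), normalized, center 0."""
    rng = np.random.default_rng(seed)
    # assign bond charges: all values reachable from both ends
    bond_q = [np.array([0])]
    maxc = [0]
    for l in range(lattice.L):
        maxc.append(maxc[-1] + int(lattice.phys_charges(l).max()))
    minc_right = [0] * (lattice.L + 1)
    for l in range(lattice.L - 1, -1, -1):
        minc_right[l] = minc_right[l + 1] + int(lattice.phys_charges(l).max())
    for l in range(1, lattice.L):
        lo = max(0, total_charge - minc_right[l])
        hi = min(maxc[l], total_charge)
        vals = np.arange(lo, hi + 1)
        reps = rng.integers(1, m + 1, size=vals.size)
        q = np.repeat(vals, reps)[:m]
        if q.size == 0:
            q = vals[:1]
        bond_q.append(np.sort(q))
    bond_q.append(np.array([total_charge]))
    tensors = []
    for l in range(lattice.L):
        Dl, Dr = bond_q[l].size, bond_q[l + 1].size
        d = lattice.dims[l]
        t = rng.standard_normal((Dl, d, Dr)) + 1j * rng.standard_normal((Dl, d, Dr))
        mask = (
            bond_q[l][:, None, None]
            + lattice.phys_charges(l)[None, :, None]
            == bond_q[l + 1][None, None, :]
        )
        tensors.append(t * mask)
    psi = VibronicMPS(lattice, tensors, bond_q)
    psi.canonicalize(0)
    return psi.normalize()


# ---------------------------------------------------------------------------
# contractions
# ---------------------------------------------------------------------------


def overlap(psi: VibronicMPS, phi: VibronicMPS) -> complex:
    """<psi|phi> by transfer-matrix contraction."""
    if psi.lattice != phi.lattice:
        raise ValueError("lattice mismatch")
    E = np.ones((1, 1), dtype=complex)
    for A, B in zip(psi.tensors, phi.tensors):
        # E[a, b] -> sum_s (A*[a, s, a'] E[a, b] B[b, s, b'])
        T = np.tensordot(E, B, axes=(1, 0))  # (a, s, b')
        E = np.tensordot(A.conj(), T, axes=((0, 1), (0, 1)))
    return complex(E[0, 0])


def norm(psi: VibronicMPS) -> float:
    return psi.norm()


def expectation_mpo(psi: VibronicMPS, mpo) -> complex:
    """<psi|O|psi> for an MPO on the same lattice (not normalized)."""
    from .sweeps import contract_left

    E = np.ones((1, 1, 1), dtype=complex)
    for A, W in zip(psi.tensors, mpo.tensors):
        E = contract_left(E, A, W)
    return complex(E[0, 0, 0])


def local_expectation(psi: VibronicMPS, site: int, op: np.ndarray) -> complex:
    """<psi|op_site|psi> with identities elsewhere (not normalized)."""
    E = np.ones((1, 1), dtype=complex)
    for l, A in enumerate(psi.tensors):
        B = np.tensordot(op, A, axes=(1, 1)).transpose(1, 0, 2) if l == site else A
        T = np.tensordot(E, B, axes=(1, 0))
        E = np.tensordot(A.conj(), T, axes=((0, 1), (0, 1)))
    return complex(E[0, 0])


def truncate(psi: VibronicMPS, m_max=None, cutoff: float = 1e-12):
    """Truncate every bond to ``m_max`` (within charge sectors) and drop
    relative singular weight below ``cutoff``; renormalize.

    Returns ``(psi_trunc, discarded)`` with ``discarded`` the summed squared
    singular values removed (so fidelity = 1 - discarded for a normalized
    input).
    """
    out = psi.copy()
    out.canonicalize(out.lattice.L - 1)
    discarded = 0.0
    for l in range(out.lattice.L - 1, 0, -1):
        discarded += out._shift_left(l, m_max=m_max, cutoff=cutoff)
    out.center = 0
    out.normalize()
    return out, discarded
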