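"""Environment contractions and effective operators for sweep algorithms.

Environments carry three legs (bra bond, MPO bond, ket bond).  The
effective one- and two-site operators defined here are shared by the
ground-state DMRG and the two-site TDVP integrator.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "contract_left",
    "contract_right",
    "init_right_envs",
    "two_site_matvec",
    "one_site_matvec",
]


def contract_left(E, A, W, B=None):
    """Grow a left environment E[a, w, b] past one site.

    A is the bra tensor, B the ket tensor (defaults to A), W the MPO tensor
    (w, s, t, w') with s the bra (output) and t the ket (input) index.
    """
    if B is None:
        B = A
    T = np.tensordot(E, B, axes=(2, 0))  # (a, w, t, b')
    T = np.tensordot(W, T, axes=((0, 2), (1, 2)))  # (s, w', a, b')
    return np.tensordot(A.conj(), T, axes=((0, 1), (2, 0)))  # (a', w', b')


def contract_right(E, A, W, B=None):
    """Grow a right environment E[a, w, b] past one site (moving left)."""
    if B is None:
        B = A
    T = np.tensordot(B, E, axes=(2, 2))  # (b', t, a, w)
    T = np.tensordot(W, T, axes=((2, 3), (1, 3)))  # (w_l, s, b', a)
    return np.tensordot(A.conj(), T, axes=((1, 2), (1, 3)))  # (a_l, w_l, b'_l)


def init_right_envs(psi, mpo):
    """Right environments R[l] closing sites l..L-1, for a center-0 state.

    R has length L + 1; R[L] is the trivial boundary.
    """
    L = psi.lattice.L
    R = [None] * (L + 1)
    R[L] = np.ones((1, 1, 1), dtype=complex)
    for l in range(L - 1, 0, -1):
        R[l] = contract_right(R[l + 1], psi.tensors[l], mpo.tensors[l])
    return R


def two_site_matvec(Lenv, W1, W2, Renv):
    """Return a matvec applying the two-site effective Hamiltonian.

    Acts on theta of shape (Dl, d1, d2, Dr).
    """

    def mv(theta):
        T = np.tensordot(Lenv, theta, axes=(2, 0))  # (a, w, t1, t2, r)
        T = np.tensordot(W1, T, axes=((0, 2), (1, 2)))  # (s1, w', a, t2, r)
        T = np.tensordot(W2, T, axes=((0, 2), (1, 3)))  # (s2, w'', s1, a, r)
        T = np.tensordot(T, Renv, axes=((1, 4), (1, 2)))  # (s2, s1, a, a_r)
        return T.transpose(2, 1, 0, 3)

    return mv


def one_site_matvec(Lenv, W, Renv):
    """Matvec of the one-site effective Hamiltonian on A (Dl, d, Dr)."""

    def mv(A):
        T = np.tensordot(Lenv, A, axes=(2, 0))  # (a, w, t, r)
        T = np.tensordot(W, T, axes=((0, 2), (1, 2)))  # (s, w', a, r)
        T = np.tensordot(T, Renv, axes=((1, 3), (1, 2)))  # (s, a, a_r)
        return T.transpose(1, 0, 2)

    return mv
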