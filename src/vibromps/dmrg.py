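"""Two-site ground-state DMRG for the vibronic lattice.

Variational energy minimization: each microiteration replaces a two-site
block by the lowest eigenvector of the effective Hamiltonian (Lanczos with
the current block as the starting vector; dense diagonalization for tiny
blocks), sweeping forward and backward until the inter-sweep energy change
drops below tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .krylov import eigmin_krylov, _check_hermitian, KrylovError
from .mps import VibronicMPS
from .mpo import MPO
from .sweeps import (
    contract_left,
    contract_right,
    init_right_envs,
    two_site_matvec,
)
from .tdvp import _split_two_site

__all__ = ["SweepReport", "optimize"]

_DENSE_DIM = 500


@dataclass
class SweepReport:
    """Energies and truncation diagnostics per sweep."""

    energies: list = field(default_factory=list)  # one per sweep (last microit)
    site_energies: list = field(default_factory=list)  # list of lists
    max_bond: list = field(default_factory=list)
    max_discarded: list = field(default_factory=list)
    converged: bool = False

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sweep": np.arange(1, len(self.energies) + 1),
                "energy": self.energies,
                "max_bond": self.max_bond,
                "max_discarded": self.max_discarded,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _sector_mask(psi, l):
    """Boolean mask of two-site entries allowed by the bond/physical charges."""
    lat = psi.lattice
    ql = psi.bond_q[l]
    qr = psi.bond_q[l + 2]
    c1 = lat.phys_charges(l)
    c2 = lat.phys_charges(l + 1)
    return (
        ql[:, None, None, None]
        + c1[None, :, None, None]
        + c2[None, None, :, None]
        == qr[None, None, None, :]
    )


def _solve_local(mv, theta, mask, tol):
    """Lowest eigenpair of the local effective Hamiltonian, restricted to
    the U(1) charge sector of the current block (the complementary sectors
    of the product space are not part of the variational state)."""
    sel = np.flatnonzero(mask.ravel())
    flat_mv = lambda x: mv(x.reshape(theta.shape)).ravel()

    def red_mv(y):
        x = np.zeros(theta.size, dtype=complex)
        x[sel] = y
        return flat_mv(x)[sel]

    rng = np.random.default_rng(0)
    v0 = theta.ravel()[sel]
    _check_hermitian(red_mv, v0, rng)
    if sel.size <= _DENSE_DIM:
        Hd = np.empty((sel.size, sel.size), dtype=complex)
        eye = np.eye(sel.size)
        for c in range(sel.size):
            Hd[:, c] = red_mv(eye[:, c].astype(complex))
        evals, evecs = np.linalg.eigh(Hd)
        e, y = float(evals[0]), evecs[:, 0]
    else:
        e, y = eigmin_krylov(red_mv, v0, tol=tol)
    out = np.zeros(theta.size, dtype=complex)
    out[sel] = y
    return e, out.reshape(theta.shape)


def optimize(
    psi0: VibronicMPS,
    mpo: MPO,
    m_max: int | None = None,
    n_sweeps: int = 20,
    tol: float = 1e-9,
    cutoff: float = 1e-12,
    eig_tol: float = 1e-9,
):
    """Variational ground state within the bond-dimension-``m_max`` manifold.

    Returns ``(psi, report)``.  Converged when the energy change between
    consecutive sweeps is below ``tol``.
    """
    psi = psi0.copy()
    psi.canonicalize(0)
    psi.normalize()
    L = psi.lattice.L
    if L < 2:
        raise ValueError("ground-state sweeps need at least two sites")
    W = mpo.tensors
    Lenv = [None] * (L + 1)
    Lenv[0] = np.ones((1, 1, 1), dtype=complex)
    Renv = init_right_envs(psi, mpo)
    report = SweepReport()
    prev_E = None
    for _ in range(n_sweeps):
        site_E = []
        disc_max = 0.0
        for l in range(L - 1):
            theta = np.tensordot(psi.tensors[l], psi.tensors[l + 1], axes=(2, 0))
            mv = two_site_matvec(Lenv[l], W[l], W[l + 1], Renv[l + 2])
            e, theta = _solve_local(mv, theta, _sector_mask(psi, l), eig_tol)
            site_E.append(e)
            d, _, _ = _split_two_site(psi, l, theta, m_max, cutoff, "right")
            psi.tensors[psi.center] /= np.linalg.norm(psi.tensors[psi.center])
            disc_max = max(disc_max, d)
            Lenv[l + 1] = contract_left(Lenv[l], psi.tensors[l], W[l])
        for l in range(L - 2, -1, -1):
            theta = np.tensordot(psi.tensors[l], psi.tensors[l + 1], axes=(2, 0))
            mv = two_site_matvec(Lenv[l], W[l], W[l + 1], Renv[l + 2])
            e, theta = _solve_local(mv, theta, _sector_mask(psi, l), eig_tol)
            site_E.append(e)
            d, _, _ = _split_two_site(psi, l, theta, m_max, cutoff, "left")
            psi.tensors[psi.center] /= np.linalg.norm(psi.tensors[psi.center])
            disc_max = max(disc_max, d)
            Renv[l + 1] = contract_right(Renv[l + 2], psi.tensors[l + 1], W[l + 1])
        report.site_energies.append(site_E)
        report.energies.append(site_E[-1])
        report.max_bond.append(max(psi.bond_dims()))
        report.max_discarded.append(disc_max)
        if prev_E is not None and abs(prev_E - site_E[-1]) < tol:
            report.converged = True
            break
        prev_E = site_E[-1]
    psi.center = 0
    return psi, report
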