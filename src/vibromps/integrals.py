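"""Numerical one- and two-body matrix elements in modal bases.

For a real-valued modal basis the matrix elements of the n-mode Hamiltonian
are

    H[i]_{k,h}      = int phi_k (T + v1[i]) phi_h dQ_i
    H[i,j]_{kk',hh'} = int int phi_k phi_k' v2[i,j] phi_h phi_h' dQ_i dQ_j

and analogously for coupling surfaces V (which carry no kinetic term).
Quadrature uses each basis's stored grid; two-body integrals use the tensor
product of the 1D rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import ModalBasis
from .nmode import NModeFunction, VibronicModel

__all__ = [
    "IntegralTable",
    "one_body_integrals",
    "two_body_integrals",
    "compute_tables",
    "QuadratureError",
]


class QuadratureError(RuntimeError):
    """Raised when doubling the quadrature resolution moves an entry by more
    than the requested tolerance."""


def _potential_block(basis: ModalBasis, v1) -> np.ndarray:
    vgrid = np.asarray(v1(basis.points), dtype=float)
    blk = (basis.values * (basis.weights * vgrid)) @ basis.values.T
    return 0.5 * (blk + blk.T)


def one_body_integrals(
    basis: ModalBasis,
    v1=None,
    include_kinetic: bool = True,
    check_convergence: bool = False,
    conv_tol: float = 1e-8,
) -> np.ndarray:
    """One-body block ``<k| [T +] v1 |h>`` on the basis's quadrature grid.

    ``include_kinetic=False`` gives the potential-only block used for
    coupling surfaces.  With ``check_convergence`` the potential part is
    recomputed on a doubled grid and a :class:`QuadratureError` is raised if
    any entry moves by more than ``conv_tol``.
    """
    blk = np.zeros((basis.N, basis.N))
    if v1 is not None:
        blk += _potential_block(basis, v1)
        if check_convergence:
            ref = _potential_block(basis.refined(), v1)
            dev = np.max(np.abs(ref - blk))
            if dev > conv_tol:
                raise QuadratureError(
                    f"one-body quadrature unconverged (moved {dev:.2e} on grid "
                    f"doubling, tol {conv_tol:.0e})"
                )
    if include_kinetic:
        blk = blk + basis.kin
    return blk


def _pair_weights(basis: ModalBasis) -> np.ndarray:
    """X[k, h, g] = w_g phi_k(g) phi_h(g), flattened to (N*N, G)."""
    X = basis.values[:, None, :] * basis.values[None, :, :] * basis.weights
    return X.reshape(basis.N**2, -1)


def _two_body_block(bi: ModalBasis, bj: ModalBasis, v2) -> np.ndarray:
    Vg = np.asarray(
        v2(bi.points[:, None], bj.points[None, :]), dtype=float
    )
    out = _pair_weights(bi) @ Vg @ _pair_weights(bj).T
    out = out.reshape(bi.N, bi.N, bj.N, bj.N).transpose(0, 2, 1, 3)
    # symmetrize within each mode (real basis, Hermitian operator)
    out = 0.5 * (out + out.transpose(2, 3, 0, 1))
    return np.ascontiguousarray(out)


def two_body_integrals(
    bi: ModalBasis,
    bj: ModalBasis,
    v2,
    check_convergence: bool = False,
    conv_tol: float = 1e-8,
) -> np.ndarray:
    """Two-body block, shape (N_i, N_j, N_i, N_j) indexed [k_i, k_j, h_i, h_j].

    Tensor-product quadrature of the two 1D rules.
    """
    out = _two_body_block(bi, bj, v2)
    if check_convergence:
        ref = _two_body_block(bi.refined(), bj.refined(), v2)
        dev = np.max(np.abs(ref - out))
        if dev > conv_tol:
            raise QuadratureError(
                f"two-body quadrature unconverged (moved {dev:.2e} on grid "
                f"doubling, tol {conv_tol:.0e})"
            )
    return out


@dataclass
class IntegralTable:
    """All integral blocks of a vibronic model in given modal bases.

    Keys: ``onebody[(surface, i)]`` and ``twobody[(surface, (i, j))]`` where
    ``surface`` is ``("d", alpha)`` for a diagonal PES or ``("o", (a, b))``
    (a < b) for a coupling.  Diagonal one-body blocks include the kinetic
    matrix; coupling blocks are potential-only.
    """

    N_el: int
    M: int
    Ns: tuple
    onebody: dict = field(default_factory=dict)
    twobody: dict = field(default_factory=dict)
    constants: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def hermiticity_deviation(self) -> float:
        dev = 0.0
        for blk in self.onebody.values():
            dev = max(dev, float(np.max(np.abs(blk - blk.T))))
        for blk in self.twobody.values():
            dev = max(dev, float(np.max(np.abs(blk - blk.transpose(2, 3, 0, 1)))))
        return dev


def compute_tables(
    model: VibronicModel,
    bases: list[ModalBasis],
    check_convergence: bool = False,
) -> IntegralTable:
    """Evaluate every block the model declares, in the given bases.

    Every mode of every diagonal surface gets a one-body block (the kinetic
    term is always present even when the surface stores no one-body
    potential term for that mode); couplings only get blocks for the terms
    they actually carry.
    """
    if len(bases) != model.M:
        raise ValueError("need one modal basis per mode")
    tab = IntegralTable(
        N_el=model.N_el,
        M=model.M,
        Ns=tuple(b.N for b in bases),
        meta={"grids": [len(b.points) for b in bases]},
    )
    for a in range(model.N_el):
        surf: NModeFunction = model.diag[a]
        tab.constants[("d", a)] = float(surf.F0)
        for i in range(model.M):
            tab.onebody[(("d", a), i)] = one_body_integrals(
                bases[i],
                surf.F1.get(i),
                include_kinetic=True,
                check_convergence=check_convergence and i in surf.F1,
            )
        for (i, j), v2 in surf.F2.items():
            tab.twobody[(("d", a), (i, j))] = two_body_integrals(
                bases[i], bases[j], v2, check_convergence=check_convergence
            )
    for (a, b), surf in model.offdiag.items():
        key = ("o", (a, b))
        tab.constants[key] = float(surf.F0)
        for i, v1 in surf.F1.items():
            tab.onebody[(key, i)] = one_body_integrals(
                bases[i], v1, include_kinetic=False,
                check_convergence=check_convergence,
            )
        for (i, j), v2 in surf.F2.items():
            tab.twobody[(key, (i, j))] = two_body_integrals(
                bases[i], bases[j], v2, check_convergence=check_convergence
            )
    return tab
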