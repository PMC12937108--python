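"""Per-mode single-particle (modal) basis functions on quadrature grids.

Two constructions are provided:

- :func:`harmonic_basis`: analytic harmonic-oscillator eigenfunctions
  tabulated on a scaled Gauss-Hermite grid (the analytic reference basis).
- :func:`relaxed_basis`: numerical eigenfunctions of a 1D Hamiltonian
  ``T + v1`` obtained with a sine-DVR discretization on a uniform grid.
  With ``v1`` the one-body potential of the electronic ground state this is
  the ground-state vibrational eigenbasis in which the Condon initial
  wavepacket is a single occupation-zero product state.

A :class:`ModalBasis` stores the grid (nodes and plain ``dQ`` weights), the
tabulated functions, the eigenvalues when the basis is an eigenbasis, and
the kinetic-energy matrix in the basis, so downstream integral evaluation
never needs to differentiate tabulated functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ModalBasis", "harmonic_basis", "relaxed_basis", "BasisError"]


class BasisError(ValueError):
    """Raised for unbuildable or under-resolved bases."""


@dataclass
class ModalBasis:
    """Orthonormal 1D basis for one vibrational mode.

    ``values[k, g]`` tabulates function k at grid node g; the quadrature
    contract is ``sum_g w[g] values[k, g] values[h, g] = delta_kh``.
    ``kin[k, h]`` is the matrix of ``-c d^2/dQ^2`` (``c`` the mode's kinetic
    coefficient, 1/2 by default) in the basis.
    """

    mode: int
    N: int
    points: np.ndarray
    weights: np.ndarray
    values: np.ndarray
    kin: np.ndarray
    eigvals: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def gram(self) -> np.ndarray:
        return (self.values * self.weights) @ self.values.T

    def check_orthonormal(self, tol: float = 1e-8) -> None:
        dev = np.max(np.abs(self.gram() - np.eye(self.N)))
        if dev > tol:
            raise BasisError(
                f"basis for mode {self.mode} not orthonormal on its grid "
                f"(max deviation {dev:.2e} > {tol:.0e}); widen or refine the grid"
            )

    def refined(self) -> "ModalBasis":
        """Same basis tabulated on a grid with twice the resolution.

        Used by quadrature-convergence checks.  Analytic bases are
        regenerated; numerical bases are spline-interpolated onto the finer
        grid (adequate for a convergence *probe*, not for production
        integrals).
        """
        kind = self.meta.get("kind")
        if kind == "harmonic":
            return harmonic_basis(
                self.meta["omega"],
                self.N,
                n_points=2 * len(self.points),
                mode=self.mode,
                kinetic_coeff=self.meta.get("kinetic_coeff", 0.5),
            )
        from scipy.interpolate import CubicSpline

        q = self.points
        qf = np.linspace(q[0], q[-1], 2 * len(q) - 1)
        vals = np.array([CubicSpline(q, row)(qf) for row in self.values])
        dq = qf[1] - qf[0]
        return ModalBasis(
            mode=self.mode,
            N=self.N,
            points=qf,
            weights=np.full(qf.size, dq),
            values=vals,
            kin=self.kin.copy(),
            eigvals=None if self.eigvals is None else self.eigvals.copy(),
            meta=dict(self.meta, refined=True),
        )


def _hermite_functions(N: int, x: np.ndarray) -> np.ndarray:
    """Normalized Hermite functions h_k(x), k < N, by stable recurrence.

    h_k(x) = pi^{-1/4} (2^k k!)^{-1/2} H_k(x) exp(-x^2/2).
    """
    out = np.empty((N, x.size))
    out[0] = np.pi**-0.25 * np.exp(-0.5 * x**2)
    if N > 1:
        out[1] = np.sqrt(2.0) * x * out[0]
    for k in range(1, N - 1):
        out[k + 1] = np.sqrt(2.0 / (k + 1)) * x * out[k] - np.sqrt(
            k / (k + 1)
        ) * out[k - 1]
    return out


def harmonic_basis(
    omega: float,
    N: int,
    n_points: int | None = None,
    mode: int = 0,
    kinetic_coeff: float = 0.5,
) -> ModalBasis:
    """First N harmonic-oscillator eigenfunctions of frequency ``omega``.

    The grid is the Gauss-Hermite rule of order ``n_points`` (default
    ``max(2 N + 16, 48)``) scaled by ``1/sqrt(omega)``, with the Gaussian
    weight factored back in so the stored weights implement a plain
    ``int dQ`` quadrature.  Eigenvalues are ``omega (k + 1/2)``; the kinetic
    matrix is the analytic pentadiagonal ladder-operator form.
    """
    if omega <= 0:
        raise BasisError("omega must be positive")
    if N < 1:
        raise BasisError("need at least one basis function")
    K = n_points or max(2 * N + 16, 48)
    x, wgh = np.polynomial.hermite.hermgauss(K)
    Q = x / np.sqrt(omega)
    # plain-integration weights: w_g = wgh_g * exp(x_g^2) / sqrt(omega)
    w = wgh * np.exp(x**2) / np.sqrt(omega)
    vals = np.sqrt(np.sqrt(omega)) * _hermite_functions(N, x)
    # T = 2c * [ (2n+1)/4 - (b^dag b^dag + b b)/4 ] * omega   (c = 1/2 default)
    k = np.arange(N)
    T = np.diag((2 * k + 1) * omega / 4.0).astype(float)
    if N > 2:
        off = -omega / 4.0 * np.sqrt((k[:-2] + 1) * (k[:-2] + 2))
        T += np.diag(off, 2) + np.diag(off, -2)
    T *= 2.0 * kinetic_coeff
    basis = ModalBasis(
        mode=mode,
        N=N,
        points=Q,
        weights=w,
        values=vals,
        kin=T,
        eigvals=omega * (k + 0.5),
        meta={"kind": "harmonic", "omega": float(omega), "kinetic_coeff": kinetic_coeff},
    )
    basis.check_orthonormal(1e-8)
    return basis


def _sine_dvr_kinetic(n: int, dq: float, coeff: float) -> np.ndarray:
    """Exact particle-in-a-box (sine) DVR matrix of ``-coeff d^2/dQ^2``.

    Grid points are the n interior nodes of a box of length (n + 1) dq.
    """
    j = np.arange(1, n + 1)
    dif = j[:, None] - j[None, :]
    summ = j[:, None] + j[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (
            (-1.0) ** dif
            * (np.pi / ((n + 1) * dq)) ** 2
            / 2.0
            * (
                1.0 / np.sin(np.pi * dif / (2 * (n + 1))) ** 2
                - 1.0 / np.sin(np.pi * summ / (2 * (n + 1))) ** 2
            )
        )
    diag = (np.pi / ((n + 1) * dq)) ** 2 / 2.0 * (
        (2.0 * (n + 1) ** 2 + 1) / 3.0 - 1.0 / np.sin(np.pi * j / (n + 1)) ** 2
    )
    T[np.arange(n), np.arange(n)] = diag
    # T above is the matrix of -d^2/dQ^2; rescale to -coeff d^2/dQ^2
    return coeff * T


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: positive at the leftmost antinode.

    The leftmost antinode is the first grid point where |f| reaches at least
    half of its global maximum.
    """
    out = vecs.copy()
    for r in range(out.shape[0]):
        a = np.abs(out[r])
        idx = int(np.argmax(a >= 0.5 * a.max()))
        if out[r, idx] < 0:
            out[r] = -out[r]
    return out


def relaxed_basis(
    v1,
    N: int,
    qmin: float,
    qmax: float,
    n_points: int = 401,
    mode: int = 0,
    kinetic_coeff: float = 0.5,
) -> ModalBasis:
    """Lowest N eigenfunctions of T + v1 on a uniform sine-DVR grid.

    ``v1`` is any 1D callable (a one-body n-mode term, a spline, a lambda).
    Eigenvalues come out ascending; each eigenfunction is normalized under
    the uniform-weight quadrature and sign-fixed to be positive at its
    leftmost antinode so downstream integrals are reproducible.
    """
    if N < 1:
        raise BasisError("need at least one basis function")
    if n_points < max(2 * N, 16):
        raise BasisError("grid too coarse for the requested basis size")
    # interior nodes of the DVR box [qmin, qmax]
    dq = (qmax - qmin) / (n_points + 1)
    q = qmin + dq * np.arange(1, n_points + 1)
    H = _sine_dvr_kinetic(n_points, dq, kinetic_coeff) + np.diag(
        np.asarray(v1(q), dtype=float)
    )
    evals, evecs = np.linalg.eigh(H)
    if N > n_points:
        raise BasisError("requested more states than grid points")
    vals = _fix_signs(evecs[:, :N].T / np.sqrt(dq))
    kin = dq * (vals @ _sine_dvr_kinetic(n_points, dq, kinetic_coeff) @ vals.T)
    # symmetrize: T is Hermitian, the projection should be too
    kin = 0.5 * (kin + kin.T)
    basis = ModalBasis(
        mode=mode,
        N=N,
        points=q,
        weights=np.full(n_points, dq),
        values=vals,
        kin=kin,
        eigvals=evals[:N].copy(),
        meta={
            "kind": "relaxed",
            "qmin": float(qmin),
            "qmax": float(qmax),
            "kinetic_coeff": kinetic_coeff,
        },
    )
    basis.check_orthonormal(1e-8)
    return basis


def default_bounds(omega: float, n_turning: float = 7.0) -> tuple[float, float]:
    """Symmetric grid bounds at ``n_turning`` classical turning points of the
    reference frequency (ground-state turning point ``1/sqrt(omega)``)."""
    L = n_turning / np.sqrt(omega)
    return (-L, L)
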