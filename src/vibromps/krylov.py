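"""Lanczos solvers for the local (effective) problems of sweep algorithms.

Both routines operate on an arbitrary Hermitian matvec over flattened
tensors: a short-iterate Lanczos exponential ``exp(z H) v`` for the TDVP
local steps (z on the imaginary axis for real time, on the negative real
axis for imaginary time) and a restarted Lanczos smallest-eigenpair solver
for the ground-state microiterations.  Full reorthogonalization is used
throughout - local dimensions are desk-scale.
"""

from __future__ import annotations

import numpy as np

__all__ = ["expm_krylov", "eigmin_krylov", "KrylovError"]


class KrylovError(RuntimeError):
    """Local Krylov solve failed to converge; carries diagnostics."""


def _check_hermitian(matvec, v, rng, tol=1e-8):
    """Spot-check Hermiticity of the matvec with one random pair."""
    x = rng.standard_normal(v.shape) + 1j * rng.standard_normal(v.shape)
    y = rng.standard_normal(v.shape) + 1j * rng.standard_normal(v.shape)
    lhs = np.vdot(x, matvec(y))
    rhs = np.vdot(matvec(x), y)
    scale = max(abs(lhs), abs(rhs), 1e-30)
    if abs(lhs - rhs) / scale > tol:
        raise KrylovError(
            f"effective operator not Hermitian: <x|Hy> = {lhs:.3e}, "
            f"<Hx|y> = {rhs:.3e}"
        )


def expm_krylov(matvec, v, z, tol=1e-10, max_krylov=30, _depth=0):
    """Evaluate ``exp(z H) v`` for Hermitian H given as a matvec.

    Builds a Lanczos basis until the result changes by less than ``tol``
    (relative) between successive Krylov dimensions.  If ``max_krylov``
    vectors do not suffice (large ||H|| dt), the step is split into two
    half-steps recursively; a :class:`KrylovError` is raised only when even
    deep substepping fails.
    """
    v = np.asarray(v, dtype=complex).ravel()
    beta0 = np.linalg.norm(v)
    if beta0 == 0:
        return v.copy()
    V = [v / beta0]
    alphas, betas = [], []
    prev = None
    for j in range(max_krylov):
        w = matvec(V[j])
        a = np.vdot(V[j], w).real
        alphas.append(a)
        w = w - a * V[j]
        if j > 0:
            w = w - betas[-1] * V[j - 1]
        # full reorthogonalization
        for u in V:
            w = w - np.vdot(u, w) * u
        b = np.linalg.norm(w)
        # small-matrix exponential in the current Krylov space
        T = np.diag(alphas).astype(complex)
        if len(betas):
            T += np.diag(betas, 1) + np.diag(betas, -1)
        evals, evecs = np.linalg.eigh(T)
        coef = evecs @ (np.exp(z * evals) * evecs[0].conj())
        est = beta0 * np.column_stack(V) @ coef
        if prev is not None:
            if np.linalg.norm(est - prev) <= tol * max(np.linalg.norm(est), 1e-30):
                return est
        if b <= 1e-14 * max(abs(a), 1.0):
            # invariant subspace: result exact
            return est
        prev = est
        betas.append(b)
        V.append(w / b)
    if _depth < 12:
        half = expm_krylov(matvec, v, z / 2, tol, max_krylov, _depth + 1)
        return expm_krylov(matvec, half, z / 2, tol, max_krylov, _depth + 1)
    raise KrylovError(
        f"Krylov exponential did not converge within {max_krylov} vectors "
        "even after substepping"
    )


def eigmin_krylov(matvec, v0, tol=1e-9, max_krylov=40, max_restarts=50):
    """Smallest eigenpair of a Hermitian matvec by restarted Lanczos.

    Returns ``(eigenvalue, eigenvector)``; converged when the residual
    ``||H x - e x||`` drops below ``tol * max(1, |e|)``.
    """
    x = np.asarray(v0, dtype=complex).ravel()
    nrm = np.linalg.norm(x)
    if nrm == 0:
        raise KrylovError("zero start vector")
    x = x / nrm
    theta = None
    for _ in range(max_restarts):
        V = [x]
        alphas, betas = [], []
        for j in range(max_krylov):
            w = matvec(V[j])
            a = np.vdot(V[j], w).real
            alphas.append(a)
            w = w - a * V[j]
            if j > 0:
                w = w - betas[-1] * V[j - 1]
            for u in V:
                w = w - np.vdot(u, w) * u
            b = np.linalg.norm(w)
            if b <= 1e-14 * max(abs(a), 1.0):
                break
            betas.append(b)
            V.append(w / b)
        T = np.diag(alphas)
        if betas:
            T = T + np.diag(betas[: len(alphas) - 1], 1) + np.diag(
                betas[: len(alphas) - 1], -1
            )
        evals, evecs = np.linalg.eigh(T)
        theta = evals[0]
        x = np.column_stack(V) @ evecs[:, 0]
        x = x / np.linalg.norm(x)
        res = np.linalg.norm(matvec(x) - theta * x)
        if res <= tol * max(1.0, abs(theta)):
            return float(theta), x
    raise KrylovError(
        f"Lanczos eigensolver stalled (residual {res:.3e} > {tol:.0e})"
    )
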