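"""Quadrature matrix elements vs ladder-operator closed forms."""

import numpy as np
import pytest

from vibromps.basis import harmonic_basis
from vibromps.integrals import (
    QuadratureError,
    compute_tables,
    one_body_integrals,
    two_body_integrals,
)
from vibromps.nmode import Poly1, Poly2, random_coupled_model
from vibromps.pipeline import ground_state_bases


def q_matrix(omega, N):
    """<k|Q|h> for harmonic-oscillator eigenfunctions of frequency omega."""
    k = np.arange(N - 1)
    off = np.sqrt((k + 1) / (2 * omega))
    return np.diag(off, 1) + np.diag(off, -1)


def q2_matrix(omega, N):
    q = q_matrix(omega, N + 2)
    return (q @ q)[:N, :N]


class TestOneBody:
    def test_ho_eigenbasis_is_diagonal(self):
        b = harmonic_basis(1.0, 6)
        blk = one_body_integrals(b, Poly1([0, 0, 0.5]), include_kinetic=True)
        assert np.allclose(np.diag(blk), np.arange(6) + 0.5, atol=1e-9)
        assert np.max(np.abs(blk - np.diag(np.diag(blk)))) < 1e-9

    @pytest.mark.parametrize("omega,N", [(1.0, 8), (0.02, 16)])
    def test_position_operator_ladder_form(self, omega, N):
        b = harmonic_basis(omega, N)
        blk = one_body_integrals(b, Poly1([0, 1]), include_kinetic=False)
        assert np.max(np.abs(blk - q_matrix(omega, N))) < 1e-9

    def test_null_operator(self):
        b = harmonic_basis(1.0, 4)
        blk = one_body_integrals(b, None, include_kinetic=False)
        assert np.all(blk == 0)

    def test_symmetric(self):
        b = harmonic_basis(0.5, 7)
        blk = one_body_integrals(b, Poly1([0, 0.3, 0.2, 0.1]), include_kinetic=True)
        assert np.max(np.abs(blk - blk.T)) < 1e-10

    def test_convergence_check_passes_smooth(self):
        b = harmonic_basis(1.0, 5)
        one_body_integrals(b, Poly1([0, 0, 0.5]), check_convergence=True)

    def test_convergence_check_raises_on_rough_potential(self):
        b = harmonic_basis(1.0, 8, n_points=24)
        rough = lambda q: np.cos(40.0 * q)  # far beyond the rule's resolution
        with pytest.raises(QuadratureError):
            one_body_integrals(
                b, rough, include_kinetic=False, check_convergence=True,
                conv_tol=1e-12,
            )


class TestTwoBody:
    def test_bilinear_separable_product(self):
        bi, bj = harmonic_basis(1.0, 5), harmonic_basis(2.0, 4)
        blk = two_body_integrals(bi, bj, Poly2([[0, 0], [0, 1]]))
        qi, qj = q_matrix(1.0, 5), q_matrix(2.0, 4)
        ref = np.einsum("kh,lm->klhm", qi, qj)
        assert np.max(np.abs(blk - ref)) < 1e-9

    def test_zero_tensor(self):
        bi = harmonic_basis(1.0, 3)
        blk = two_body_integrals(bi, bi, Poly2([[0.0]]))
        assert np.all(blk == 0)

    def test_q2q2_separable_closed_form(self):
        bi, bj = harmonic_basis(0.8, 6), harmonic_basis(1.3, 6)
        blk = two_body_integrals(bi, bj, Poly2([[0, 0, 0], [0, 0, 0], [0, 0, 1]]))
        ref = np.einsum("kh,lm->klhm", q2_matrix(0.8, 6), q2_matrix(1.3, 6))
        assert np.max(np.abs(blk - ref)) < 1e-9

    def test_hermiticity(self):
        bi, bj = harmonic_basis(1.0, 4), harmonic_basis(0.5, 5)
        blk = two_body_integrals(bi, bj, lambda a, b: a * b + 0.3 * a**2 * b)
        assert np.max(np.abs(blk - blk.transpose(2, 3, 0, 1))) < 1e-10

    def test_quadrature_doubling_stable(self):
        bi, bj = harmonic_basis(1.0, 4), harmonic_basis(0.5, 4)
        two_body_integrals(
            bi, bj, Poly2([[0, 0], [0, 0.2]]), check_convergence=True
        )


class TestTables:
    def test_every_declared_block_present(self):
        model = random_coupled_model(2, seed=4)
        bases = ground_state_bases(model, 5, n_points=201)
        tab = compute_tables(model, bases)
        # kinetic-bearing one-body block for every (state, mode)
        for a in range(2):
            for i in range(2):
                assert (("d", a), i) in tab.onebody
        assert (("o", (0, 1)), 0) in tab.onebody  # linear coupling term
        assert tab.hermiticity_deviation() < 1e-10

    def test_ground_basis_diagonalizes_ground_state(self):
        """In the relaxed ground-state basis the state-0 one-body blocks are
        diagonal with the 1D eigenvalues."""
        model = random_coupled_model(2, seed=4)
        bases = ground_state_bases(model, 5, n_points=401)
        tab = compute_tables(model, bases)
        for i in range(2):
            blk = tab.onebody[(("d", 0), i)]
            assert np.max(np.abs(blk - np.diag(bases[i].eigvals))) < 1e-7
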