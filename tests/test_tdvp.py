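"""Two-site TDVP: oracle equivalence, conservation laws, local order."""

import numpy as np
import pytest

from vibromps.basis import harmonic_basis
from vibromps.mpo import MPO, compile_mpo, identity_mpo
from vibromps.mps import Lattice, product_state
from vibromps.nmode import make_displaced_ho_model, random_coupled_model
from vibromps.oracle import dense_propagate
from vibromps.sqham import assemble_hamiltonian
from vibromps.tdvp import propagate, step_error_probe
from vibromps.units import fs_to_au


def zero_mpo(lat):
    mpo = identity_mpo(lat)
    mpo.tensors[0] = 0.0 * mpo.tensors[0]
    return mpo


class TestLimits:
    def test_zero_hamiltonian_leaves_state_unchanged(self):
        lat = Lattice(2, (4, 4))
        psi0 = product_state(lat, 1, [1, 2])
        rec, psi = propagate(psi0, zero_mpo(lat), 0.5, 20)
        assert np.max(np.abs(rec.autocorr - 1.0)) < 1e-12
        assert np.max(np.abs(psi.to_dense() - psi0.to_dense())) < 1e-12

    def test_eigenstate_acquires_pure_phase(self):
        omega = 0.01
        model = make_displaced_ho_model(omega, 0.0, dE=0.002)
        ham = assemble_hamiltonian(model, [harmonic_basis(omega, 6)])
        mpo = compile_mpo(ham)
        lat = Lattice(1, (6,))
        k = 2
        psi0 = product_state(lat, 0, [k])
        rec, _ = propagate(psi0, mpo, 0.5, 100)
        E = 0.002 + omega * (k + 0.5)
        expect = np.exp(-1j * E * fs_to_au(rec.times_fs))
        assert np.max(np.abs(rec.autocorr - expect)) < 1e-8


class TestOracleEquivalence:
    def test_full_m_autocorrelation_matches_dense(self, coupled_2x2):
        sys, mpo, lat = (
            coupled_2x2["dense"],
            coupled_2x2["mpo"],
            coupled_2x2["lattice"],
        )
        psi0 = product_state(lat, 1)
        rec, _ = propagate(psi0, mpo, 0.5, 60)
        v0 = np.zeros(sys.D, dtype=complex)
        v0[sys.state_index(1, (0, 0))] = 1.0
        _, C, pops = dense_propagate(sys, v0, fs_to_au(rec.times_fs))
        assert np.max(np.abs(rec.autocorr - C)) < 1e-6
        assert np.max(np.abs(rec.populations - pops)) < 1e-6


class TestConservation:
    def test_norm_and_energy_without_truncation(self, coupled_2x2):
        mpo, lat = coupled_2x2["mpo"], coupled_2x2["lattice"]
        rec, _ = propagate(product_state(lat, 1), mpo, 0.5, 100)
        assert np.max(np.abs(rec.norms - 1.0)) < 1e-8
        drift = np.max(np.abs(rec.energies - rec.energies[0]))
        assert drift / abs(rec.energies[0]) < 1e-6

    def test_population_sum_with_truncation(self, coupled_2x2):
        mpo, lat = coupled_2x2["mpo"], coupled_2x2["lattice"]
        rec, _ = propagate(product_state(lat, 1), mpo, 0.5, 60, m_max=3)
        assert rec.discarded_cum[-1] > 0  # truncation active
        assert np.max(np.abs(rec.populations.sum(axis=1) - 1.0)) < 1e-8

    def test_truncated_bond_never_exceeds_untruncated(self, coupled_2x2):
        mpo, lat = coupled_2x2["mpo"], coupled_2x2["lattice"]
        rec, _ = propagate(product_state(lat, 1), mpo, 0.5, 30, m_max=3)
        assert np.all(rec.max_bond_post <= rec.max_bond_pre)
        assert np.all(rec.max_bond_post <= 3)


class TestLocalOrder:
    def test_error_vanishes_with_dt(self, coupled_2x2):
        mpo, lat = coupled_2x2["mpo"], coupled_2x2["lattice"]
        psi0 = product_state(lat, 1)
        e_big = step_error_probe(psi0, mpo, 0.5, m_max=2)
        e_small = step_error_probe(psi0, mpo, 0.05, m_max=2)
        assert e_small < e_big
        assert step_error_probe(psi0, mpo, 1e-4, m_max=2) < 1e-6

    def test_commuting_diagonal_hamiltonian_exact_at_any_dt(self):
        omega = 0.01
        model = make_displaced_ho_model(omega, 0.0, 0.0)
        mpo = compile_mpo(assemble_hamiltonian(model, [harmonic_basis(omega, 5)]))
        psi0 = product_state(Lattice(1, (5,)), 0, [1])
        assert step_error_probe(psi0, mpo, 4.0) < 1e-9

    def test_observed_local_order_three(self):
        """Richardson estimate vs the oracle on the frozen audit instance:
        a weakly coupled two-state, two-mode model with the bond cap just
        below the rank the step requires, where the splitting error of the
        symmetric two-site integrator dominates."""
        model = random_coupled_model(2, seed=7, coupling_scale=5e-4)
        bases = [harmonic_basis(model.frequencies[i], 10, mode=i) for i in range(2)]
        mpo = compile_mpo(assemble_hamiltonian(model, bases))
        psi0 = product_state(Lattice(2, (10, 10)), 1)
        e1 = step_error_probe(psi0, mpo, 1.0, m_max=4)
        e2 = step_error_probe(psi0, mpo, 0.5, m_max=4)
        p = np.log2(e1 / e2)
        assert p == pytest.approx(3.0, abs=0.3)

    def test_probe_refuses_oversized_instances(self, coupled_2x2):
        lat = coupled_2x2["lattice"]
        with pytest.raises(ValueError, match="too large"):
            step_error_probe(
                product_state(lat, 1), coupled_2x2["mpo"], 0.5, cap=10
            )


class TestImaginaryTime:
    def test_energy_cools_toward_ground_state(self, coupled_2x2):
        mpo, lat, dense = (
            coupled_2x2["mpo"],
            coupled_2x2["lattice"],
            coupled_2x2["dense"],
        )
        e_ref = np.linalg.eigvalsh(dense.H)[0]
        rec, _ = propagate(
            product_state(lat, 1), mpo, 8.0, 60, imaginary_time=True
        )
        assert rec.energies[-1] < rec.energies[0]
        assert rec.energies[-1] == pytest.approx(e_ref, abs=1e-5)


def test_rejects_unnormalized_initial_state(coupled_2x2):
    lat, mpo = coupled_2x2["lattice"], coupled_2x2["mpo"]
    psi = product_state(lat, 1)
    psi.tensors[0] = 2.0 * psi.tensors[0]
    with pytest.raises(ValueError, match="normalized"):
        propagate(psi, mpo, 0.5, 1)
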