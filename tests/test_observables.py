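"""Condon states, autocorrelation, populations, absorption spectra."""

import numpy as np
import pytest

from vibromps.basis import harmonic_basis
from vibromps.mpo import compile_mpo
from vibromps.mps import Lattice, overlap, product_state
from vibromps.nmode import (
    DipoleModel,
    NModeFunction,
    VibronicModel,
    make_displaced_ho_model,
)
from vibromps.observables import (
    Spectrum,
    absorption_spectrum,
    condon_initial_state,
    find_peaks,
    populations,
)
from vibromps.sqham import assemble_hamiltonian
from vibromps.tdvp import propagate
from vibromps.units import au_to_fs, fs_to_au


class TestCondonState:
    def test_ground_basis_gives_zero_occupation_product(self):
        lat = Lattice(2, (5, 5))
        psi, scale = condon_initial_state(lat, 1, mu=DipoleModel(mu0=0.4))
        assert scale == pytest.approx(0.16)
        assert psi.norm() == pytest.approx(1.0)
        assert np.allclose(populations(psi), [0.0, 1.0], atol=1e-14)
        ref = product_state(lat, 1, [0, 0])
        assert abs(overlap(psi, ref)) == pytest.approx(1.0)

    def test_orthogonal_to_pre_excitation_sector(self):
        """The charge-0 reference (no electronic occupation) and the excited
        charge-1 wavepacket live in disjoint symmetry sectors."""
        lat = Lattice(2, (4,))
        from vibromps.mps import VibronicMPS

        psi, _ = condon_initial_state(lat, 0)
        # build the vacuum-electronic reference by hand
        t = []
        for l in range(lat.L):
            d = lat.dims[l]
            x = np.zeros((1, d, 1), dtype=complex)
            x[0, 0, 0] = 1.0
            t.append(x)
        vac = VibronicMPS(lat, t, [np.array([0])] * (lat.L + 1), 0)
        assert abs(overlap(psi, vac)) == 0.0


class TestPopulations:
    def test_rabi_cos_squared(self, rabi_two_level):
        mpo, lat, c = (
            rabi_two_level["mpo"],
            rabi_two_level["lattice"],
            rabi_two_level["c"],
        )
        rec, _ = propagate(product_state(lat, 1), mpo, 0.5, 100)
        t = fs_to_au(rec.times_fs)
        assert np.max(np.abs(rec.populations[:, 1] - np.cos(c * t) ** 2)) < 1e-6

    def test_zero_coupling_constant_populations(self):
        w = 0.01
        model = VibronicModel(
            N_el=2,
            M=1,
            frequencies=np.array([w]),
            diag={
                0: NModeFunction(M=1, F1={0: lambda q: 0.5 * w**2 * q**2}),
                1: NModeFunction(
                    M=1, F0=0.01, F1={0: lambda q: 0.5 * w**2 * (q - 3.0) ** 2}
                ),
            },
        )
        mpo = compile_mpo(assemble_hamiltonian(model, [harmonic_basis(w, 5)]))
        lat = Lattice(2, (5,))
        rec, _ = propagate(product_state(lat, 1), mpo, 0.5, 40)
        assert np.max(np.abs(rec.populations[:, 1] - 1.0)) < 1e-10

    def test_decoupled_autocorrelation_is_single_block(self):
        """Without coupling the autocorrelation of a wavepacket started on
        one surface equals that surface's own (displaced HO) closed form."""
        w, d = 0.01, 8.0
        S = 0.5 * w * d**2
        model = VibronicModel(
            N_el=2,
            M=1,
            frequencies=np.array([w]),
            diag={
                0: NModeFunction(M=1, F1={0: lambda q: 0.5 * w**2 * q**2}),
                1: NModeFunction(M=1, F1={0: lambda q: 0.5 * w**2 * (q - d) ** 2}),
            },
        )
        mpo = compile_mpo(assemble_hamiltonian(model, [harmonic_basis(w, 14)]))
        rec, _ = propagate(product_state(Lattice(2, (14,)), 1), mpo, 0.5, 80)
        t = fs_to_au(rec.times_fs)
        exact = np.exp(-S * (1 - np.exp(-1j * w * t))) * np.exp(-1j * w * t / 2)
        assert np.max(np.abs(rec.autocorr - exact)) < 1e-5


class TestSpectrum:
    def test_pure_phase_gives_single_peak_at_energy(self):
        E, dt_fs, n = 0.02, 0.5, 400
        t = dt_fs * np.arange(n + 1)
        C = np.exp(-1j * E * fs_to_au(t))
        spec = absorption_spectrum(t, C)
        pos, hts = find_peaks(spec, floor=0.5)
        grid = 2 * np.pi / fs_to_au(t[-1])
        assert len(pos) == 1
        assert abs(pos[0] - E) < grid

    def test_zero_autocorrelation_gives_zero_spectrum(self):
        t = 0.5 * np.arange(64)
        spec = absorption_spectrum(t, np.zeros(64, dtype=complex))
        assert np.all(spec.magnitude == 0)

    def test_shift_applied_and_recorded(self):
        t = 0.5 * np.arange(32)
        spec = absorption_spectrum(t, np.exp(-0.01 * t), shift=0.1)
        assert spec.shift == 0.1
        assert spec.omega[0] == pytest.approx(0.1)

    def test_non_uniform_grid_rejected(self):
        t = np.array([0.0, 0.5, 1.5])
        with pytest.raises(ValueError):
            absorption_spectrum(t, np.ones(3, dtype=complex))

    def test_parseval_stable_under_doubling_for_decaying_C(self):
        gamma, dt = 0.02, 0.5
        t1 = dt * np.arange(801)
        t2 = dt * np.arange(1601)
        make = lambda t: absorption_spectrum(
            t, np.exp(-gamma * fs_to_au(t)) * np.exp(-1j * 0.05 * fs_to_au(t))
        )
        s1, s2 = make(t1), make(t2)
        p1 = np.trapezoid(s1.magnitude**2, s1.omega)
        p2 = np.trapezoid(s2.magnitude**2, s2.omega)
        assert p2 == pytest.approx(p1, rel=1e-3)

    def test_peaks_only_at_oracle_eigenvalue_differences(self, coupled_2x2):
        sys, mpo, lat = (
            coupled_2x2["dense"],
            coupled_2x2["mpo"],
            coupled_2x2["lattice"],
        )
        rec, _ = propagate(product_state(lat, 1), mpo, 0.5, 400)
        spec = absorption_spectrum(rec.times_fs, rec.autocorr)
        pos, _ = find_peaks(spec, floor=0.05)
        evals = np.linalg.eigvalsh(sys.H)
        grid = 2 * np.pi / fs_to_au(rec.times_fs[-1])
        for w in pos:
            assert np.min(np.abs(evals - w)) < grid

    def test_franck_condon_progression(self):
        """Displaced HO with S = 0.5: peaks spaced by omega, intensities
        Poisson e^{-S} S^n / n! (window chosen as an integer number of
        vibrational periods)."""
        omega, S = 0.01, 0.5
        d = np.sqrt(2 * S / omega)
        model = make_displaced_ho_model(omega, d, 0.0)
        mpo = compile_mpo(assemble_hamiltonian(model, [harmonic_basis(omega, 16)]))
        period_fs = au_to_fs(2 * np.pi / omega)
        steps_per, n_periods = 32, 20
        rec, _ = propagate(
            product_state(Lattice(1, (16,)), 0), mpo, period_fs / steps_per,
            steps_per * n_periods,
        )
        spec = absorption_spectrum(rec.times_fs, rec.autocorr)
        pos, hts = find_peaks(spec, floor=0.001)
        grid = 2 * np.pi / fs_to_au(rec.times_fs[-1])
        assert np.all(np.abs(np.diff(pos[:6]) - omega) < grid)
        pn = np.exp(-S) * S ** np.arange(5) / np.array([1, 1, 2, 6, 24])
        ratios = (hts[:5] / hts[0]) / (pn / pn[0])
        assert np.max(np.abs(ratios - 1)) < 0.03
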