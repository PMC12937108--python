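"""n-mode expansion containers, synthetic generators, model file I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vibromps.nmode import (
    Grid1,
    ModelError,
    Morse1,
    NModeFunction,
    Poly1,
    Poly2,
    evaluate_nmode,
    load_model,
    make_coupled_two_state_model,
    make_displaced_ho_model,
    random_coupled_model,
    save_model,
)


class TestEvaluateNMode:
    def test_constant_only(self):
        f = NModeFunction(M=3, F0=0.5)
        assert evaluate_nmode(f, [1.0, -2.0, 0.3]) == 0.5

    def test_one_body_additive(self):
        f = NModeFunction(
            M=2, F1={0: lambda q: q**2, 1: lambda q: 2 * q}
        )
        assert evaluate_nmode(f, (1.0, 3.0)) == pytest.approx(7.0)

    def test_two_body_term_by_term_oracle(self):
        f = NModeFunction(
            M=2,
            F1={0: lambda q: q**2, 1: lambda q: 2 * q},
            F2={(0, 1): lambda a, b: a * b},
        )
        Q = (1.0, 3.0)
        # brute-force sum over the stored terms
        expected = sum(g(Q[i]) for i, g in f.F1.items()) + f.F2[(0, 1)](*Q)
        assert evaluate_nmode(f, Q) == pytest.approx(10.0)
        assert evaluate_nmode(f, Q) == pytest.approx(expected, abs=1e-14)

    def test_dimension_mismatch(self):
        f = NModeFunction(M=2, F0=1.0)
        with pytest.raises(ModelError):
            evaluate_nmode(f, [1.0])

    @given(
        st.lists(st.floats(-3, 3), min_size=3, max_size=3),
        st.lists(st.floats(-2, 2), min_size=4, max_size=4),
    )
    @settings(max_examples=50, deadline=None)
    def test_additivity_property(self, Q, coefs):
        """The expansion value is exactly the sum of its stored terms."""
        c0, c1, c2, c12 = coefs
        f = NModeFunction(
            M=3,
            F0=c0,
            F1={0: Poly1([0, c1]), 2: Poly1([0, 0, c2])},
            F2={(0, 2): Poly2([[0, 0], [0, c12]])},
        )
        val = evaluate_nmode(f, Q)
        expected = c0 + c1 * Q[0] + c2 * Q[2] ** 2 + c12 * Q[0] * Q[2]
        assert val == pytest.approx(expected, abs=1e-12)

    def test_invalid_indices_rejected(self):
        with pytest.raises(ModelError):
            NModeFunction(M=2, F1={5: lambda q: q})
        with pytest.raises(ModelError):
            NModeFunction(M=3, F2={(2, 1): lambda a, b: a * b})


class TestDisplacedHO:
    def test_undisplaced_minimum(self):
        m = make_displaced_ho_model(1.0, 0.0, dE=0.25)
        assert evaluate_nmode(m.diag[0], [0.0]) == pytest.approx(0.25)

    def test_quadratic_evaluation(self):
        m = make_displaced_ho_model(1.0, 1.0, 0.0)
        assert evaluate_nmode(m.diag[0], [1.0]) == pytest.approx(0.0, abs=1e-14)
        assert evaluate_nmode(m.diag[0], [0.0]) == pytest.approx(0.5)

    def test_huang_rhys_metadata(self):
        m = make_displaced_ho_model(1.0, 1.0, 0.0)
        assert m.metadata["huang_rhys"] == pytest.approx(0.5)

    def test_minimum_and_curvature_by_finite_differences(self):
        omega, d = 0.8, 1.7
        m = make_displaced_ho_model(omega, d, 0.0)
        f = m.diag[0]
        h = 1e-4
        grad = (f([d + h]) - f([d - h])) / (2 * h)
        curv = (f([d + h]) - 2 * f([d]) + f([d - h])) / h**2
        assert abs(grad) < 1e-6
        assert curv == pytest.approx(omega**2, rel=1e-6)

    def test_rejects_bad_frequency(self):
        with pytest.raises(ModelError):
            make_displaced_ho_model(-1.0, 0.0)


class TestCoupledTwoState:
    def test_morse_minimum(self):
        spec = {
            "frequencies": [0.01],
            "states": [
                {"energy": 0.0, "modes": [{"type": "harmonic"}]},
                {"energy": 0.1, "modes": [{"type": "morse", "D": 1.0, "a": 0.1}]},
            ],
        }
        m = make_coupled_two_state_model(1, spec)
        # Morse term vanishes at its minimum Q = 0
        assert evaluate_nmode(m.diag[1], [0.0]) == pytest.approx(0.1)

    def test_inconsistent_spec_rejected(self):
        spec = {
            "frequencies": [0.01, 0.02],
            "states": [
                {"energy": 0.0, "modes": [{"type": "harmonic"}]},  # one missing
                {"energy": 0.1, "modes": [{}, {}]},
            ],
        }
        with pytest.raises(ModelError):
            make_coupled_two_state_model(2, spec)

    def test_generator_deterministic(self):
        a = random_coupled_model(3, seed=42)
        b = random_coupled_model(3, seed=42)
        assert np.allclose(a.frequencies, b.frequencies)
        Q = [0.3, -1.0, 2.0]
        assert evaluate_nmode(a.diag[1], Q) == evaluate_nmode(b.diag[1], Q)


class TestModelFileRoundTrip:
    def test_round_trip_values(self, tmp_path):
        m = random_coupled_model(2, seed=9)
        p = tmp_path / "model.yaml"
        save_model(m, p)
        m2 = load_model(p)
        assert m2.N_el == m.N_el and m2.M == m.M
        assert np.allclose(m2.frequencies, m.frequencies)
        rng = np.random.default_rng(0)
        for Q in rng.uniform(-2, 2, size=(5, 2)):
            for a in range(2):
                assert evaluate_nmode(m2.diag[a], Q) == pytest.approx(
                    evaluate_nmode(m.diag[a], Q), rel=1e-12, abs=1e-15
                )
            assert evaluate_nmode(m2.offdiag[(0, 1)], Q) == pytest.approx(
                evaluate_nmode(m.offdiag[(0, 1)], Q), rel=1e-12, abs=1e-15
            )

    def test_grid_term_round_trip(self, tmp_path):
        q = np.linspace(-3, 3, 121)
        f = NModeFunction(M=1, F1={0: Grid1(q, np.tanh(q))})
        from vibromps.nmode import VibronicModel

        m = VibronicModel(
            N_el=1, M=1, frequencies=np.array([0.01]), diag={0: f}
        )
        p = tmp_path / "m.yaml"
        save_model(m, p)
        m2 = load_model(p)
        assert evaluate_nmode(m2.diag[0], [0.7]) == pytest.approx(
            np.tanh(0.7), abs=1e-6
        )

    def test_unknown_format_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("format: not-a-model\n")
        with pytest.raises(ModelError):
            load_model(p)


def test_complex_couplings_rejected():
    """Couplings are real and stored once per unordered pair."""
    from vibromps.nmode import VibronicModel

    with pytest.raises(ModelError):
        VibronicModel(
            N_el=2,
            M=0,
            frequencies=np.zeros(0),
            diag={0: NModeFunction(M=0), 1: NModeFunction(M=0)},
            offdiag={(0, 0): NModeFunction(M=0, F0=0.1)},
        )


def test_morse_equivalent_frequency():
    m = Morse1(D=10.0, a=0.5)
    assert m.omega == pytest.approx(0.5 * np.sqrt(20.0))
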