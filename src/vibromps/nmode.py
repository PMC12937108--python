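"""n-mode representation of potential surfaces and vibronic model definitions.

A multidimensional function ``F(Q)`` over the mass-weighted normal coordinates
``Q = (Q_1, ..., Q_M)`` is stored as a many-body (n-mode) expansion

    F(Q) = F0 + sum_i F1[i](Q_i) + sum_{i<j} F2[ij](Q_i, Q_j) + ...

truncated here at order two for evaluation (order three is accepted as a
structural hook).  The expansion carries a zeroth-order constant ``F0`` so
that vertical electronic energies and constant nonadiabatic couplings live in
the same container as the coordinate-dependent terms.

A :class:`VibronicModel` collects one diagonal surface per electronic state
and one real coupling surface per unordered state pair, i.e. the block
operator

    H = [[T + v_1,   V_12, ...],
         [V_21,   T + v_2, ...],
         ...]

with ``T = -1/2 sum_i d^2/dQ_i^2`` (hbar = 1, mass-weighted coordinates).

All energies are in hartree and coordinates in mass-weighted atomic units;
:mod:`vibromps.units` converts to cm^-1 / eV / fs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import yaml

from .units import cm1_to_au, au_to_cm1

__all__ = [
    "Poly1",
    "Morse1",
    "Grid1",
    "Poly2",
    "NModeFunction",
    "VibronicModel",
    "DipoleModel",
    "evaluate_nmode",
    "make_displaced_ho_model",
    "make_coupled_two_state_model",
    "random_coupled_model",
    "save_model",
    "load_model",
]


class ModelError(ValueError):
    """Raised for inconsistent model definitions."""


# ---------------------------------------------------------------------------
# serializable 1D / 2D term functions
# ---------------------------------------------------------------------------


class Poly1:
    """Polynomial one-body term sum_p c_p Q^p (ascending coefficients)."""

    kind = "poly"

    def __init__(self, coeffs):
        self.coeffs = np.atleast_1d(np.asarray(coeffs, dtype=float))

    def __call__(self, q):
        return np.polynomial.polynomial.polyval(q, self.coeffs)

    def to_dict(self):
        return {"type": "poly", "coeffs": self.coeffs.tolist()}


class Morse1:
    """Morse one-body term D (1 - exp(-a (Q - q0)))^2.

    Zero at its minimum ``q0``; harmonic curvature ``2 D a^2`` there, i.e. an
    equivalent harmonic frequency ``omega = a sqrt(2 D)`` in mass-weighted
    units.
    """

    kind = "morse"

    def __init__(self, D, a, q0=0.0):
        if D <= 0 or a <= 0:
            raise ModelError("Morse parameters D and a must be positive")
        self.D, self.a, self.q0 = float(D), float(a), float(q0)

    def __call__(self, q):
        return self.D * (1.0 - np.exp(-self.a * (np.asarray(q) - self.q0))) ** 2

    @property
    def omega(self) -> float:
        return self.a * np.sqrt(2.0 * self.D)

    def to_dict(self):
        return {"type": "morse", "D": self.D, "a": self.a, "q0": self.q0}


class Grid1:
    """Tabulated one-body term, cubic-spline interpolated."""

    kind = "grid"

    def __init__(self, q, v):
        from scipy.interpolate import CubicSpline

        q = np.asarray(q, dtype=float)
        v = np.asarray(v, dtype=float)
        if q.ndim != 1 or q.shape != v.shape or q.size < 4:
            raise ModelError("Grid1 needs matching 1D arrays of >= 4 points")
        self.q, self.v = q, v
        self._spl = CubicSpline(q, v)

    def __call__(self, q):
        return self._spl(q)

    def to_dict(self):
        return {"type": "grid", "q": self.q.tolist(), "v": self.v.tolist()}


class Poly2:
    """Two-body polynomial term sum_{pq} c[p, q] Qi^p Qj^q."""

    kind = "poly2"

    def __init__(self, coeffs):
        self.coeffs = np.atleast_2d(np.asarray(coeffs, dtype=float))

    def __call__(self, qi, qj):
        qi, qj = np.broadcast_arrays(qi, qj)
        return np.polynomial.polynomial.polyval2d(qi, qj, self.coeffs)

    def to_dict(self):
        return {"type": "poly2", "coeffs": self.coeffs.tolist()}


_TERM1_TYPES = {"poly": Poly1, "morse": Morse1, "grid": Grid1}


def _term1_from_dict(d: Mapping) -> Callable:
    t = d["type"]
    if t == "poly":
        return Poly1(d["coeffs"])
    if t == "morse":
        return Morse1(d["D"], d["a"], d.get("q0", 0.0))
    if t == "grid":
        return Grid1(d["q"], d["v"])
    raise ModelError(f"unknown one-body term type {t!r}")


def _term2_from_dict(d: Mapping) -> Callable:
    if d["type"] == "poly2":
        return Poly2(d["coeffs"])
    raise ModelError(f"unknown two-body term type {d['type']!r}")


# ---------------------------------------------------------------------------
# n-mode containers
# ---------------------------------------------------------------------------


@dataclass
class NModeFunction:
    """n-mode expansion of a surface or coupling over M modes.

    ``F1`` maps a mode index to a 1D callable, ``F2`` maps an ordered pair
    ``(i, j)`` with ``i < j`` to a 2D callable, ``F3`` is a structural hook
    for three-body terms (stored, not evaluated).
    """

    M: int
    F0: float = 0.0
    F1: dict = field(default_factory=dict)
    F2: dict = field(default_factory=dict)
    F3: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.M < 0:
            raise ModelError("mode count must be non-negative")
        if not np.isfinite(self.F0):
            raise ModelError("F0 must be finite")
        for i in self.F1:
            if not (0 <= i < self.M):
                raise ModelError(f"one-body mode index {i} outside [0, {self.M})")
        for ij in self.F2:
            i, j = ij
            if not (0 <= i < j < self.M):
                raise ModelError(f"two-body pair {ij} must satisfy 0 <= i < j < M")
        for ijk in self.F3:
            if not (0 <= ijk[0] < ijk[1] < ijk[2] < self.M):
                raise ModelError(f"three-body triple {ijk} must be strictly ordered")

    @property
    def order(self) -> int:
        if self.F3:
            return 3
        if self.F2:
            return 2
        if self.F1:
            return 1
        return 0

    def __call__(self, Q) -> float:
        return evaluate_nmode(self, Q)


def evaluate_nmode(f: NModeFunction, Q) -> float:
    """Evaluate the n-mode expansion at a point in M-dimensional mode space.

    Exactly additive over the stored terms; three-body hooks, if populated,
    are included.
    """
    Q = np.atleast_1d(np.asarray(Q, dtype=float))
    if Q.shape != (f.M,):
        raise ModelError(f"expected {f.M} coordinates, got shape {Q.shape}")
    val = float(f.F0)
    for i, g in f.F1.items():
        val += float(g(Q[i]))
    for (i, j), g in f.F2.items():
        val += float(g(Q[i], Q[j]))
    for (i, j, k), g in f.F3.items():
        val += float(g(Q[i], Q[j], Q[k]))
    return val


@dataclass
class DipoleModel:
    """Transition dipole in n-mode representation.

    Only the constant (Condon) term ``mu0`` is used by the dynamics; the
    coordinate-dependent orders are carried as a hook.
    """

    mu0: float = 1.0
    higher: NModeFunction | None = None

    def __post_init__(self):
        if not np.isfinite(self.mu0):
            raise ModelError("mu0 must be finite")


@dataclass
class VibronicModel:
    """Multi-state vibronic Hamiltonian in n-mode form.

    Attributes
    ----------
    N_el, M:
        Number of electronic states and vibrational modes.
    frequencies:
        Per-mode reference harmonic frequency in hartree (used for basis
        construction and for unit checks).
    diag:
        ``state -> NModeFunction`` diagonal PES; its ``F0`` holds the
        vertical electronic energy.
    offdiag:
        ``(alpha, beta), alpha < beta -> NModeFunction`` real coupling,
        applied Hermitianly to both blocks.
    kinetic_coeff:
        Per-mode coefficient ``c_i`` of ``-d^2/dQ_i^2``; the default 1/2
        everywhere is the mass-weighted convention.
    """

    N_el: int
    M: int
    frequencies: np.ndarray
    diag: dict = field(default_factory=dict)
    offdiag: dict = field(default_factory=dict)
    kinetic_coeff: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.N_el < 1 or self.M < 0:
            raise ModelError("need N_el >= 1 and M >= 0")
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.shape != (self.M,):
            raise ModelError("frequencies must have one entry per mode")
        if self.M and np.any(self.frequencies <= 0):
            raise ModelError("reference frequencies must be positive")
        if self.kinetic_coeff is None:
            self.kinetic_coeff = np.full(self.M, 0.5)
        self.kinetic_coeff = np.asarray(self.kinetic_coeff, dtype=float)
        for a in range(self.N_el):
            if a not in self.diag:
                raise ModelError(f"missing diagonal surface for state {a}")
            if self.diag[a].M != self.M:
                raise ModelError("diagonal surface mode count mismatch")
        norm = {}
        for (a, b), f in self.offdiag.items():
            if a == b:
                raise ModelError("off-diagonal coupling needs distinct states")
            if not (0 <= a < self.N_el and 0 <= b < self.N_el):
                raise ModelError("coupling state index out of range")
            if f.M != self.M:
                raise ModelError("coupling surface mode count mismatch")
            key = (min(a, b), max(a, b))
            if key in norm and norm[key] is not f:
                raise ModelError(f"coupling {key} defined twice")
            norm[key] = f
        self.offdiag = norm

    def coupling(self, a: int, b: int) -> NModeFunction | None:
        """Coupling surface for an unordered state pair, or None."""
        return self.offdiag.get((min(a, b), max(a, b)))


# ---------------------------------------------------------------------------
# synthetic model generators
# ---------------------------------------------------------------------------


def make_displaced_ho_model(omega: float, d: float, dE: float = 0.0) -> VibronicModel:
    """Single excited state, single mode: v(Q) = omega^2 (Q - d)^2 / 2 + dE.

    The displacement is recorded as a Huang-Rhys factor S = omega d^2 / 2 in
    the model metadata; the Condon emission from the undisplaced ground
    vibrational state then carries the analytic Poisson Franck-Condon
    progression exp(-S) S^n / n!.
    """
    if omega <= 0:
        raise ModelError("omega must be positive")
    pes = NModeFunction(
        M=1,
        F0=float(dE),
        F1={0: Poly1([0.5 * omega**2 * d**2, -(omega**2) * d, 0.5 * omega**2])},
    )
    return VibronicModel(
        N_el=1,
        M=1,
        frequencies=np.array([omega]),
        diag={0: pes},
        metadata={"huang_rhys": 0.5 * omega * d**2, "omega": omega, "dE": float(dE)},
    )


def _state_mode_term(entry: Mapping, omega_ref: float):
    """One-body PES term from a per-mode spec entry."""
    kind = entry.get("type", "harmonic")
    if kind == "harmonic":
        w = float(entry.get("omega", omega_ref))
        d = float(entry.get("shift", 0.0))
        return Poly1([0.5 * w**2 * d**2, -(w**2) * d, 0.5 * w**2])
    if kind == "poly":
        return Poly1(entry["coeffs"])
    if kind == "morse":
        return Morse1(entry["D"], entry["a"], entry.get("q0", 0.0))
    raise ModelError(f"unknown per-mode spec type {kind!r}")


def make_coupled_two_state_model(
    M: int,
    spec: Mapping,
    coupling: NModeFunction | None = None,
) -> VibronicModel:
    """Two-state model with per-mode anharmonic diagonals and a coupling.

    ``spec`` is a mapping with:

    - ``frequencies``: M reference frequencies (hartree)
    - ``states``: two entries, each ``{"energy": F0, "modes": [per-mode term
      spec, ...], "pairs": {(i, j): Poly2-coeffs}}`` where a per-mode term
      spec is ``{"type": "harmonic"|"poly"|"morse", ...}``
    """
    freqs = np.asarray(spec["frequencies"], dtype=float)
    states = spec["states"]
    if len(states) != 2:
        raise ModelError("spec must define exactly two states")
    diag = {}
    for a, st in enumerate(states):
        modes = st.get("modes", [])
        if len(modes) != M:
            raise ModelError(f"state {a} must specify all {M} modes")
        F1 = {i: _state_mode_term(m, freqs[i]) for i, m in enumerate(modes)}
        F2 = {
            tuple(sorted(ij)): Poly2(c) for ij, c in st.get("pairs", {}).items()
        }
        diag[a] = NModeFunction(M=M, F0=float(st.get("energy", 0.0)), F1=F1, F2=F2)
    offdiag = {}
    if coupling is not None:
        offdiag[(0, 1)] = coupling
    return VibronicModel(
        N_el=2, M=M, frequencies=freqs, diag=diag, offdiag=offdiag
    )


def random_coupled_model(
    M: int,
    seed: int,
    gap: float = 0.02,
    coupling_scale: float = 0.004,
    anharmonic: bool = True,
) -> VibronicModel:
    """Seeded maleimide-like two-state generator.

    Emulates a vibronically coupled pair of excited states of a rigid
    organic chromophore: mode frequencies drawn from 800-1800 cm^-1, the
    lower surface harmonic, the upper surface displaced (Huang-Rhys factors
    0.05-0.35) with mild Morse distortion on roughly half the modes, a
    bilinear (Duschinsky-like) two-body term on the first mode pair, and a
    constant plus linear off-diagonal coupling.  ``gap`` is the vertical
    energy separation between the two diabatic states (hartree).
    """
    rng = np.random.default_rng(seed)
    freqs = cm1_to_au(rng.uniform(800.0, 1800.0, size=M))
    # lower surface: harmonic at the reference frequencies
    lo = NModeFunction(
        M=M, F0=0.0, F1={i: Poly1([0.0, 0.0, 0.5 * freqs[i] ** 2]) for i in range(M)}
    )
    # upper surface: displaced, frequency-scaled, optionally Morse-distorted
    F1 = {}
    for i in range(M):
        w = freqs[i] * rng.uniform(0.9, 1.1)
        S = rng.uniform(0.05, 0.35)
        d = np.sqrt(2.0 * S / w) * rng.choice([-1.0, 1.0])
        if anharmonic and rng.random() < 0.5:
            # Morse with matching curvature at the displaced minimum
            D = rng.uniform(15.0, 40.0) * w
            a = w / np.sqrt(2.0 * D)
            F1[i] = Morse1(D, a, q0=d)
        else:
            F1[i] = Poly1([0.5 * w**2 * d**2, -(w**2) * d, 0.5 * w**2])
    F2 = {}
    if M >= 2:
        bilin = 0.05 * freqs[0] * freqs[1]
        F2[(0, 1)] = Poly2([[0.0, 0.0], [0.0, bilin]])
    hi = NModeFunction(M=M, F0=float(gap), F1=F1, F2=F2)
    # constant + linear diabatic coupling
    c0 = coupling_scale * rng.uniform(0.5, 1.5)
    lam = coupling_scale * rng.uniform(-1.0, 1.0, size=M)
    V = NModeFunction(
        M=M, F0=c0, F1={i: Poly1([0.0, lam[i]]) for i in range(M)}
    )
    return VibronicModel(
        N_el=2,
        M=M,
        frequencies=freqs,
        diag={0: lo, 1: hi},
        offdiag={(0, 1): V},
        metadata={"seed": int(seed)},
    )


# ---------------------------------------------------------------------------
# model file I/O (YAML, documented schema)
# ---------------------------------------------------------------------------

_FORMAT = "vibromps-model-v1"


def _nmode_to_dict(f: NModeFunction) -> dict:
    d: dict = {"constant": float(f.F0)}
    if f.F1:
        d["onebody"] = {str(i): g.to_dict() for i, g in sorted(f.F1.items())}
    if f.F2:
        d["twobody"] = {f"{i},{j}": g.to_dict() for (i, j), g in sorted(f.F2.items())}
    return d


def _nmode_from_dict(d: Mapping, M: int) -> NModeFunction:
    F1 = {int(k): _term1_from_dict(v) for k, v in d.get("onebody", {}).items()}
    F2 = {}
    for k, v in d.get("twobody", {}).items():
        i, j = (int(x) for x in k.split(","))
        F2[(i, j)] = _term2_from_dict(v)
    return NModeFunction(M=M, F0=float(d.get("constant", 0.0)), F1=F1, F2=F2)


def save_model(model: VibronicModel, path) -> None:
    """Write a model file (YAML; frequencies stored in cm^-1)."""
    doc = {
        "format": _FORMAT,
        "n_states": model.N_el,
        "n_modes": model.M,
        "frequencies_cm1": [float(au_to_cm1(w)) for w in model.frequencies],
        "states": {str(a): _nmode_to_dict(model.diag[a]) for a in range(model.N_el)},
        "couplings": {
            f"{a},{b}": _nmode_to_dict(f) for (a, b), f in sorted(model.offdiag.items())
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model(path) -> VibronicModel:
    """Read a model file written by :func:`save_model`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("format") != _FORMAT:
        raise ModelError(f"unrecognized model file format {doc.get('format')!r}")
    M = int(doc["n_modes"])
    diag = {int(a): _nmode_from_dict(d, M) for a, d in doc["states"].items()}
    offdiag = {}
    for k, d in doc.get("couplings", {}).items():
        a, b = (int(x) for x in k.split(","))
        offdiag[(a, b)] = _nmode_from_dict(d, M)
    return VibronicModel(
        N_el=int(doc["n_states"]),
        M=M,
        frequencies=np.array([cm1_to_au(w) for w in doc["frequencies_cm1"]]),
        diag=diag,
        offdiag=offdiag,
    )
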