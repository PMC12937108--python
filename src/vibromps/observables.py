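"""Condon excitation, autocorrelation, diabatic populations, spectra.

The absorption lineshape is the half-line Fourier transform of the
wavepacket autocorrelation function

    I(omega) ~ int_0^infty e^{i omega t} <psi(0)|psi(t)> dt

evaluated by trapezoid quadrature on the propagation time grid; the
absolute magnitude |I| is reported and the frequency axis may be shifted so
the 0-0 line lands on a reference energy.  No zero-padding or broadening is
applied by default (flags exist).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mps import Lattice, VibronicMPS, local_expectation, product_state
from .mpo import E_NUM
from .nmode import DipoleModel
from .units import fs_to_au

__all__ = [
    "Spectrum",
    "condon_initial_state",
    "autocorrelation",
    "populations",
    "absorption_spectrum",
    "find_peaks",
]


def condon_initial_state(
    lattice: Lattice,
    gamma: int,
    occupations=None,
    mu: DipoleModel | None = None,
):
    """Initial excited wavepacket under the Condon approximation.

    The vibrational part is the electronic-ground-state wavepacket (in the
    ground-state modal basis: all occupations zero, or explicit
    ``occupations``); the electronic occupation is placed on state
    ``gamma``.  The state is normalized; the constant dipole ``mu.mu0``
    only scales overall intensity and is returned separately.

    Returns ``(psi, intensity_scale)`` with ``intensity_scale = mu0**2``.
    """
    psi = product_state(lattice, gamma, occupations)
    scale = 1.0 if mu is None else float(mu.mu0) ** 2
    return psi, scale


def autocorrelation(record) -> np.ndarray:
    """C(t) = <psi(0)|psi(t)> from a propagation record."""
    return np.asarray(record.autocorr)


def populations(psi: VibronicMPS) -> np.ndarray:
    """Diabatic populations <N_gamma> = <a^dag_gamma a_gamma>, normalized."""
    n2 = psi.norm() ** 2
    p = np.array(
        [local_expectation(psi, g, E_NUM).real for g in range(psi.lattice.N_el)]
    )
    return p / n2


@dataclass
class Spectrum:
    """|I(omega)| with full transform metadata.

    ``omega`` is in hartree (before any unit conversion by the caller) and
    already includes the 0-0 ``shift``; the raw complex transform is kept in
    ``intensity``.
    """

    omega: np.ndarray
    intensity: np.ndarray
    shift: float
    meta: dict = field(default_factory=dict)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.intensity)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "omega": self.omega,
                "re_I": self.intensity.real,
                "im_I": self.intensity.imag,
                "abs_I": self.magnitude,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def absorption_spectrum(
    times_fs: np.ndarray,
    C: np.ndarray,
    shift: float = 0.0,
    omega_max: float | None = None,
    n_omega: int | None = None,
    zero_pad: int = 0,
    broadening_fs: float | None = None,
) -> Spectrum:
    """Half-line Fourier transform of the autocorrelation function.

    ``I(omega_k) = sum_n w_n exp(i omega_k t_n) C(t_n) dt`` with trapezoid
    end weights on the uniform grid starting at t = 0.  ``shift`` moves the
    frequency axis (0-0 placement).  ``zero_pad`` appends that many zero
    samples and ``broadening_fs`` applies a Gaussian window of the given
    width; both default off.
    """
    t = fs_to_au(np.asarray(times_fs, dtype=float))
    C = np.asarray(C, dtype=complex)
    if t.ndim != 1 or t.shape != C.shape or t.size < 2:
        raise ValueError("need matching 1D time/autocorrelation arrays")
    dt = t[1] - t[0]
    if t[0] != 0.0 or not np.allclose(np.diff(t), dt, rtol=0, atol=1e-10 * dt):
        raise ValueError("time grid must be uniform and start at t = 0")
    if broadening_fs is not None:
        C = C * np.exp(-0.5 * (t / fs_to_au(broadening_fs)) ** 2)
    if zero_pad:
        C = np.concatenate([C, np.zeros(zero_pad)])
        t = t[0] + dt * np.arange(C.size)
    T = t[-1]
    w = np.full(t.size, dt)
    w[0] = w[-1] = 0.5 * dt
    if omega_max is None:
        omega_max = np.pi / dt
    if n_omega is None:
        n_omega = int(np.ceil(omega_max / (2 * np.pi / T))) + 1
    omega = np.linspace(0.0, omega_max, n_omega)
    phases = np.exp(1j * np.outer(omega, t))
    I = phases @ (w * C)
    return Spectrum(
        omega=omega + shift,
        intensity=I,
        shift=shift,
        meta={
            "dt_au": dt,
            "T_au": T,
            "zero_pad": zero_pad,
            "broadening_fs": broadening_fs,
            "convention": "half-line e^{+i omega t}, magnitude reported",
        },
    )


def find_peaks(spec: Spectrum, floor: float = 0.01):
    """Local maxima of |I| above ``floor`` x global max, with quadratic
    sub-grid refinement.

    Returns ``(positions, heights)`` sorted by position.
    """
    y = spec.magnitude
    x = spec.omega
    thr = floor * y.max()
    pos, hts = [], []
    for i in range(1, y.size - 1):
        if y[i] >= y[i - 1] and y[i] > y[i + 1] and y[i] >= thr:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            if denom < 0:
                delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
                delta = np.clip(delta, -0.5, 0.5)
            else:
                delta = 0.0
            h = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta
            pos.append(x[i] + delta * (x[1] - x[0]))
            hts.append(h)
    return np.asarray(pos), np.asarray(hts)
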