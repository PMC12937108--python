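"""Unit conversions.

All internal quantities are in Hartree atomic units with hbar = 1 and
mass-weighted normal coordinates, so the per-mode kinetic operator is
T(Q) = -1/2 d^2/dQ^2 and a harmonic mode of frequency ``omega`` (hartree)
has potential ``omega**2 Q**2 / 2`` and level spacing ``omega``.

Conversion factors follow CODATA 2018.
"""

# 1 hartree in cm^-1
HARTREE_CM1 = 219474.6313632
# 1 hartree in eV
HARTREE_EV = 27.211386245988
# 1 atomic unit of time in femtoseconds
AU_TIME_FS = 0.02418884254


def cm1_to_au(x: float) -> float:
    """Wavenumber (cm^-1) to energy (hartree)."""
    return x / HARTREE_CM1


def au_to_cm1(x: float) -> float:
    return x * HARTREE_CM1


def ev_to_au(x: float) -> float:
    return x / HARTREE_EV


def au_to_ev(x: float) -> float:
    return x * HARTREE_EV


def fs_to_au(t: float) -> float:
    """Time in fs to atomic units of time."""
    return t / AU_TIME_FS


def au_to_fs(t: float) -> float:
    return t * AU_TIME_FS
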