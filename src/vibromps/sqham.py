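"""Second-quantized vibronic Hamiltonian as a symbolic term list.

Each term is

    coeff * a^dag_alpha a_beta * prod_i (b^dag_{k_i} b_{h_i})

with at most one composite bosonic factor per mode (factors on distinct
modes commute, so they are stored as per-mode matrix units E_{kh} =
b^dag_k b_h).  Diagonal blocks (alpha == beta) carry the per-state
vibrational Hamiltonian including kinetic energy; off-diagonal blocks carry
potential-only coupling composites plus constant couplings; vertical
energies appear as terms with an empty bosonic factor list.

The term list is also the plain-text interchange format between integral
generation and MPO compilation:

    # vibromps-terms-v1 N_el=<n> M=<m> N=<N_0,...>
    coeff  alpha beta  [i k_i h_i  [j k_j h_j]]
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import ModalBasis
from .integrals import IntegralTable, compute_tables
from .nmode import VibronicModel

__all__ = ["SQTerm", "SQHamiltonian", "assemble_hamiltonian"]


@dataclass(frozen=True)
class SQTerm:
    coeff: float
    elec: tuple  # (alpha, beta) meaning a^dag_alpha a_beta
    bos: tuple = ()  # ((mode, k, h), ...) strictly increasing in mode

    def conjugate_key(self):
        """Index signature of the Hermitian-conjugate term."""
        a, b = self.elec
        return ((b, a), tuple((i, h, k) for i, k, h in self.bos))

    def key(self):
        return (self.elec, self.bos)


@dataclass
class SQHamiltonian:
    """Term list plus the MPS lattice it acts on."""

    N_el: int
    M: int
    Ns: tuple
    terms: list = field(default_factory=list)

    def validate(self) -> None:
        for t in self.terms:
            a, b = t.elec
            if not (0 <= a < self.N_el and 0 <= b < self.N_el):
                raise ValueError(f"electronic index out of range in {t}")
            modes = [i for i, _, _ in t.bos]
            if modes != sorted(set(modes)):
                raise ValueError(f"bosonic modes must be strictly increasing in {t}")
            for i, k, h in t.bos:
                if not (0 <= i < self.M and 0 <= k < self.Ns[i] and 0 <= h < self.Ns[i]):
                    raise ValueError(f"bosonic index out of range in {t}")
            if not np.isfinite(t.coeff) or t.coeff == 0.0:
                raise ValueError(f"bad coefficient in {t}")

    def hermiticity_deviation(self) -> float:
        """Max |coeff - conj partner coeff| over all terms (0 = closed)."""
        lut = {t.key(): t.coeff for t in self.terms}
        dev = 0.0
        for t in self.terms:
            dev = max(dev, abs(t.coeff - lut.get(t.conjugate_key(), 0.0)))
        return dev

    # -- plain-text term-list interchange format ---------------------------

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            ns = ",".join(str(n) for n in self.Ns)
            fh.write(f"# vibromps-terms-v1 N_el={self.N_el} M={self.M} N={ns}\n")
            for t in self.terms:
                cols = [repr(t.coeff), str(t.elec[0]), str(t.elec[1])]
                for i, k, h in t.bos:
                    cols += [str(i), str(k), str(h)]
                fh.write("  ".join(cols) + "\n")

    @classmethod
    def from_file(cls, path) -> "SQHamiltonian":
        with open(path) as fh:
            header = fh.readline().split()
            if not header or header[1] != "vibromps-terms-v1":
                raise ValueError("not a vibromps term-list file")
            kv = dict(tok.split("=") for tok in header[2:])
            Ns = tuple(int(x) for x in kv["N"].split(",")) if kv["N"] else ()
            ham = cls(N_el=int(kv["N_el"]), M=int(kv["M"]), Ns=Ns)
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                tok = line.split()
                coeff = float(tok[0])
                elec = (int(tok[1]), int(tok[2]))
                rest = [int(x) for x in tok[3:]]
                bos = tuple(
                    (rest[p], rest[p + 1], rest[p + 2]) for p in range(0, len(rest), 3)
                )
                ham.terms.append(SQTerm(coeff, elec, bos))
        ham.validate()
        return ham


def assemble_hamiltonian(
    model: VibronicModel,
    bases: list[ModalBasis],
    tables: IntegralTable | None = None,
    screen: float = 1e-12,
) -> SQHamiltonian:
    """Build the second-quantized term list from integral tables.

    Entries with |coefficient| below ``screen`` (hartree) are dropped.  The
    result is closed under Hermitian conjugation by construction: one-body
    blocks are symmetric, couplings are emitted for both (alpha, beta) and
    (beta, alpha) with the same real table.
    """
    if tables is None:
        tables = compute_tables(model, bases)
    ham = SQHamiltonian(N_el=model.N_el, M=model.M, Ns=tables.Ns)

    def emit(coeff, elec, bos=()):
        if abs(coeff) > screen:
            ham.terms.append(SQTerm(float(coeff), elec, tuple(bos)))

    def emit_surface(surface_key, elec_pairs):
        c0 = tables.constants.get(surface_key, 0.0)
        for ab in elec_pairs:
            emit(c0, ab)
        for (key, i), blk in tables.onebody.items():
            if key != surface_key:
                continue
            for k in range(blk.shape[0]):
                for h in range(blk.shape[1]):
                    for ab in elec_pairs:
                        emit(blk[k, h], ab, [(i, k, h)])
        for (key, ij), blk in tables.twobody.items():
            if key != surface_key:
                continue
            i, j = ij
            Ni, Nj = blk.shape[0], blk.shape[1]
            for ki in range(Ni):
                for kj in range(Nj):
                    for hi in range(Ni):
                        for hj in range(Nj):
                            for ab in elec_pairs:
                                emit(
                                    blk[ki, kj, hi, hj],
                                    ab,
                                    [(i, ki, hi), (j, kj, hj)],
                                )

    for a in range(model.N_el):
        emit_surface(("d", a), [(a, a)])
    for (a, b) in model.offdiag:
        key = ("o", (a, b))
        if key not in tables.constants:
            raise ValueError(f"missing integral table for coupling {(a, b)}")
        emit_surface(key, [(a, b), (b, a)])

    ham.validate()
    return ham
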