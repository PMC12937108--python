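"""HDF5 containers for modal bases and MPS tensors (caching/checkpointing).

Versioned, portable dumps: a basis container stores grid, tabulated
functions, eigenvalues and the kinetic matrix; an MPS container stores the
lattice spec, per-bond charge sectors and all site tensors.
"""

from __future__ import annotations

import h5py
import numpy as np

from .basis import ModalBasis
from .mps import Lattice, VibronicMPS

__all__ = ["save_basis", "load_basis", "save_mps", "load_mps"]

_BASIS_VERSION = 1
_MPS_VERSION = 1


def save_basis(basis: ModalBasis, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "vibromps-basis"
        f.attrs["version"] = _BASIS_VERSION
        f.attrs["mode"] = basis.mode
        f.attrs["N"] = basis.N
        f.create_dataset("points", data=basis.points)
        f.create_dataset("weights", data=basis.weights)
        f.create_dataset("values", data=basis.values)
        f.create_dataset("kin", data=basis.kin)
        if basis.eigvals is not None:
            f.create_dataset("eigvals", data=basis.eigvals)
        for k, v in basis.meta.items():
            f.attrs[f"meta_{k}"] = v


def load_basis(path) -> ModalBasis:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "vibromps-basis":
            raise ValueError("not a vibromps basis container")
        meta = {
            k[5:]: (v.item() if isinstance(v, np.generic) else v)
            for k, v in f.attrs.items()
            if k.startswith("meta_")
        }
        return ModalBasis(
            mode=int(f.attrs["mode"]),
            N=int(f.attrs["N"]),
            points=f["points"][()],
            weights=f["weights"][()],
            values=f["values"][()],
            kin=f["kin"][()],
            eigvals=f["eigvals"][()] if "eigvals" in f else None,
            meta=meta,
        )


def save_mps(psi: VibronicMPS, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "vibromps-mps"
        f.attrs["version"] = _MPS_VERSION
        f.attrs["N_el"] = psi.lattice.N_el
        f.attrs["Ns"] = np.asarray(psi.lattice.Ns, dtype=np.int64)
        f.attrs["center"] = -1 if psi.center is None else psi.center
        for l, (t, q) in enumerate(zip(psi.tensors, psi.bond_q)):
            f.create_dataset(f"tensor_{l}", data=t)
            f.create_dataset(f"bond_q_{l}", data=q)
        f.create_dataset(f"bond_q_{psi.lattice.L}", data=psi.bond_q[-1])


def load_mps(path) -> VibronicMPS:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "vibromps-mps":
            raise ValueError("not a vibromps MPS container")
        lat = Lattice(int(f.attrs["N_el"]), tuple(int(x) for x in f.attrs["Ns"]))
        tensors = [f[f"tensor_{l}"][()] for l in range(lat.L)]
        bond_q = [f[f"bond_q_{l}"][()] for l in range(lat.L + 1)]
        center = int(f.attrs["center"])
        return VibronicMPS(lat, tensors, bond_q, None if center < 0 else center)
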