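"""End-to-end workflows: configuration, staged artifacts, determinism.

The pipeline runs bases -> integrals -> term list -> MPO -> Condon initial
state -> TDVP propagation -> observables, writing every stage to the output
directory (term list as plain text, records and spectra as CSV, run
metadata as JSON, MPS checkpoints as HDF5).  Reruns with an identical
configuration are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .basis import ModalBasis, default_bounds, relaxed_basis
from .integrals import compute_tables
from .mpo import compile_mpo
from .mps import Lattice
from .nmode import Poly1, VibronicModel, load_model
from .observables import absorption_spectrum, condon_initial_state
from .oracle import build_dense, dense_propagate
from .sqham import SQHamiltonian, assemble_hamiltonian
from .tdvp import propagate
from .units import fs_to_au

__all__ = ["RunConfig", "run_pipeline", "ground_state_bases"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated settings of an end-to-end run."""

    model_file: str
    basis_size: int = 8
    basis_points: int = 401
    basis_turning: float = 7.0
    dt_fs: float = 0.5
    n_steps: int = 800
    m_max: int | None = None
    cutoff: float = 1e-12
    target_state: int = 1
    condon: bool = True
    outdir: str = "run_out"
    checkpoint_every: int = 0
    shift: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.model_file).exists():
            raise ConfigError(f"model file {self.model_file!r} does not exist")
        if self.basis_size < 1 or self.basis_points < 16:
            raise ConfigError("basis_size >= 1 and basis_points >= 16 required")
        if self.dt_fs <= 0 or self.n_steps < 1:
            raise ConfigError("need positive dt_fs and n_steps >= 1")
        if self.m_max is not None and self.m_max < 1:
            raise ConfigError("m_max must be positive when given")
        if not self.condon:
            raise ConfigError("only Condon excitation is implemented")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        extra = set(doc) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def ground_state_bases(
    model: VibronicModel,
    N: int,
    n_points: int = 401,
    n_turning: float = 7.0,
) -> list[ModalBasis]:
    """Relaxed modal bases from the electronic ground state (state 0).

    For every mode the 1D Hamiltonian is the mode's kinetic operator plus
    the ground-state one-body potential term (harmonic at the reference
    frequency when the surface stores no term for that mode); its lowest N
    eigenfunctions form the basis, so the Condon wavepacket is the
    occupation-zero product state.
    """
    bases = []
    ground = model.diag[0]
    for i in range(model.M):
        w = model.frequencies[i]
        v1 = ground.F1.get(i, Poly1([0.0, 0.0, 0.5 * w**2]))
        lo, hi = default_bounds(w, n_turning)
        bases.append(
            relaxed_basis(
                v1,
                N,
                lo,
                hi,
                n_points=n_points,
                mode=i,
                kinetic_coeff=float(model.kinetic_coeff[i]),
            )
        )
    return bases


def _stage_hamiltonian(cfg: RunConfig, outdir: Path):
    model = load_model(cfg.model_file)
    bases = ground_state_bases(
        model, cfg.basis_size, cfg.basis_points, cfg.basis_turning
    )
    tables = compute_tables(model, bases)
    ham = assemble_hamiltonian(model, bases, tables)
    ham.to_file(outdir / "terms.txt")
    return model, bases, ham


def run_pipeline(cfg: RunConfig) -> dict:
    """Deterministic end-to-end run; returns a dict of artifact paths and
    headline numbers (final populations, spectral maximum)."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model, bases, ham = _stage_hamiltonian(cfg, outdir)
    if not (0 <= cfg.target_state < model.N_el):
        raise ConfigError("target state out of range")
    mpo = compile_mpo(ham)
    lat = Lattice.from_sqham(ham)
    psi0, _scale = condon_initial_state(lat, cfg.target_state)

    callback = None
    if cfg.checkpoint_every > 0:
        from .serialize import save_mps

        def callback(step, psi):
            if step % cfg.checkpoint_every == 0:
                save_mps(psi, outdir / "checkpoint.h5")

    record, psi = propagate(
        psi0,
        mpo,
        cfg.dt_fs,
        cfg.n_steps,
        m_max=cfg.m_max,
        cutoff=cfg.cutoff,
        callback=callback,
    )
    record.to_csv(outdir / "record.csv")
    spec = absorption_spectrum(record.times_fs, record.autocorr, shift=cfg.shift)
    spec.to_csv(outdir / "spectrum.csv")
    meta = {
        "config": asdict(cfg),
        "lattice": {"N_el": lat.N_el, "Ns": list(lat.Ns)},
        "n_terms": len(ham.terms),
        "mpo_bond_dims": mpo.bond_dims(),
        "max_bond": int(np.max(record.max_bond_post)),
        "final_norm": float(record.norms[-1]),
        "final_populations": record.populations[-1].tolist(),
        "discarded_total": float(record.discarded_cum[-1]),
    }
    with open(outdir / "run.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return {
        "terms": str(outdir / "terms.txt"),
        "record": str(outdir / "record.csv"),
        "spectrum": str(outdir / "spectrum.csv"),
        "meta": str(outdir / "run.json"),
        "record_obj": record,
        "spectrum_obj": spec,
    }


def run_oracle(cfg: RunConfig, cap: int = 20_000) -> dict:
    """Exact dense reference run with the same staged inputs (diff target)."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model, bases, ham = _stage_hamiltonian(cfg, outdir)
    sys = build_dense(ham, cap=cap)
    v0 = np.zeros(sys.D, dtype=complex)
    v0[sys.state_index(cfg.target_state, (0,) * model.M)] = 1.0
    times_fs = cfg.dt_fs * np.arange(cfg.n_steps + 1)
    _, C, pops = dense_propagate(sys, v0, fs_to_au(times_fs))
    import pandas as pd

    df = pd.DataFrame({"t_fs": times_fs, "re_C": C.real, "im_C": C.imag})
    for g in range(sys.N_el):
        df[f"pop_{g}"] = pops[:, g]
    df.to_csv(outdir / "oracle_record.csv", index=False)
    return {"record": str(outdir / "oracle_record.csv"), "C": C, "pops": pops}
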