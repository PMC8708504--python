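"""Readers/writers, configuration and run manifests.

Interchange formats are all plain text except the ``.npz`` frame store used
for exact restarts: extended XYZ for configurations, a LAMMPS-data-like file
for bonded topology, TSV for observable logs, YAML for configs and JSON for
manifests.  Coordinates are stored wrapped; unwrapping is an analysis-time
operation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model import (SPECIES_CODES, SPECIES_NAMES, BeadState, Box, ConfigError,
                    SimulationParams, Topology, TrajectoryFrame,
                    default_a_matrix)


class FrameParseError(ValueError):
    """Raised for malformed or truncated trajectory files."""


# ---------------------------------------------------------------- extended XYZ

def write_xyz(frame: TrajectoryFrame, path: str | Path,
              append: bool = False, comment_extra: str = "") -> None:
    """Write one frame in extended-XYZ with velocities and molecule ids."""
    state = frame.state
    L = state.box.edge_length
    header = (
        f'Lattice="{L} 0 0 0 {L} 0 0 0 {L}" '
        'Properties=species:S:1:pos:R:3:vel:R:3:mol:I:1 '
        f'step={frame.step}'
    )
    if comment_extra:
        header += " " + comment_extra
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(f"{state.n_beads}\n{header}\n")
        for k in range(state.n_beads):
            x, y, z = state.positions[k]
            vx, vy, vz = state.velocities[k]
            fh.write(f"{SPECIES_NAMES[state.species[k]]} "
                     f"{x:.10g} {y:.10g} {z:.10g} "
                     f"{vx:.10g} {vy:.10g} {vz:.10g} "
                     f"{int(state.molecule_id[k])}\n")


def read_xyz(path: str | Path) -> TrajectoryFrame:
    """Read the first frame of an extended-XYZ file written by write_xyz."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FrameParseError(f"{path}: empty file")
    try:
        n = int(lines[0])
    except ValueError as exc:
        raise FrameParseError(f"{path}: line 1 is not a bead count") from exc
    if len(lines) < n + 2:
        raise FrameParseError(
            f"{path}: truncated — header promises {n} beads, "
            f"file holds {len(lines) - 2} records")
    header = lines[1]
    L = None
    step = 0
    for tok in header.replace('"', " ").split():
        if tok.startswith("step="):
            step = int(tok[5:])
    if "Lattice=" in header:
        nums = header.split('Lattice=')[1].replace('"', ' ').split()
        L = float(nums[0])
    if L is None:
        raise FrameParseError(f"{path}: no Lattice in header")
    pos = np.empty((n, 3))
    vel = np.empty((n, 3))
    species = np.empty(n, dtype=np.int8)
    mol = np.empty(n, dtype=np.int32)
    for k in range(n):
        parts = lines[2 + k].split()
        if len(parts) != 8:
            raise FrameParseError(f"{path}: record {k + 1} has "
                                  f"{len(parts)} fields, expected 8")
        species[k] = SPECIES_CODES[parts[0]]
        pos[k] = [float(v) for v in parts[1:4]]
        vel[k] = [float(v) for v in parts[4:7]]
        mol[k] = int(parts[7])
    state = BeadState(positions=pos, velocities=vel, species=species,
                      molecule_id=mol, box=Box(L))
    return TrajectoryFrame(step=step, state=state)


# ------------------------------------------------------------ binary frame store

def write_frame(frame: TrajectoryFrame, path: str | Path) -> None:
    """Write a frame; format chosen by extension (.xyz text, .npz binary).

    The binary store keeps forces, so a run restarted from it continues
    bit-identically.
    """
    path = Path(path)
    if path.suffix == ".xyz":
        write_xyz(frame, path)
        return
    state = frame.state
    arrays = dict(step=np.int64(frame.step), L=np.float64(state.box.edge_length),
                  positions=state.positions, velocities=state.velocities,
                  species=state.species, molecule_id=state.molecule_id)
    if state.forces is not None:
        arrays["forces"] = state.forces
    if state.tags is not None:
        arrays["tags"] = state.tags
    np.savez(path, **arrays)


def read_frame(path: str | Path) -> TrajectoryFrame:
    path = Path(path)
    if path.suffix == ".xyz":
        return read_xyz(path)
    try:
        data = np.load(path)
        state = BeadState(
            positions=data["positions"], velocities=data["velocities"],
            species=data["species"], molecule_id=data["molecule_id"],
            box=Box(float(data["L"])),
            forces=data["forces"] if "forces" in data else None,
            tags=data["tags"] if "tags" in data else None)
        return TrajectoryFrame(step=int(data["step"]), state=state)
    except (KeyError, OSError, ValueError) as exc:
        raise FrameParseError(f"{path}: {exc}") from exc


# ------------------------------------------------------- LAMMPS-like topology

def write_topology(topology: Topology, state: BeadState, path: str | Path) -> None:
    """Bonded topology in a LAMMPS-data-like format (atoms + bonds sections)."""
    L = state.box.edge_length
    with open(path, "w") as fh:
        fh.write("# star-terpolymer DPD topology\n\n")
        fh.write(f"{state.n_beads} atoms\n{len(topology.bonds)} bonds\n")
        fh.write(f"{len(SPECIES_NAMES)} atom types\n1 bond types\n\n")
        for lo, hi in (("xlo xhi", L), ("ylo yhi", L), ("zlo zhi", L)):
            fh.write(f"0.0 {hi} {lo}\n")
        fh.write("\nAtoms\n\n")
        for k in range(state.n_beads):
            x, y, z = state.positions[k]
            fh.write(f"{k + 1} {int(state.molecule_id[k]) + 1} "
                     f"{int(state.species[k]) + 1} {x:.10g} {y:.10g} {z:.10g}\n")
        fh.write("\nBonds\n\n")
        for b, (i, j) in enumerate(topology.bonds):
            fh.write(f"{b + 1} 1 {i + 1} {j + 1}\n")


# ----------------------------------------------------------------- run config

#: Published-run defaults; anything not overridden in a config file takes these.
CONFIG_DEFAULTS = {
    "box_length": 40.0,
    "fp": 0.10,
    "a_ES": 97.9,
    "a_FS": 125.0,
    "gamma": 4.5,
    "dt": 0.04,
    "spring_C": 4.0,
    "kBT": 1.0,
    "rho": 3.0,
    "steps": 500_000,
    "snapshot_every": 10_000,
    "seed": 0,
}

_KNOWN_KEYS = set(CONFIG_DEFAULTS) | {"a_matrix", "sigma", "experiment"}


def load_config(path: str | Path) -> tuple[dict, SimulationParams]:
    """Read a YAML run config; unknown keys and inconsistencies are errors.

    Returns (run settings dict, SimulationParams).  An empty file yields the
    default interaction table and integration constants.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = {**CONFIG_DEFAULTS, **raw}
    if cfg["dt"] <= 0:
        raise ConfigError(f"{path}: timestep must be positive, got {cfg['dt']}")
    if not 0 < cfg["fp"] < 1:
        raise ConfigError(f"{path}: fp must be in (0, 1)")
    if "a_matrix" in raw:
        a = np.asarray(raw["a_matrix"], dtype=float)
        if a.shape != (4, 4) or not np.allclose(a, a.T):
            raise ConfigError(f"{path}: a_matrix must be a symmetric 4x4 table")
    else:
        a = default_a_matrix(a_ES=cfg["a_ES"], a_FS=cfg["a_FS"])
    params = SimulationParams(a_matrix=a, gamma=cfg["gamma"], dt=cfg["dt"],
                              spring_C=cfg["spring_C"], kBT=cfg["kBT"],
                              rho=cfg["rho"], seed=int(cfg["seed"]))
    if "sigma" in raw and not np.isclose(raw["sigma"], params.sigma):
        raise ConfigError(
            f"{path}: sigma={raw['sigma']} violates sigma^2 = 2 gamma kBT "
            f"(expected {params.sigma})")
    return cfg, params


# ---------------------------------------------------------------- run manifest

@dataclass
class RunManifest:
    """Parameter echo + file index; sufficient to re-run or re-analyse."""

    kind: str
    seed: int
    config: dict
    frames: list[str] = field(default_factory=list)
    observable_log: str | None = None
    code_version: str = "stardpd 0.1.0"

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
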