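"""Domain types and system construction for star-terpolymer DPD simulations.

The model is a coarse-grained miktoarm star terpolymer E12O6F2: three linear
arms of 12 E beads, 6 O beads and 2 F beads joined at a single junction.  E
and F are solvophobic, O is solvophilic, S is solvent.  All beads have unit
mass and interact within the cutoff radius rc; reduced units rc = m = kBT = 1
define the length, mass and energy scales of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

# Species codes used throughout the package (index into the a-matrix).
SPECIES_E = 0
SPECIES_O = 1
SPECIES_F = 2
SPECIES_S = 3
SPECIES_NAMES = ("E", "O", "F", "S")
SPECIES_CODES = {name: code for code, name in enumerate(SPECIES_NAMES)}

#: molecule_id assigned to solvent beads
SOLVENT_MOL_ID = -1

#: Diagonal (like–like) repulsion amplitude at reduced density rho = 3.
A_LIKE = 25.0

#: Fixed off-diagonal repulsion amplitudes between polymer blocks and the
#: O–solvent pair.  E–solvent and F–solvent are the control parameters of the
#: morphology diagram (aES in [26, 97.9], aFS in [26, 125]) and default to
#: their maximal, most solvophobic values used in the formation runs.
A_EO = 38.5
A_EF = 78.0
A_OF = 89.4
A_OS = 26.0
A_ES_DEFAULT = 97.9
A_FS_DEFAULT = 125.0


def default_a_matrix(a_ES: float = A_ES_DEFAULT, a_FS: float = A_FS_DEFAULT) -> np.ndarray:
    """Return the 4x4 symmetric repulsion-amplitude matrix (order E, O, F, S)."""
    a = np.full((4, 4), A_LIKE, dtype=np.float64)
    pairs = {
        (SPECIES_E, SPECIES_O): A_EO,
        (SPECIES_E, SPECIES_F): A_EF,
        (SPECIES_O, SPECIES_F): A_OF,
        (SPECIES_O, SPECIES_S): A_OS,
        (SPECIES_E, SPECIES_S): a_ES,
        (SPECIES_F, SPECIES_S): a_FS,
    }
    for (i, j), val in pairs.items():
        a[i, j] = a[j, i] = val
    return a


class InvalidArchitectureError(ValueError):
    """Raised for a star-polymer arm specification that cannot be built."""


class ConfigError(ValueError):
    """Raised for invalid or inconsistent simulation parameters."""


@dataclass
class SimulationParams:
    """Force-field and integration constants in reduced DPD units.

    sigma is never supplied: the fluctuation–dissipation relation
    sigma^2 = 2 gamma kBT fixes it, and the constructor derives it.
    """

    a_matrix: np.ndarray = field(default_factory=default_a_matrix)
    gamma: float = 4.5
    r_cut: float = 1.0
    spring_C: float = 4.0
    dt: float = 0.04
    kBT: float = 1.0
    rho: float = 3.0
    bead_mass: float = 1.0
    seed: int = 0
    sigma: float = field(init=False)

    def __post_init__(self) -> None:
        self.a_matrix = np.asarray(self.a_matrix, dtype=np.float64)
        if self.a_matrix.shape != (4, 4):
            raise ConfigError(f"a_matrix must be 4x4, got {self.a_matrix.shape}")
        if not np.allclose(self.a_matrix, self.a_matrix.T):
            raise ConfigError("a_matrix must be symmetric")
        if self.dt <= 0:
            raise ConfigError(f"timestep must be positive, got {self.dt}")
        if self.gamma < 0 or self.kBT <= 0:
            raise ConfigError("gamma must be >= 0 and kBT > 0")
        # fluctuation–dissipation: sigma^2 = 2 gamma kBT
        self.sigma = float(np.sqrt(2.0 * self.gamma * self.kBT))

    def with_overrides(self, a_ES: float | None = None, a_FS: float | None = None,
                       **kwargs) -> "SimulationParams":
        """Copy of the parameter set with E–S / F–S amplitudes replaced."""
        a = self.a_matrix.copy()
        if a_ES is not None:
            a[SPECIES_E, SPECIES_S] = a[SPECIES_S, SPECIES_E] = a_ES
        if a_FS is not None:
            a[SPECIES_F, SPECIES_S] = a[SPECIES_S, SPECIES_F] = a_FS
        return replace(self, a_matrix=a, **kwargs)


@dataclass(frozen=True)
class Box:
    """Periodic cubic simulation box with edge length in rc units."""

    edge_length: float
    periodic: bool = True

    def __post_init__(self) -> None:
        if self.edge_length <= 2.0:
            raise ConfigError(
                f"box edge {self.edge_length} must exceed 2*r_cut for minimum image"
            )

    @property
    def volume(self) -> float:
        return self.edge_length ** 3


@dataclass
class Topology:
    """Bond list and per-molecule structure of the polymer component.

    ``bonds`` is an (n_bonds, 2) integer array of bead indices.  ``molecules``
    lists (start, stop) bead-index ranges, one per molecule; within a molecule
    beads are laid out arm by arm (E arm first; its first bead is the hub).
    """

    bonds: np.ndarray
    molecules: list[tuple[int, int]]
    arm_lengths: tuple[int, int, int] = (12, 6, 2)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def beads_per_molecule(self) -> int:
        return int(sum(self.arm_lengths))


@dataclass
class BeadState:
    """Mutable particle state: wrapped positions, velocities, labels.

    ``tags`` is a free per-bead integer channel used for provenance tracking
    (e.g. two-colour labelling of the two vesicles in a fusion run).
    """

    positions: np.ndarray
    velocities: np.ndarray
    species: np.ndarray
    molecule_id: np.ndarray
    box: Box
    forces: np.ndarray | None = None
    tags: np.ndarray | None = None

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "BeadState":
        return BeadState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            species=self.species.copy(),
            molecule_id=self.molecule_id.copy(),
            box=self.box,
            forces=None if self.forces is None else self.forces.copy(),
            tags=None if self.tags is None else self.tags.copy(),
        )

    def polymer_mask(self) -> np.ndarray:
        return self.species != SPECIES_S


@dataclass
class TrajectoryFrame:
    """A timestamped snapshot plus logged observables."""

    step: int
    state: BeadState
    observables: dict = field(default_factory=dict)


def build_star_molecule(arm_lengths: Sequence[int] = (12, 6, 2)) -> tuple[np.ndarray, np.ndarray]:
    """Construct one star molecule as (species codes, local bond list).

    Each arm is a linear chain; the first bead of arm 0 (the E arm) is the
    junction hub, and the first beads of the other arms bond directly to it.
    For the default (12, 6, 2) architecture this yields 20 beads and 19 bonds.
    """
    arm_lengths = tuple(int(n) for n in arm_lengths)
    if len(arm_lengths) != 3 or any(n < 1 for n in arm_lengths):
        raise InvalidArchitectureError(
            f"need three arms of length >= 1, got {arm_lengths}"
        )
    n_e, n_o, n_f = arm_lengths
    species = np.concatenate([
        np.full(n_e, SPECIES_E, dtype=np.int8),
        np.full(n_o, SPECIES_O, dtype=np.int8),
        np.full(n_f, SPECIES_F, dtype=np.int8),
    ])
    bonds = []
    offsets = np.cumsum([0, n_e, n_o])
    for off, n in zip(offsets, arm_lengths):
        bonds.extend((off + k, off + k + 1) for k in range(n - 1))
    # junction: first O bead and first F bead bond to the first E bead (hub)
    bonds.append((0, offsets[1]))
    bonds.append((0, offsets[2]))
    return species, np.asarray(bonds, dtype=np.int64)


def maxwell_boltzmann_velocities(n: int, kBT: float, mass: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """Velocities from the Maxwell–Boltzmann distribution, COM drift removed."""
    v = rng.normal(0.0, np.sqrt(kBT / mass), size=(n, 3))
    v -= v.mean(axis=0)
    return v


def initialize_system(box: Box, fp: float, params: SimulationParams,
                      seed: int | None = None,
                      arm_lengths: Sequence[int] = (12, 6, 2),
                      ) -> tuple[BeadState, Topology]:
    """Random initial configuration at number density rho and polymer volume
    fraction ``fp``.

    ``fp`` is the fraction of all beads that are polymer beads (all beads have
    the same volume, so bead fraction equals volume fraction).  Molecules are
    grown as compact random walks with bonded-neighbour spacing 0.8 rc from
    uniformly random anchors; the zero-rest-length springs admit any bounded
    initial bond length.  Velocities are Maxwell–Boltzmann at kBT with the
    total momentum shifted to exactly zero.
    """
    if not 0.0 < fp < 1.0:
        raise ConfigError(f"polymer volume fraction must be in (0, 1), got {fp}")
    L = box.edge_length
    mol_species, mol_bonds = build_star_molecule(arm_lengths)
    bpm = len(mol_species)
    # a compact random-walk arm has RMS extent ~0.8*sqrt(arm length) rc;
    # require it to fit in half the box so the initial coil is not self-imaged
    if L < 2.0 * 0.8 * np.sqrt(max(arm_lengths)):
        raise ConfigError(f"box edge {L} too small for one molecule")

    n_total = int(round(params.rho * L ** 3))
    n_molecules = int(round(fp * n_total / bpm))
    if n_molecules < 1:
        raise ConfigError(f"fp={fp} gives zero molecules at L={L}")
    n_poly = n_molecules * bpm
    if n_poly > n_total:
        raise ConfigError("polymer beads exceed total bead budget")

    rng = np.random.default_rng(params.seed if seed is None else seed)
    positions = np.empty((n_total, 3), dtype=np.float64)
    species = np.empty(n_total, dtype=np.int8)
    molecule_id = np.empty(n_total, dtype=np.int32)

    bond_step = 0.8 * params.r_cut
    n_e, n_o, _ = (int(a) for a in arm_lengths)
    molecules = []
    bonds = []
    for m in range(n_molecules):
        base = m * bpm
        hub = rng.uniform(0.0, L, size=3)
        coords = np.empty((bpm, 3))
        # grow each arm as a random walk from the hub
        for off, n_arm in zip(np.cumsum([0, n_e, n_o]), arm_lengths):
            prev = hub
            for k in range(n_arm):
                if off == 0 and k == 0:
                    coords[0] = hub
                    continue
                step_dir = rng.normal(size=3)
                step_dir /= np.linalg.norm(step_dir)
                coords[off + k] = prev + bond_step * step_dir
                prev = coords[off + k]
            # non-E arms start their walk from the hub again
        positions[base:base + bpm] = coords
        species[base:base + bpm] = mol_species
        molecule_id[base:base + bpm] = m
        molecules.append((base, base + bpm))
        bonds.append(mol_bonds + base)

    n_solvent = n_total - n_poly
    positions[n_poly:] = rng.uniform(0.0, L, size=(n_solvent, 3))
    species[n_poly:] = SPECIES_S
    molecule_id[n_poly:] = SOLVENT_MOL_ID
    positions %= L

    velocities = maxwell_boltzmann_velocities(n_total, params.kBT, params.bead_mass, rng)

    topology = Topology(
        bonds=np.concatenate(bonds) if bonds else np.empty((0, 2), dtype=np.int64),
        molecules=molecules,
        arm_lengths=tuple(int(a) for a in arm_lengths),
    )
    state = BeadState(positions=positions, velocities=velocities, species=species,
                      molecule_id=molecule_id, box=box)
    return state, topology
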