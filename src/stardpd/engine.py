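"""DPD force field, thermostat and integrator (public API over the kernels).

The force on bead i is the sum of four pairwise contributions within the
cutoff rc:

* conservative soft repulsion  F_C = a_ij (1 - r/rc) r_hat,
* dissipative drag             F_D = -gamma (1 - r/rc)^2 (v_ij . r_hat) r_hat,
* random kicks                 F_R = sigma (1 - r/rc) xi_ij dt^(-1/2) r_hat,
* harmonic bonds               F_S = -C r_ij  (zero rest length).

F_D and F_R together form the pairwise Groot–Warren thermostat; the
fluctuation–dissipation relation sigma^2 = 2 gamma kBT and the weight-function
relation omega_D = omega_R^2 are built in.  All pair terms are antisymmetric,
so total momentum is conserved to rounding error.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from . import _kernels
from .model import BeadState, SimulationParams, Topology

logger = logging.getLogger(__name__)

#: Groot–Warren linear coefficient between the Flory–Huggins chi parameter and
#: the excess repulsion amplitude at reduced density rho = 3.
CHI_COEFF = 3.27

_EMPTY_BONDS = np.empty((0, 2), dtype=np.int64)


class IntegrationBlowupError(RuntimeError):
    """Raised when the integrator produces non-finite coordinates/velocities."""


def chi_to_a(chi: float, a_ii: float = 25.0) -> float:
    """Map a Flory–Huggins chi parameter to a DPD repulsion amplitude."""
    if a_ii <= 0:
        raise ValueError("a_ii must be positive")
    return a_ii + CHI_COEFF * chi


def a_to_chi(aij: float, a_ii: float = 25.0) -> float:
    """Inverse of :func:`chi_to_a`."""
    if a_ii <= 0:
        raise ValueError("a_ii must be positive")
    return (aij - a_ii) / CHI_COEFF


def conservative_force(rij: np.ndarray, aij: float, r_cut: float = 1.0) -> np.ndarray:
    """Soft repulsion a_ij (1 - r/rc) r_hat for one separation vector."""
    rij = np.asarray(rij, dtype=np.float64)
    r = np.linalg.norm(rij)
    if r >= r_cut:
        return np.zeros(3)
    if r == 0.0:
        warnings.warn("exact bead overlap: conservative force undefined, "
                      "returning zero", RuntimeWarning, stacklevel=2)
        return np.zeros(3)
    return aij * (1.0 - r / r_cut) * rij / r


def dissipative_random_forces(rij: np.ndarray, vij: np.ndarray,
                              params: SimulationParams,
                              xi: float) -> tuple[np.ndarray, np.ndarray]:
    """Thermostat pair forces for a given unit-variance noise variate xi."""
    rij = np.asarray(rij, dtype=np.float64)
    vij = np.asarray(vij, dtype=np.float64)
    r = np.linalg.norm(rij)
    rc = params.r_cut
    if r >= rc or r == 0.0:
        return np.zeros(3), np.zeros(3)
    e = rij / r
    w = 1.0 - r / rc
    f_d = -params.gamma * w * w * float(vij @ e) * e
    f_r = params.sigma * w * xi / np.sqrt(params.dt) * e
    return f_d, f_r


def spring_force(topology: Topology, positions: np.ndarray, spring_C: float,
                 L: float) -> np.ndarray:
    """Per-bead bond forces from zero-rest-length harmonic springs."""
    forces = np.zeros_like(positions)
    _kernels.bond_forces(positions, topology.bonds, spring_C, L, forces)
    return forces


def pair_noise(seed: int, step: int, i: int, j: int) -> float:
    """The symmetric per-pair noise variate used by both force paths."""
    lo, hi = (i, j) if i < j else (j, i)
    return _kernels.pair_noise(seed, step, lo, hi)


def compute_forces(state: BeadState, topology: Topology | None,
                   params: SimulationParams, step_index: int,
                   method: str = "cells") -> np.ndarray:
    """All forces on every bead at noise key ``step_index``.

    ``method`` selects the cell-list path ("cells") or the O(N^2) all-pairs
    oracle ("bruteforce"); both consume the identical per-pair noise stream.
    """
    forces = np.zeros_like(state.positions)
    fn = {"cells": _kernels.nonbonded_forces_cells,
          "bruteforce": _kernels.nonbonded_forces_bruteforce}[method]
    fn(state.positions, state.velocities, state.species, params.a_matrix,
       params.gamma, params.sigma, params.r_cut, state.box.edge_length,
       params.dt, params.seed, step_index, forces)
    bonds = topology.bonds if topology is not None else _EMPTY_BONDS
    if bonds.shape[0] > 0:
        _kernels.bond_forces(state.positions, bonds, params.spring_C,
                             state.box.edge_length, forces)
    return forces


def measure_temperature(state: BeadState, mass: float = 1.0) -> float:
    """Kinetic temperature sum(m v^2) / (3N - 3), COM motion removed."""
    v = state.velocities - state.velocities.mean(axis=0)
    n = state.n_beads
    if n < 2:
        raise ValueError("temperature undefined for fewer than 2 beads")
    return float(mass * np.sum(v * v) / (3.0 * n - 3.0))


def total_momentum(state: BeadState, mass: float = 1.0) -> np.ndarray:
    return mass * state.velocities.sum(axis=0)


def step(state: BeadState, topology: Topology | None, params: SimulationParams,
         step_index: int) -> None:
    """Advance the state by one timestep in place.

    ``state.forces`` must hold forces at noise key ``step_index`` (computed by
    :func:`compute_forces` on first use); the updated forces are stored back.
    """
    if state.forces is None:
        state.forces = compute_forces(state, topology, params, step_index)
    bonds = topology.bonds if topology is not None else _EMPTY_BONDS
    _kernels.step_kernel(state.positions, state.velocities, state.forces,
                         state.species, bonds, params.a_matrix, params.gamma,
                         params.sigma, params.r_cut, state.box.edge_length,
                         params.dt, params.bead_mass, params.spring_C,
                         params.seed, step_index)
    if not np.isfinite(state.positions).all() or not np.isfinite(state.velocities).all():
        raise IntegrationBlowupError(
            f"non-finite coordinates or velocities after step {step_index + 1}"
        )


def run(state: BeadState, topology: Topology | None, params: SimulationParams,
        n_steps: int, step_offset: int = 0, log_every: int = 100):
    """Advance ``n_steps`` steps in a single compiled loop.

    Returns a dict of logged observables (step, kinetic temperature, |total
    momentum|).  Raises :class:`IntegrationBlowupError` on divergence.  The
    trajectory is a pure function of (initial state, params.seed,
    step_offset), so a run can be restarted from any snapshot that carries
    positions, velocities and forces.
    """
    if state.forces is None:
        state.forces = compute_forces(state, topology, params, step_offset)
    bonds = topology.bonds if topology is not None else _EMPTY_BONDS
    log_steps, log_temp, log_mom, blowup = _kernels.run_kernel(
        state.positions, state.velocities, state.forces, state.species, bonds,
        params.a_matrix, params.gamma, params.sigma, params.r_cut,
        state.box.edge_length, params.dt, params.bead_mass, params.spring_C,
        params.seed, step_offset, n_steps, log_every)
    if blowup >= 0:
        raise IntegrationBlowupError(f"integration blew up at step {blowup}")
    return {"step": log_steps, "temperature": log_temp, "momentum": log_mom}
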