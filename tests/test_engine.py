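"""Force field, thermostat, noise stream and integrator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stardpd import engine
from stardpd.model import (Box, BeadState, SOLVENT_MOL_ID, SPECIES_S,
                           SimulationParams, Topology, initialize_system,
                           maxwell_boltzmann_velocities)


def _free_params(seed=0):
    """Parameter set with all interactions off (ideal gas, no thermostat)."""
    return SimulationParams(a_matrix=np.zeros((4, 4)), gamma=0.0, seed=seed)


# ------------------------------------------------------------------ pair terms

def test_conservative_force_vanishes_at_cutoff():
    f = engine.conservative_force(np.array([1.0, 0.0, 0.0]), aij=25.0)
    assert np.allclose(f, 0.0)
    # continuity: just inside the cutoff the magnitude is ~0
    f_in = engine.conservative_force(np.array([1.0 - 1e-8, 0.0, 0.0]), aij=25.0)
    assert np.linalg.norm(f_in) < 1e-6


def test_conservative_force_maximum_repulsion():
    f = engine.conservative_force(np.array([1e-9, 0.0, 0.0]), aij=25.0)
    assert np.linalg.norm(f) == pytest.approx(25.0, rel=1e-6)


def test_conservative_force_midpoint():
    f = engine.conservative_force(np.array([0.5, 0.0, 0.0]), aij=78.0)
    assert np.linalg.norm(f) == pytest.approx(39.0)
    assert f[0] > 0  # repulsive, along r_ij


def test_conservative_force_overlap_warns():
    with pytest.warns(RuntimeWarning):
        f = engine.conservative_force(np.zeros(3), aij=25.0)
    assert np.allclose(f, 0.0)


def test_dissipative_force_zero_for_tangential_motion(default_params):
    rij = np.array([0.5, 0.0, 0.0])
    vij = np.array([0.0, 1.3, -0.7])  # no radial component
    f_d, _ = engine.dissipative_random_forces(rij, vij, default_params, xi=0.4)
    assert np.allclose(f_d, 0.0)


def test_thermostat_forces_vanish_at_cutoff(default_params):
    f_d, f_r = engine.dissipative_random_forces(
        np.array([1.0, 0, 0]), np.array([1.0, 0, 0]), default_params, xi=1.0)
    assert np.allclose(f_d, 0.0)
    assert np.allclose(f_r, 0.0)


def test_random_force_variance_matches_closed_form(default_params):
    """Var(|F_R|) over the noise stream equals sigma^2 w(r)^2 / dt."""
    p = default_params
    rij = np.array([0.6, 0.0, 0.0])
    mags = []
    for s in range(20000):
        xi = engine.pair_noise(p.seed, s, 3, 7)
        _, f_r = engine.dissipative_random_forces(rij, np.zeros(3), p, xi)
        mags.append(f_r[0])
    w = 1.0 - 0.6
    expected = p.sigma**2 * w**2 / p.dt
    assert np.var(mags) == pytest.approx(expected, rel=0.05)
    assert np.mean(mags) == pytest.approx(0.0, abs=0.1)


def test_pair_noise_symmetric_and_standardized():
    draws = np.array([engine.pair_noise(5, s, 10, 42) for s in range(50000)])
    assert abs(draws.mean()) < 0.02
    assert np.var(draws) == pytest.approx(1.0, rel=0.02)
    assert engine.pair_noise(5, 17, 10, 42) == engine.pair_noise(5, 17, 42, 10)


def test_spring_force_values(default_params):
    topo = Topology(bonds=np.array([[0, 1]]), molecules=[(0, 2)])
    pos = np.array([[1.0, 1.0, 1.0], [1.5, 1.0, 1.0]])
    f = engine.spring_force(topo, pos, spring_C=4.0, L=10.0)
    # magnitude C*r toward the partner; bond forces sum to zero
    assert f[0, 0] == pytest.approx(2.0)
    assert f[1, 0] == pytest.approx(-2.0)
    np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-14)
    # zero extension -> zero force
    f0 = engine.spring_force(topo, np.ones((2, 3)), 4.0, 10.0)
    assert np.allclose(f0, 0.0)


# ------------------------------------------------------------------ chi mapping

def test_chi_mapping_examples():
    assert engine.chi_to_a(0.0, 25.0) == pytest.approx(25.0)
    assert engine.a_to_chi(38.5, 25.0) == pytest.approx(13.5 / 3.27)


@given(chi=st.floats(-10, 100), a_ii=st.floats(1.0, 50.0))
@settings(deadline=None, max_examples=50, derandomize=True)
def test_chi_roundtrip(chi, a_ii):
    assert engine.a_to_chi(engine.chi_to_a(chi, a_ii), a_ii) == pytest.approx(
        chi, abs=1e-9)


# ------------------------------------------------------------------ integrator

def test_pure_drift_without_forces():
    """With all interactions off, beads drift in straight lines mod L."""
    L = 10.0
    pos = np.array([[1.0, 2.0, 3.0], [9.5, 5.0, 5.0]])
    vel = np.array([[1.0, 0.0, 0.0], [25.0, 0.0, 0.0]])
    state = BeadState(pos.copy(), vel.copy(), np.full(2, SPECIES_S, np.int8),
                      np.full(2, SOLVENT_MOL_ID, np.int32), Box(L))
    params = _free_params()
    for s in range(10):
        engine.step(state, None, params, s)
    expect = (pos + 10 * params.dt * vel) % L
    np.testing.assert_allclose(state.positions, expect, atol=1e-12)
    np.testing.assert_allclose(state.velocities, vel)


def test_forces_cells_equal_bruteforce(tiny_polymer_system, default_params):
    """Cell-list and all-pairs paths agree on the shared noise stream."""
    state, topo = tiny_polymer_system
    f_cells = engine.compute_forces(state, topo, default_params, 3, "cells")
    f_brute = engine.compute_forces(state, topo, default_params, 3, "bruteforce")
    assert np.abs(f_cells - f_brute).max() < 1e-10


def test_momentum_conserved_short_run(tiny_polymer_system, default_params):
    state, topo = tiny_polymer_system
    state = state.copy()
    log = engine.run(state, topo, default_params, 200, log_every=200)
    assert log["momentum"][-1] < 1e-10


def test_trajectory_deterministic(tiny_polymer_system, default_params):
    state, topo = tiny_polymer_system
    s1, s2 = state.copy(), state.copy()
    engine.run(s1, topo, default_params, 150)
    engine.run(s2, topo, default_params, 150)
    np.testing.assert_array_equal(s1.positions, s2.positions)
    np.testing.assert_array_equal(s1.velocities, s2.velocities)


def test_step_equals_run(tiny_polymer_system, default_params):
    """The single-step API and the compiled loop produce the same trajectory."""
    state, topo = tiny_polymer_system
    s1, s2 = state.copy(), state.copy()
    for k in range(20):
        engine.step(s1, topo, default_params, k)
    engine.run(s2, topo, default_params, 20)
    np.testing.assert_array_equal(s1.positions, s2.positions)
    np.testing.assert_array_equal(s1.velocities, s2.velocities)


def test_measure_temperature():
    rng = np.random.default_rng(3)
    n = 100_000
    vel = maxwell_boltzmann_velocities(n, 1.0, 1.0, rng)
    state = BeadState(rng.uniform(0, 10, (n, 3)), vel,
                      np.full(n, SPECIES_S, np.int8),
                      np.full(n, SOLVENT_MOL_ID, np.int32), Box(10.0))
    assert engine.measure_temperature(state) == pytest.approx(1.0, abs=0.01)
    state.velocities[:] = 0.0
    assert engine.measure_temperature(state) == 0.0


def test_blowup_detected(tiny_polymer_system, default_params):
    state, _ = tiny_polymer_system
    state = state.copy()
    state.velocities[0, 0] = np.nan
    with pytest.raises(engine.IntegrationBlowupError):
        engine.run(state, None, default_params, 50, log_every=10)


def test_equilibrated_bond_length_below_nonbonded_peak(default_params):
    """C=4 springs hold bonded beads at slightly smaller separation than the
    preferred (first-peak) distance of nonbonded neighbour pairs."""
    from scipy.spatial import cKDTree
    state, topo = initialize_system(Box(6.0), 0.2, default_params, seed=77)
    engine.run(state, topo, default_params, 3000)
    L = state.box.edge_length
    d = state.positions[topo.bonds[:, 0]] - state.positions[topo.bonds[:, 1]]
    d -= L * np.round(d / L)
    bonded = np.linalg.norm(d, axis=1).mean()
    # first maximum of the nonbonded pair-distance distribution (shell-
    # volume normalised), i.e. the preferred nonbonded separation
    tree = cKDTree(state.positions, boxsize=L)
    pairs = tree.query_pairs(1.2, output_type="ndarray")
    bonded_set = {tuple(b) for b in np.sort(topo.bonds, axis=1)}
    dd = state.positions[pairs[:, 0]] - state.positions[pairs[:, 1]]
    dd -= L * np.round(dd / L)
    r = np.linalg.norm(dd, axis=1)
    nb = np.array([rr for p, rr in zip(map(tuple, np.sort(pairs, axis=1)), r)
                   if p not in bonded_set])
    hist, edges = np.histogram(nb, bins=24, range=(0, 1.2))
    g = hist / (edges[1:] ** 3 - edges[:-1] ** 3)
    peak = 0.5 * (edges[:-1] + edges[1:])[g.argmax()]
    assert bonded < peak
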