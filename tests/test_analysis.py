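"""Clustering, shape descriptors, density profiles, interior census,
morphology labels and fusion metrics, validated against constructed
configurations with known ground truth."""

import numpy as np
import pytest

from stardpd import analysis, fixtures
from stardpd.model import (Box, BeadState, SOLVENT_MOL_ID, SPECIES_E,
                           SPECIES_O, SPECIES_S, initialize_system)


def _bare_state(pos, species, mol_id, L):
    n = len(pos)
    return BeadState(np.mod(np.asarray(pos, float), L),
                     np.zeros((n, 3)), np.asarray(species, np.int8),
                     np.asarray(mol_id, np.int32), Box(L))


# ------------------------------------------------------------------ clustering

def test_single_molecule_is_one_cluster(default_params):
    state, topo = initialize_system(Box(6.0), 20 / 648.0, default_params, seed=3)
    assert topo.n_molecules == 1
    clusters = analysis.find_aggregates(state)
    assert len(clusters) == 1
    assert len(clusters[0]) == 20


def test_two_separated_shells_are_two_clusters():
    a, _ = fixtures.make_hollow_vesicle(L=40.0, r_inner=3.0, r_outer=5.0,
                                        n_E=3000, n_O=800, n_F=200, seed=1)
    # second shell moved to the opposite octant, ids offset
    b, _ = fixtures.make_hollow_vesicle(L=40.0, r_inner=3.0, r_outer=5.0,
                                        n_E=3000, n_O=800, n_F=200, seed=2)
    shift = np.array([20.0, 20.0, 20.0])
    poly_a = a.polymer_mask()
    poly_b = b.polymer_mask()
    pos = np.concatenate([a.positions[poly_a], b.positions[poly_b] + shift])
    species = np.concatenate([a.species[poly_a], b.species[poly_b]])
    mol = np.concatenate([a.molecule_id[poly_a],
                          b.molecule_id[poly_b] + a.molecule_id[poly_a].max() + 1])
    state = _bare_state(pos, species, mol, 40.0)
    clusters = analysis.find_aggregates(state)
    assert len(clusters) == 2


def _bruteforce_clusters(state, cutoff):
    """O(N^2) union–find oracle over solvophobic contacts + molecule merge."""
    from scipy.cluster.hierarchy import DisjointSet
    L = state.box.edge_length
    phobic = np.flatnonzero((state.species == SPECIES_E)
                            | (state.species == 2))
    ds = DisjointSet(phobic.tolist())
    for ii in range(len(phobic)):
        for jj in range(ii + 1, len(phobic)):
            d = state.positions[phobic[ii]] - state.positions[phobic[jj]]
            d -= L * np.round(d / L)
            if np.dot(d, d) < cutoff**2:
                ds.merge(int(phobic[ii]), int(phobic[jj]))
    # whole-molecule merge
    by_mol = {}
    for b in phobic:
        by_mol.setdefault(int(state.molecule_id[b]), []).append(int(b))
    for beads in by_mol.values():
        for b in beads[1:]:
            ds.merge(beads[0], b)
    polymer = np.flatnonzero(state.polymer_mask())
    root_of_mol = {m: ds[beads[0]] for m, beads in by_mol.items()}
    groups = {}
    for b in polymer:
        r = root_of_mol[int(state.molecule_id[b])]
        groups.setdefault(r, set()).add(int(b))
    return sorted((frozenset(g) for g in groups.values()), key=len, reverse=True)


def test_clustering_matches_bruteforce_oracle(tiny_polymer_system):
    state, _ = tiny_polymer_system
    got = sorted((frozenset(c.tolist()) for c in
                  analysis.find_aggregates(state, cutoff=1.0)),
                 key=len, reverse=True)
    assert got == _bruteforce_clusters(state, 1.0)


def test_clustering_translation_invariant(tiny_polymer_system):
    state, _ = tiny_polymer_system
    ref = {frozenset(c.tolist()) for c in analysis.find_aggregates(state)}
    shifted = state.copy()
    shifted.positions = np.mod(shifted.positions + [3.7, -1.2, 5.9],
                               state.box.edge_length)
    got = {frozenset(c.tolist()) for c in analysis.find_aggregates(shifted)}
    assert got == ref


def test_analysis_does_not_mutate_input(shell_vesicle):
    state, _ = shell_vesicle
    before = state.positions.copy()
    beads = analysis.find_aggregates(state)[0]
    analysis.inertia_descriptor(state, beads)
    analysis.interior_census(state, beads)
    analysis.density_profile(state, beads)
    analysis.classify_morphology(state)
    np.testing.assert_array_equal(state.positions, before)


# ------------------------------------------------------------ shape descriptors

def test_shell_inertia_ratios_near_unity(shell_vesicle):
    state, spec = shell_vesicle
    beads = analysis.find_aggregates(state)[0]
    _, (r21, r31) = analysis.inertia_descriptor(state, beads)
    assert r21 == pytest.approx(1.0, rel=0.05)
    assert r31 == pytest.approx(1.0, rel=0.05)
    assert analysis.classify_shape((r21, r31)) == "sphere"


def test_rod_inertia_matches_closed_form(rod_fixture):
    state, spec = rod_fixture
    beads = analysis.find_aggregates(state)[0]
    _, (r21, r31) = analysis.inertia_descriptor(state, beads)
    assert r21 == pytest.approx(spec.truth["ratio_21"], rel=0.01)
    assert r31 == pytest.approx(spec.truth["ratio_31"], rel=0.01)
    assert analysis.classify_shape((r21, r31)) == "cylinder"


def test_disk_inertia_perpendicular_axis(disk_fixture):
    state, spec = disk_fixture
    beads = analysis.find_aggregates(state)[0]
    eig, (r21, r31) = analysis.inertia_descriptor(state, beads)
    assert r21 == pytest.approx(spec.truth["ratio_21"], rel=0.01)
    assert r31 == pytest.approx(spec.truth["ratio_31"], rel=0.01)
    # thin disk: I3 ~ I1 + I2
    assert eig[2] == pytest.approx(eig[0] + eig[1], rel=0.02)
    assert analysis.classify_shape((r21, r31)) == "disk"


def test_degenerate_cluster_rejected(shell_vesicle):
    state, _ = shell_vesicle
    with pytest.raises(analysis.DegenerateGeometryError):
        analysis.inertia_descriptor(state, np.array([0, 1]))


def test_classify_shape_sphere_example():
    assert analysis.classify_shape((1.02, 1.03)) == "sphere"


def test_stretched_shell_is_cylinder(shell_vesicle):
    """A shell stretched 3x along one axis classifies as a cylinder."""
    state, _ = shell_vesicle
    state = state.copy()
    L = state.box.edge_length
    c = L / 2
    state.box = Box(3 * L)
    p = state.positions - c
    p[:, 2] *= 3.0
    state.positions = np.mod(p + 1.5 * L, 3 * L)
    beads = analysis.find_aggregates(state, cutoff=1.5)[0]
    _, ratios = analysis.inertia_descriptor(state, beads, cutoff=1.5)
    assert analysis.classify_shape(ratios) == "cylinder"


# ------------------------------------------------------------- density profile

def test_uniform_fluid_profile_flat(small_fluid):
    state, _ = small_fluid
    # treat a central blob of solvent as the "aggregate" for centring only
    center = np.array([5.0, 5.0, 5.0])
    d = np.linalg.norm(state.positions - center, axis=1)
    blob = np.argsort(d)[:50]
    df = analysis.density_profile(state, blob, n_bins=10, r_max=4.0)
    dens = df["density_S"].to_numpy()[1:]  # innermost shell is tiny
    assert dens.std() / dens.mean() < 0.2
    np.testing.assert_allclose(dens.mean(), 3.0, rtol=0.1)


def test_vesicle_profile_O_bimodal_E_unimodal(shell_vesicle):
    state, _ = shell_vesicle
    beads = analysis.find_aggregates(state)[0]
    df = analysis.density_profile(state, beads, n_bins=40, r_max=9.0)
    from scipy.signal import find_peaks
    o = df["density_O"].to_numpy()
    e = df["density_E"].to_numpy()
    o_peaks, _ = find_peaks(o, prominence=0.25 * o.max())
    e_peaks, _ = find_peaks(np.concatenate([[0], e, [0]]),
                            prominence=0.25 * e.max())
    assert len(o_peaks) >= 2       # linings on both faces
    assert len(e_peaks) == 1       # single membrane body


def test_profile_conserves_counts(shell_vesicle):
    state, _ = shell_vesicle
    beads = analysis.find_aggregates(state)[0]
    df = analysis.density_profile(state, beads, n_bins=25, r_max=5.0)
    center_counts = df[[f"count_{s}" for s in "EOFS"]].to_numpy().sum()
    # exact conservation: every bead within r_max lands in exactly one bin
    coords, _ = analysis.unwrap_cluster(state, beads)
    center = np.mod(coords.mean(axis=0), state.box.edge_length)
    d = state.positions - center
    L = state.box.edge_length
    d -= L * np.round(d / L)
    within = np.count_nonzero(np.linalg.norm(d, axis=1) < 5.0)
    assert center_counts == within


# ------------------------------------------------------------- interior census

def test_census_open_disk_encloses_nothing(disk_fixture):
    state, _ = disk_fixture
    beads = analysis.find_aggregates(state)[0]
    cen = analysis.interior_census(state, beads)
    assert cen.interior_solvent == 0


def test_census_matches_constructed_count(shell_vesicle):
    state, spec = shell_vesicle
    beads = analysis.find_aggregates(state)[0]
    cen = analysis.interior_census(state, beads, voxel_size=0.5)
    truth = spec.truth["interior_solvent"]
    assert cen.interior_solvent == pytest.approx(truth, rel=0.10)
    # voxel refinement does not break the seal
    cen_fine = analysis.interior_census(state, beads, voxel_size=0.25)
    assert cen_fine.interior_solvent == pytest.approx(truth, rel=0.10)


def test_census_phi_O_constructed():
    """k of K O beads placed in the lumen gives phi_O = 100 k / K."""
    rng = np.random.default_rng(8)
    L = 16.0
    c = L / 2
    # dense E shell, watertight by construction
    n_shell = 6000
    v = rng.normal(size=(n_shell, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    shell = c + v * rng.uniform(4.0, 5.0, n_shell)[:, None]
    k, K = 5, 20
    o_in = c + rng.normal(0, 0.5, (k, 3))                 # lumen
    o_out = c + rng.normal(size=(K - k, 3)) * 0.1 + 6.0   # outside, clustered
    pos = np.concatenate([shell, o_in, o_out])
    species = np.concatenate([np.full(n_shell, SPECIES_E),
                              np.full(K, SPECIES_O)])
    mol = np.arange(n_shell + K) // 20
    state = _bare_state(pos, species, mol, L)
    beads = np.arange(n_shell + K)
    cen = analysis.interior_census(state, beads)
    assert cen.phi_O == pytest.approx(100.0 * k / K)


def test_census_undefined_when_walls_fill_box():
    L = 5.0
    g = np.arange(0.25, L, 0.5)
    pos = np.stack(np.meshgrid(g, g, g), axis=-1).reshape(-1, 3)
    state = _bare_state(pos, np.full(len(pos), SPECIES_E),
                        np.arange(len(pos)), L)
    with pytest.raises(analysis.CensusUndefinedError):
        analysis.interior_census(state, np.arange(len(pos)))


# ---------------------------------------------------------- morphology labels

def test_dilute_chains_disordered(default_params):
    state, topo = initialize_system(Box(8.0), 0.026, default_params, seed=4)
    reports = analysis.classify_morphology(state, bonds=topo.bonds)
    assert all(r.label == "disordered" for r in reports)


def test_closed_shell_is_vesicle(shell_vesicle):
    state, _ = shell_vesicle
    reports = analysis.classify_morphology(state)
    big = max(reports, key=lambda r: len(r.beads))
    assert big.label == "vesicle"
    assert big.census.interior_solvent > 0


def test_box_spanning_slab_is_network():
    rng = np.random.default_rng(9)
    L = 12.0
    n = int(3 * L * L * 2)
    pos = np.stack([rng.uniform(0, L, n), rng.uniform(0, L, n),
                    rng.uniform(5.0, 7.0, n)], axis=1)
    state = _bare_state(pos, np.full(n, SPECIES_E), np.arange(n) // 20, L)
    reports = analysis.classify_morphology(state)
    big = max(reports, key=lambda r: len(r.beads))
    assert big.percolating
    assert big.label == "network"


# -------------------------------------------------------------- fusion metrics

def test_fusion_metrics_identical_frames(shell_vesicle):
    state, _ = shell_vesicle
    m = analysis.fusion_metrics(state, state)
    assert m["solvent_gain_percent"] == pytest.approx(0.0)


def test_fusion_metrics_constructed_gain(shell_vesicle):
    state, spec = shell_vesicle
    n0 = analysis.fusion_metrics(state, state)["interior_solvent_before"]
    after = state.copy()
    c = state.box.edge_length / 2
    extra = np.array([[c, c, c], [c + 0.3, c, c]])
    after.positions = np.concatenate([after.positions, extra])
    after.velocities = np.concatenate([after.velocities, np.zeros((2, 3))])
    after.species = np.concatenate([after.species,
                                    np.full(2, SPECIES_S, np.int8)])
    after.molecule_id = np.concatenate([after.molecule_id,
                                        np.full(2, SOLVENT_MOL_ID, np.int32)])
    m = analysis.fusion_metrics(state, after)
    assert m["solvent_gain_percent"] == pytest.approx(100.0 * 2 / n0)


def test_fusion_metrics_requires_vesicles(shell_vesicle, disk_fixture):
    state, _ = shell_vesicle
    disk, _ = disk_fixture
    with pytest.raises(ValueError, match="after"):
        analysis.fusion_metrics(state, disk)


def test_raspberry_bumps_counted(shell_vesicle):
    state, spec = shell_vesicle
    beads = analysis.find_aggregates(state)[0]
    n = analysis.count_f_bumps(state, beads)
    assert abs(n - spec.truth["n_bumps"]) <= 2
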