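"""Observables for characterising self-assembled aggregates.

All operations are pure: they never mutate the input frame.  The pipeline is

1. :func:`find_aggregates` — cluster polymer beads by solvophobic contacts,
2. :func:`unwrap_cluster` — undo periodic wrapping (and detect percolation),
3. shape descriptors (:func:`inertia_descriptor`, :func:`classify_shape`),
   radial :func:`density_profile`, and the voxel :func:`interior_census`,
4. :func:`classify_morphology` — the decision cascade assigning one
   morphology label per aggregate,
5. :func:`fusion_metrics` — solvent-encapsulation change across a fusion run.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .model import (SPECIES_E, SPECIES_F, SPECIES_O, SPECIES_S, SPECIES_NAMES,
                    BeadState)

MORPHOLOGY_LABELS = (
    "disordered", "network", "spherical_micelle", "cylindrical_micelle",
    "disk", "micelle", "vesicle", "vesicle_with_core", "semivesicle",
)

# Shape thresholds on sorted inertia eigenvalue ratios (I1 <= I2 <= I3).
SPHERE_MAX_RATIO = 1.2      # sphere: I3/I1 below this
CYL_MIN_ELONGATION = 1.5    # cylinder: I2/I1 above this ...
CYL_MAX_ECC = 1.2           # ... with I3/I2 below this
DISK_MAX_PLANAR = 1.2       # disk: I1 ~ I2 (I2/I1 below this) ...
DISK_MIN_RATIO = 1.5        # ... with I3/I1 above this


class CensusUndefinedError(RuntimeError):
    """Raised when the wall voxels leave no solvent-accessible exterior."""


class DegenerateGeometryError(ValueError):
    """Raised for shape analysis of clusters with fewer than 3 beads."""


@dataclass
class InteriorCensus:
    """Voxel census of the solvent-inaccessible interior of an aggregate.

    phi_O: interior O beads as percent of all O beads of the aggregate.
    phi_W: interior solvent beads as percent of all beads of the structure
    (aggregate polymer beads plus the enclosed solvent itself).
    """

    interior_solvent: int
    interior_O: int
    interior_F: int
    total_O: int
    aggregate_beads: int
    interior_voxel_volume: float
    interior_solvent_indices: np.ndarray | None = None

    @property
    def phi_O(self) -> float:
        return 100.0 * self.interior_O / self.total_O if self.total_O else 0.0

    @property
    def phi_W(self) -> float:
        denom = self.aggregate_beads + self.interior_solvent
        return 100.0 * self.interior_solvent / denom if denom else 0.0


@dataclass
class AggregateReport:
    """Everything measured about one aggregate in one frame."""

    beads: np.ndarray
    n_molecules: int
    eigenvalues: tuple[float, float, float] | None = None
    ratios: tuple[float, float] | None = None
    shape: str | None = None
    census: InteriorCensus | None = None
    label: str | None = None
    percolating: bool = False


def _contact_pairs(positions: np.ndarray, L: float, cutoff: float) -> np.ndarray:
    """Index pairs closer than cutoff under periodic minimum image."""
    tree = cKDTree(np.mod(positions, L), boxsize=L)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return pairs


def find_aggregates(state: BeadState, cutoff: float = 1.0) -> list[np.ndarray]:
    """Cluster polymer beads into aggregates.

    Connected components of the contact graph over solvophobic (E, F) beads at
    distance < cutoff; every molecule is then attached whole to the component
    any of its solvophobic beads belongs to (components sharing a molecule
    merge).  Returns bead-index arrays sorted by decreasing size.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    L = state.box.edge_length
    phobic = np.flatnonzero((state.species == SPECIES_E) | (state.species == SPECIES_F))
    if phobic.size == 0:
        return []
    pairs = _contact_pairs(state.positions[phobic], L, cutoff)
    # chain solvophobic beads of the same molecule so whole molecules merge
    mol = state.molecule_id[phobic]
    order = np.argsort(mol, kind="stable")
    same_mol = mol[order[:-1]] == mol[order[1:]]
    chain = np.stack([order[:-1][same_mol], order[1:][same_mol]], axis=1)
    edges = np.concatenate([pairs, chain], axis=0) if pairs.size else chain
    n = phobic.size
    adj = coo_matrix((np.ones(len(edges), dtype=np.int8),
                      (edges[:, 0], edges[:, 1])), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)

    # aggregate = all beads of every molecule represented in a component;
    # a molecule with no solvophobic bead belongs to no aggregate
    mol_label: dict[int, int] = {}
    for m, lab in zip(mol, labels):
        mol_label[int(m)] = int(lab)
    polymer = np.flatnonzero(state.polymer_mask())
    bead_label = np.array([mol_label.get(int(m), -1)
                           for m in state.molecule_id[polymer]])
    clusters = [polymer[bead_label == c] for c in range(n_comp)]
    clusters.sort(key=len, reverse=True)
    return clusters


def unwrap_cluster(state: BeadState, beads: np.ndarray, cutoff: float = 1.0,
                   bonds: np.ndarray | None = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Unwrapped coordinates of one cluster and its percolation flags.

    Walks the cluster's contact graph (optionally augmented with bonds),
    placing each bead at the minimum image of its already-placed neighbour.
    If a bead is reached twice with positions differing by a box vector, the
    cluster is connected to its own periodic image: it percolates in that
    dimension.
    """
    L = state.box.edge_length
    pos = state.positions[beads]
    n = len(beads)
    idx_of = {int(b): k for k, b in enumerate(beads)}
    pairs = _contact_pairs(pos, L, cutoff)
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in pairs:
        adj[i].append(j)
        adj[j].append(i)
    if bonds is not None and len(bonds):
        for i, j in bonds:
            ki = idx_of.get(int(i))
            kj = idx_of.get(int(j))
            if ki is not None and kj is not None:
                adj[ki].append(kj)
                adj[kj].append(ki)

    unwrapped = np.full((n, 3), np.nan)
    percolates = np.zeros(3, dtype=bool)
    for root in range(n):
        if not np.isnan(unwrapped[root, 0]):
            continue
        unwrapped[root] = pos[root]
        queue = deque([root])
        while queue:
            i = queue.popleft()
            for j in adj[i]:
                d = pos[j] - pos[i]
                d -= L * np.round(d / L)
                cand = unwrapped[i] + d
                if np.isnan(unwrapped[j, 0]):
                    unwrapped[j] = cand
                    queue.append(j)
                else:
                    mismatch = np.abs(unwrapped[j] - cand) > 0.5 * L
                    percolates |= mismatch
    return unwrapped, percolates


def inertia_descriptor(state: BeadState, beads: np.ndarray, cutoff: float = 1.0,
                       bonds: np.ndarray | None = None,
                       ) -> tuple[np.ndarray, tuple[float, float]]:
    """Principal moments of inertia (sorted ascending) and their ratios.

    The cluster is unwrapped before the tensor is formed; beads have unit
    mass.  Returns (eigenvalues I1 <= I2 <= I3, (I2/I1, I3/I1)).
    """
    if len(beads) < 3:
        raise DegenerateGeometryError(f"cluster of {len(beads)} beads has no shape")
    coords, _ = unwrap_cluster(state, beads, cutoff, bonds)
    return inertia_from_coords(coords)


def inertia_from_coords(coords: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Inertia eigenvalues/ratios of already-unwrapped unit-mass coordinates."""
    r = coords - coords.mean(axis=0)
    r2 = np.sum(r * r, axis=1)
    tensor = np.eye(3) * r2.sum() - r.T @ r
    eig = np.sort(np.linalg.eigvalsh(tensor))
    eig = np.clip(eig, 0.0, None)
    i1 = eig[0] if eig[0] > 0 else np.finfo(float).tiny
    return eig, (float(eig[1] / i1), float(eig[2] / i1))


def classify_shape(ratios: tuple[float, float]) -> str:
    """Map sorted inertia ratios (I2/I1, I3/I1) to a coarse shape class.

    A sphere has all moments comparable; a long cylinder has one small moment
    (its axis) and two large equal ones; a thin disk has two small equal
    in-plane moments and, by the perpendicular-axis relation, I3 ~ I1 + I2.
    """
    r21, r31 = ratios
    r32 = r31 / r21
    if r31 < SPHERE_MAX_RATIO:
        return "sphere"
    if r21 > CYL_MIN_ELONGATION and r32 < CYL_MAX_ECC:
        return "cylinder"
    if r21 < DISK_MAX_PLANAR and r31 > DISK_MIN_RATIO:
        return "disk"
    return "irregular"


def density_profile(state: BeadState, beads: np.ndarray, n_bins: int = 40,
                    r_max: float | None = None, cutoff: float = 1.0,
                    bonds: np.ndarray | None = None) -> pd.DataFrame:
    """Radial number density of each species around an aggregate's centre.

    The aggregate is unwrapped to locate its centre of mass; every bead in the
    box is then binned by its minimum-image distance from that centre and the
    per-species counts are divided by the spherical-shell volumes.  For a
    vesicle the O (and F) profiles are bimodal — linings on both membrane
    faces — while the membrane-forming E profile is unimodal.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    L = state.box.edge_length
    coords, _ = unwrap_cluster(state, beads, cutoff, bonds)
    center = np.mod(coords.mean(axis=0), L)
    d = state.positions - center
    d -= L * np.round(d / L)
    dist = np.linalg.norm(d, axis=1)
    if r_max is None:
        r_max = L / 2.0
    edges = np.linspace(0.0, r_max, n_bins + 1)
    shell_vol = 4.0 / 3.0 * np.pi * np.diff(edges ** 3)
    out = {"r": 0.5 * (edges[:-1] + edges[1:])}
    for code, name in enumerate(SPECIES_NAMES):
        counts, _ = np.histogram(dist[state.species == code], bins=edges)
        out[f"count_{name}"] = counts
        out[f"density_{name}"] = counts / shell_vol
    return pd.DataFrame(out)


def _periodic_label_merge(free: np.ndarray) -> np.ndarray:
    """Connected-component labels of a boolean grid with periodic wrap.

    scipy's labelling is non-periodic; labels touching across opposite faces
    are merged afterwards with a union–find pass.
    """
    labels, n_lab = ndimage.label(free)
    if n_lab == 0:
        return labels
    parent = np.arange(n_lab + 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for axis in range(3):
        lo = np.take(labels, 0, axis=axis).ravel()
        hi = np.take(labels, -1, axis=axis).ravel()
        both = (lo > 0) & (hi > 0)
        for a, b in set(zip(lo[both].tolist(), hi[both].tolist())):
            union(a, b)
    lut = np.array([find(x) for x in range(n_lab + 1)])
    return lut[labels]


def interior_census(state: BeadState, beads: np.ndarray,
                    voxel_size: float = 0.5, cutoff: float = 1.0,
                    wall_radius: float = 0.5,
                    bonds: np.ndarray | None = None) -> InteriorCensus:
    """Count beads enclosed by an aggregate's solvophobic membrane.

    The box is voxelised; voxels whose centre lies within ``wall_radius`` of
    any solvophobic (E or F) bead of the aggregate are walls, so the wall is
    the union of spheres around the membrane beads and stays watertight as the
    voxels shrink.  Flood-filling the free voxels from the voxel farthest from
    the aggregate's centre of mass (periodic connectivity) marks the
    solvent-accessible exterior; the remaining free voxels are interior.  An
    open structure (micelle, disk, bowl) encloses nothing.
    """
    L = state.box.edge_length
    if voxel_size > cutoff:
        raise ValueError("voxel_size must be <= the interaction range")
    n_vox = max(int(round(L / voxel_size)), 4)
    scale = n_vox / L

    def voxel_of(points: np.ndarray) -> tuple[np.ndarray, ...]:
        iv = np.floor(np.mod(points, L) * scale).astype(np.int64)
        np.clip(iv, 0, n_vox - 1, out=iv)
        return iv[:, 0], iv[:, 1], iv[:, 2]

    sp = state.species[beads]
    phobic = beads[(sp == SPECIES_E) | (sp == SPECIES_F)]
    tree = cKDTree(np.mod(state.positions[phobic], L), boxsize=L)
    centers = (np.indices((n_vox, n_vox, n_vox)).reshape(3, -1).T + 0.5) / scale
    dist, _ = tree.query(centers, k=1, distance_upper_bound=wall_radius + 1e-9)
    wall = (dist <= wall_radius).reshape(n_vox, n_vox, n_vox)
    free = ~wall
    if not free.any():
        raise CensusUndefinedError("wall voxels fill the box; no exterior")

    labels = _periodic_label_merge(free)

    coords, _ = unwrap_cluster(state, beads, cutoff, bonds)
    center = np.mod(coords.mean(axis=0), L)
    # seed: free voxel whose centre is farthest (minimum image) from the COM
    d = centers - center
    d -= L * np.round(d / L)
    dist2 = np.sum(d * d, axis=1).reshape(n_vox, n_vox, n_vox)
    dist2[wall] = -1.0
    seed = np.unravel_index(np.argmax(dist2), dist2.shape)
    exterior_label = labels[seed]
    if exterior_label == 0:
        raise CensusUndefinedError("no solvent-accessible exterior found")
    interior = free & (labels != exterior_label)

    ix, iy, iz = voxel_of(state.positions)
    in_interior = interior[ix, iy, iz]
    solvent_in = in_interior & (state.species == SPECIES_S)
    interior_solvent = int(np.count_nonzero(solvent_in))
    agg_mask = np.zeros(state.n_beads, dtype=bool)
    agg_mask[beads] = True
    interior_O = int(np.count_nonzero(in_interior & agg_mask & (state.species == SPECIES_O)))
    interior_F = int(np.count_nonzero(in_interior & agg_mask & (state.species == SPECIES_F)))
    total_O = int(np.count_nonzero(state.species[beads] == SPECIES_O))
    return InteriorCensus(
        interior_solvent=interior_solvent,
        interior_O=interior_O,
        interior_F=interior_F,
        total_O=total_O,
        aggregate_beads=len(beads),
        interior_voxel_volume=float(interior.sum() / scale ** 3),
        interior_solvent_indices=np.flatnonzero(solvent_in),
    )


def count_f_bumps(state: BeadState, beads: np.ndarray, cutoff: float = 1.0) -> int:
    """Number of discrete F-bead surface clusters ("bumps") of an aggregate."""
    f_beads = beads[state.species[beads] == SPECIES_F]
    if f_beads.size == 0:
        return 0
    pairs = _contact_pairs(state.positions[f_beads], state.box.edge_length, cutoff)
    n = f_beads.size
    adj = coo_matrix((np.ones(len(pairs), dtype=np.int8),
                      (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_comp, _ = connected_components(adj, directed=False)
    return int(n_comp)


def classify_morphology(state: BeadState, beads_per_molecule: int = 20,
                        cutoff: float = 1.0, voxel_size: float = 0.5,
                        min_interior_solvent: int = 1,
                        min_core_f: int = 10,
                        bonds: np.ndarray | None = None,
                        ) -> list[AggregateReport]:
    """Assign one morphology label to every aggregate in a frame.

    Decision cascade per aggregate: ``disordered`` if it holds <= 5 molecules;
    ``network`` if it connects to its own periodic image; ``vesicle`` (or
    ``vesicle_with_core`` when >= ``min_core_f`` F beads sit in the lumen) if
    the interior census finds at least ``min_interior_solvent`` enclosed
    solvent beads; otherwise the inertia-ratio shape mapped to
    spherical/cylindrical micelle or disk, with ``micelle`` for irregular.
    """
    reports: list[AggregateReport] = []
    for beads in find_aggregates(state, cutoff):
        n_mol = len(np.unique(state.molecule_id[beads]))
        rep = AggregateReport(beads=beads, n_molecules=n_mol)
        if n_mol <= 5:
            rep.label = "disordered"
            reports.append(rep)
            continue
        coords, percolates = unwrap_cluster(state, beads, cutoff, bonds)
        rep.percolating = bool(percolates.any())
        if rep.percolating:
            rep.label = "network"
            reports.append(rep)
            continue
        rep.eigenvalues = tuple(float(x) for x in inertia_from_coords(coords)[0])
        _, rep.ratios = inertia_from_coords(coords)
        rep.shape = classify_shape(rep.ratios)
        rep.census = interior_census(state, beads, voxel_size, cutoff,
                                     bonds=bonds)
        if rep.census.interior_solvent >= min_interior_solvent:
            if rep.census.interior_F >= min_core_f:
                rep.label = "vesicle_with_core"
            else:
                rep.label = "vesicle"
        else:
            rep.label = {"sphere": "spherical_micelle",
                         "cylinder": "cylindrical_micelle",
                         "disk": "disk",
                         "irregular": "micelle"}[rep.shape]
        reports.append(rep)
    return reports


def fusion_metrics(frames_before: list[BeadState] | BeadState,
                   frame_after: BeadState, voxel_size: float = 0.5,
                   cutoff: float = 1.0) -> dict:
    """Solvent-encapsulation change across a fusion event.

    Returns the percent change of enclosed solvent between the summed vesicle
    interiors before fusion and the fused vesicle after, plus the F-bump count
    of the fused aggregate.  Raises if a frame contains no vesicle.
    """
    if isinstance(frames_before, BeadState):
        frames_before = [frames_before]

    def vesicle_interiors(state: BeadState, name: str) -> list[int]:
        reports = classify_morphology(state, cutoff=cutoff, voxel_size=voxel_size)
        counts = [r.census.interior_solvent for r in reports
                  if r.label in ("vesicle", "vesicle_with_core")]
        if not counts:
            raise ValueError(f"no vesicle found in frame '{name}'")
        return counts

    before = sum(sum(vesicle_interiors(s, f"before[{k}]"))
                 for k, s in enumerate(frames_before))
    after_reports = classify_morphology(frame_after, cutoff=cutoff,
                                        voxel_size=voxel_size)
    after_vesicles = [r for r in after_reports
                      if r.label in ("vesicle", "vesicle_with_core")]
    if not after_vesicles:
        raise ValueError("no vesicle found in frame 'after'")
    after = sum(r.census.interior_solvent for r in after_vesicles)
    largest = max(after_vesicles, key=lambda r: len(r.beads))
    return {
        "interior_solvent_before": int(before),
        "interior_solvent_after": int(after),
        "solvent_gain_percent": 100.0 * (after - before) / before if before else float("nan"),
        "n_vesicles_after": len(after_vesicles),
        "f_bumps_after": count_f_bumps(frame_after, largest.beads, cutoff),
    }
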