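"""Reproducible drivers for the three computational experiments.

* the (aES, aFS) morphology state diagram at fp = 0.10,
* vesicle-formation runs at fp = 0.10 and 0.15 with the full observable log
  (aggregate count, phi_O / phi_W census, inertia ratios),
* the two-vesicle fusion protocol in an enlarged box.

Every published-scale preset carries the original run conditions verbatim
(L = 40 rc box and 5–8 x 10^5 steps for formation; L = 70 rc and 2 x 10^7
steps for fusion).  Those runs take days on one CPU, so each preset has a
desk-scale counterpart, explicitly labelled ``scaled_down``, sized so that
the qualitative outcome (aggregation, enclosure, fusion contact) is reachable
in minutes.  Desk-scale results probe the mechanisms, not the published
snapshot-for-snapshot trajectories.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, engine, io
from .model import (SOLVENT_MOL_ID, SPECIES_S, BeadState, Box,
                    SimulationParams, Topology, TrajectoryFrame,
                    maxwell_boltzmann_velocities)


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment's run conditions."""

    kind: str                      # state_diagram | formation | fusion
    box_length: float
    fp: float
    a_ES: float
    a_FS: float
    steps: int
    snapshot_every: int
    seeds: tuple[int, ...] = (1,)
    scale: str = "paper"           # paper | desk
    scaled_down: bool = False
    expectations: dict = field(default_factory=dict)

    def params(self, seed: int) -> SimulationParams:
        return SimulationParams(seed=seed).with_overrides(
            a_ES=self.a_ES, a_FS=self.a_FS)


#: Published-scale presets carry the original run conditions; desk-scale presets
#: are scaled-down property runs.  ``expectations`` documents the outcome each
#: preset is built to probe (values at paper scale are single stochastic runs:
#: acceptance there is same order and sign, not digit agreement).
PRESETS: dict[str, ExperimentConfig] = {
    "state_diagram_paper": ExperimentConfig(
        kind="state_diagram", box_length=40.0, fp=0.10, a_ES=97.9, a_FS=125.0,
        steps=500_000, snapshot_every=25_000,
        expectations={"aES=26,aFS<=76": "disordered",
                      "aES=26,aFS>=111": "network",
                      "high aES, high aFS": "vesicle"}),
    "state_diagram_desk": ExperimentConfig(
        kind="state_diagram", box_length=12.0, fp=0.10, a_ES=97.9, a_FS=125.0,
        steps=40_000, snapshot_every=10_000, scale="desk", scaled_down=True,
        expectations={"note": "coarse grid, qualitative labels only"}),
    "formation_fp10_paper": ExperimentConfig(
        kind="formation", box_length=40.0, fp=0.10, a_ES=97.9, a_FS=125.0,
        steps=800_000, snapshot_every=10_000,
        expectations={"pathway": "sphere -> disk -> vesicle-with-core -> "
                                 "cylinder -> hollow vesicle",
                      "phi_O_plateau_percent": 2.1,
                      "phi_O_plateau_steps": (320_000, 340_000)}),
    "formation_fp15_paper": ExperimentConfig(
        kind="formation", box_length=40.0, fp=0.15, a_ES=97.9, a_FS=125.0,
        steps=500_000, snapshot_every=10_000,
        expectations={"pathway": "spherical micelles -> oblate F-bump-E "
                                 "bilayer -> closed vesicle",
                      "final_label": "vesicle",
                      "final_steps": (250_000, 500_000)}),
    "formation_fp15_desk": ExperimentConfig(
        kind="formation", box_length=15.0, fp=0.15, a_ES=97.9, a_FS=125.0,
        steps=200_000, snapshot_every=20_000, seeds=(1, 2, 3),
        scale="desk", scaled_down=True,
        expectations={"final_label": "vesicle (at least one seed)",
                      "raspberry": "F beads in discrete surface clusters"}),
    "fusion_paper": ExperimentConfig(
        kind="fusion", box_length=70.0, fp=0.10, a_ES=97.9, a_FS=125.0,
        steps=20_000_000, snapshot_every=100_000,
        expectations={"solvent_gain_percent": 0.24,
                      "pathway": "F-bump kissing -> contact bending -> pore "
                                 "-> hemifusion -> tubular -> spherical"}),
    "fusion_desk": ExperimentConfig(
        kind="fusion", box_length=32.0, fp=0.10, a_ES=97.9, a_FS=125.0,
        steps=20_000, snapshot_every=5_000, scale="desk", scaled_down=True,
        expectations={"note": "two fixture vesicles brought into contact; "
                              "qualitative metrics only"}),
}


@dataclass
class RunResult:
    """Trajectory-level outcome of one driver invocation."""

    config: ExperimentConfig
    seed: int
    final_state: BeadState
    topology: Topology | None
    timeseries: pd.DataFrame
    reports: list[analysis.AggregateReport]
    equilibrated: bool


def _frame_observables(state: BeadState, topology: Topology | None,
                       step: int, voxel_size: float = 0.5) -> dict:
    """Clustering + census + shape of the largest aggregate at one step."""
    bonds = topology.bonds if topology is not None else None
    reports = analysis.classify_morphology(state, voxel_size=voxel_size,
                                           bonds=bonds)
    row = {"step": step,
           "temperature": engine.measure_temperature(state),
           "n_aggregates": len(reports),
           "largest_n_molecules": 0, "label": "none",
           "phi_O": np.nan, "phi_W": np.nan, "interior_solvent": 0,
           "ratio_21": np.nan, "ratio_31": np.nan, "f_bumps": 0}
    if reports:
        big = max(reports, key=lambda r: len(r.beads))
        row.update(largest_n_molecules=big.n_molecules, label=big.label)
        if big.census is not None:
            row.update(phi_O=big.census.phi_O, phi_W=big.census.phi_W,
                       interior_solvent=big.census.interior_solvent)
        if big.ratios is not None:
            row.update(ratio_21=big.ratios[0], ratio_31=big.ratios[1])
        row.update(f_bumps=analysis.count_f_bumps(state, big.beads))
    return row


def _is_equilibrated(temps: list[float], kBT: float, tol: float = 0.05) -> bool:
    """Temperature criterion over the final 20% of logged values."""
    if not temps:
        return False
    tail = temps[max(len(temps) * 4 // 5, len(temps) - 5):]
    return abs(float(np.mean(tail)) - kBT) / kBT < tol


def run_formation(config: ExperimentConfig, seed: int,
                  out_dir: str | Path | None = None,
                  resume: TrajectoryFrame | None = None,
                  topology: Topology | None = None,
                  progress: bool = False) -> RunResult:
    """Self-assembly run with the full per-snapshot observable log."""
    from .model import initialize_system

    params = config.params(seed)
    if resume is None:
        state, topology = initialize_system(
            Box(config.box_length), config.fp, params, seed=seed)
        step0 = 0
    else:
        state = resume.state.copy()
        step0 = resume.step
        if topology is None:
            raise ValueError("resuming requires the run topology")

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    rows = []
    t_wall = time.time()
    remaining = config.steps - step0
    n_chunks = max(remaining // config.snapshot_every, 1)
    for c in range(n_chunks):
        n = min(config.snapshot_every, config.steps - step0)
        if n <= 0:
            break
        engine.run(state, topology, params, n, step_offset=step0)
        step0 += n
        rows.append(_frame_observables(state, topology, step0))
        if out is not None:
            io.write_frame(TrajectoryFrame(step=step0, state=state),
                           out / f"frame_{step0:08d}.npz")
        if progress:
            r = rows[-1]
            print(f"  step {step0:>8d}  T={r['temperature']:.3f}  "
                  f"aggregates={r['n_aggregates']:>3d}  label={r['label']}  "
                  f"interior_S={r['interior_solvent']}  "
                  f"[{time.time() - t_wall:.0f}s]", flush=True)
    ts = pd.DataFrame(rows)
    bonds = topology.bonds if topology is not None else None
    reports = analysis.classify_morphology(state, bonds=bonds)
    eq = _is_equilibrated(ts["temperature"].tolist(), params.kBT)
    if out is not None:
        ts.to_csv(out / "observables.tsv", sep="\t", index=False)
        io.RunManifest(kind=config.kind, seed=seed,
                       config={**config.__dict__, "expectations": dict(config.expectations)},
                       frames=sorted(str(p.name) for p in out.glob("frame_*.npz")),
                       observable_log="observables.tsv").write(out / "manifest.json")
    return RunResult(config=config, seed=seed, final_state=state,
                     topology=topology, timeseries=ts, reports=reports,
                     equilibrated=eq)


def run_state_diagram(a_ES_values, a_FS_values, config: ExperimentConfig,
                      seed: int = 1, out_dir: str | Path | None = None,
                      progress: bool = False) -> pd.DataFrame:
    """One equilibrated run per (aES, aFS) grid point; final-frame labels.

    A run whose temperature drifted beyond tolerance is flagged in the
    ``equilibrated`` column rather than silently included.
    """
    from .model import initialize_system

    rows = []
    for a_es in a_ES_values:
        for a_fs in a_FS_values:
            cfg = replace(config, a_ES=float(a_es), a_FS=float(a_fs))
            params = cfg.params(seed)
            state, topo = initialize_system(Box(cfg.box_length), cfg.fp,
                                            params, seed=seed)
            log = engine.run(state, topo, params, cfg.steps,
                             log_every=max(cfg.steps // 20, 1))
            reports = analysis.classify_morphology(state, bonds=topo.bonds)
            big = max(reports, key=lambda r: len(r.beads)) if reports else None
            rows.append({
                "a_ES": a_es, "a_FS": a_fs,
                "label": big.label if big else "none",
                "n_aggregates": len(reports),
                "largest_n_molecules": big.n_molecules if big else 0,
                "equilibrated": _is_equilibrated(
                    list(log["temperature"]), params.kBT),
            })
            if progress:
                print(f"  aES={a_es:6.1f} aFS={a_fs:6.1f} -> {rows[-1]['label']}",
                      flush=True)
    df = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "state_diagram.tsv", sep="\t", index=False)
    return df


class PlacementError(ValueError):
    """Raised when two vesicles cannot be placed without overlap."""


def make_fusion_initial(vesicle: BeadState, box_length: float,
                        gap: float = 1.0, rho: float = 3.0,
                        topology: Topology | None = None, seed: int = 1,
                        kBT: float = 1.0,
                        ) -> tuple[BeadState, Topology | None]:
    """Duplicate one vesicle into a large box with outer surfaces ``gap`` apart.

    The vesicle unit = its aggregate beads plus the solvent enclosed in its
    lumen, so the pre-fusion interior census of the pair is exactly twice the
    single vesicle's.  The copies sit along x; one copy is tagged 1, the other
    2, for two-colour provenance tracking.  The remaining volume is filled
    with fresh solvent to the target density.
    """
    reports = analysis.classify_morphology(
        vesicle, bonds=topology.bonds if topology else None)
    ves = [r for r in reports if r.label in ("vesicle", "vesicle_with_core")]
    if not ves:
        raise ValueError("input frame contains no classified vesicle")
    big = max(ves, key=lambda r: len(r.beads))
    bonds = topology.bonds if topology is not None else None
    coords, _ = analysis.unwrap_cluster(vesicle, big.beads, bonds=bonds)
    center = coords.mean(axis=0)
    agg_rel = coords - center
    interior_idx = big.census.interior_solvent_indices
    d = vesicle.positions[interior_idx] - np.mod(center, vesicle.box.edge_length)
    d -= vesicle.box.edge_length * np.round(d / vesicle.box.edge_length)
    sol_rel = d
    r_outer = float(np.linalg.norm(agg_rel, axis=1).max())

    L = float(box_length)
    if gap < 0:
        raise PlacementError("gap must be nonnegative")
    if 4 * r_outer + gap > L:
        raise PlacementError(
            f"two vesicles of outer radius {r_outer:.1f} with gap {gap} do not "
            f"fit in a box of edge {L} without overlapping images")
    offset = (2 * r_outer + gap) / 2.0
    centers = [np.array([L / 2 - offset, L / 2, L / 2]),
               np.array([L / 2 + offset, L / 2, L / 2])]

    rng = np.random.default_rng(seed)
    unit_pos = np.concatenate([agg_rel, sol_rel])
    unit_species = np.concatenate([vesicle.species[big.beads],
                                   vesicle.species[interior_idx]])
    unit_mol = np.concatenate([vesicle.molecule_id[big.beads],
                               np.full(len(interior_idx), SOLVENT_MOL_ID)])
    n_unit = len(unit_pos)
    mol_stride = int(vesicle.molecule_id.max()) + 1

    pos_parts, sp_parts, mol_parts, tag_parts = [], [], [], []
    for k, c in enumerate(centers):
        pos_parts.append(unit_pos + c)
        sp_parts.append(unit_species)
        m = unit_mol.copy()
        poly = m != SOLVENT_MOL_ID
        m[poly] += k * mol_stride
        mol_parts.append(m)
        tag_parts.append(np.full(n_unit, k + 1, dtype=np.int8))

    # fresh exterior solvent, rejected from spheres around both copies
    n_total = int(round(rho * L ** 3))
    n_fill = max(n_total - 2 * n_unit, 0)
    keep_pts = []
    need = n_fill
    while need > 0:
        cand = rng.uniform(0.0, L, size=(2 * need + 64, 3))
        ok = np.ones(len(cand), dtype=bool)
        for c in centers:
            d = cand - c
            d -= L * np.round(d / L)
            ok &= np.linalg.norm(d, axis=1) > r_outer + 0.2
        cand = cand[ok][:need]
        keep_pts.append(cand)
        need -= len(cand)
    fill = np.concatenate(keep_pts) if keep_pts else np.empty((0, 3))
    pos_parts.append(fill)
    sp_parts.append(np.full(len(fill), SPECIES_S, dtype=np.int8))
    mol_parts.append(np.full(len(fill), SOLVENT_MOL_ID, dtype=np.int32))
    tag_parts.append(np.zeros(len(fill), dtype=np.int8))

    positions = np.mod(np.concatenate(pos_parts), L)
    n_all = len(positions)
    state = BeadState(
        positions=positions,
        velocities=maxwell_boltzmann_velocities(n_all, kBT, 1.0, rng),
        species=np.concatenate(sp_parts).astype(np.int8),
        molecule_id=np.concatenate(mol_parts).astype(np.int32),
        box=Box(L),
        tags=np.concatenate(tag_parts))

    new_topo = None
    if topology is not None and len(topology.bonds):
        # remap source bond indices into the two copies
        lookup = -np.ones(vesicle.n_beads, dtype=np.int64)
        lookup[big.beads] = np.arange(len(big.beads))
        src = topology.bonds
        inside = (lookup[src[:, 0]] >= 0) & (lookup[src[:, 1]] >= 0)
        base = lookup[src[inside]]
        all_bonds = [base, base + n_unit]
        new_topo = Topology(bonds=np.concatenate(all_bonds),
                            molecules=[], arm_lengths=topology.arm_lengths)
    return state, new_topo


def run_fusion(vesicle: BeadState, config: ExperimentConfig, seed: int = 1,
               gap: float = 1.0, topology: Topology | None = None,
               out_dir: str | Path | None = None,
               progress: bool = False) -> tuple[RunResult, dict]:
    """Two-vesicle fusion protocol: place, run, log fusion metrics.

    Returns the run result plus the solvent-encapsulation change between the
    initial pair and the final frame (computable only once the final frame
    again contains at least one vesicle).
    """
    params = config.params(seed)
    state, topo = make_fusion_initial(vesicle, config.box_length, gap=gap,
                                      rho=params.rho, topology=topology,
                                      seed=seed, kBT=params.kBT)
    initial = state.copy()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        io.write_frame(TrajectoryFrame(step=0, state=initial),
                       out / "frame_00000000.npz")
    rows = []
    step0 = 0
    n_chunks = max(config.steps // config.snapshot_every, 1)
    for c in range(n_chunks):
        n = min(config.snapshot_every, config.steps - step0)
        if n <= 0:
            break
        engine.run(state, topo, params, n, step_offset=step0)
        step0 += n
        rows.append(_frame_observables(state, topo, step0))
        if out is not None:
            io.write_frame(TrajectoryFrame(step=step0, state=state),
                           out / f"frame_{step0:08d}.npz")
        if progress:
            r = rows[-1]
            print(f"  step {step0:>8d}  aggregates={r['n_aggregates']}  "
                  f"label={r['label']}  interior_S={r['interior_solvent']}  "
                  f"f_bumps={r['f_bumps']}", flush=True)
    ts = pd.DataFrame(rows)
    bonds = topo.bonds if topo is not None else None
    reports = analysis.classify_morphology(state, bonds=bonds)
    result = RunResult(config=config, seed=seed, final_state=state,
                       topology=topo, timeseries=ts, reports=reports,
                       equilibrated=_is_equilibrated(
                           ts["temperature"].tolist(), params.kBT))
    try:
        metrics = analysis.fusion_metrics(initial, state)
    except ValueError as exc:
        metrics = {"error": str(exc)}
    if out is not None:
        ts.to_csv(out / "observables.tsv", sep="\t", index=False)
    return result, metrics
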