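# Methods

## Model

The system is a coarse-grained dissipative particle dynamics (DPD) fluid of
soft beads at number density ρ = 3 in a periodic cubic box, in reduced units
rc = m = kBT = 1 (time unit τ = rc·√(m/kBT)).  Four species exist: E, O, F
(polymer blocks) and S (solvent).  A polymer molecule is a miktoarm star
E₁₂O₆F₂: three linear arms of 12 E, 6 O and 2 F beads joined at a single
junction.  The junction is realised without an extra hub bead: the first bead
of the E arm is the hub, and the first beads of the O and F arms bond
directly to it.  This keeps 20 beads (19 bonds) per molecule and a
hydrophilic bead fraction of 6/20 = 30%, inside the empirical 35% ± 10%
window in which amphiphiles of this class form vesicles.  E and F are
solvophobic (large repulsion against S), O is solvophilic.

The force on bead *i* is a sum of pairwise terms inside the cutoff rc:

* conservative soft repulsion  F_C = a_ij (1 − r/rc) r̂,
* dissipative drag             F_D = −γ (1 − r/rc)² (v_ij · r̂) r̂,
* random kicks                 F_R = σ (1 − r/rc) ξ_ij Δt^(−1/2) r̂,
* bonds                        F_S = −C r_ij (zero-rest-length harmonic).

F_D and F_R form the pairwise Groot–Warren thermostat; σ² = 2γkBT and
ω_D = ω_R² are enforced at construction (σ is always derived, never set).
The Δt^(−1/2) scaling of the random force is the Groot–Warren form that makes
diffusion independent of the timestep.  The bond force is attractive; with
C = 4 it holds bonded beads at slightly smaller separation than the first
peak of the nonbonded pair-distance distribution (measured: ≈0.80 rc vs
≈0.88 rc at ρ = 3).  Repulsion amplitudes map linearly to the Flory–Huggins
χ parameter at ρ = 3: a_ij = a_ii + 3.27 χ_ij, with a_ii = 25.

Default interaction table (DPD units, order E/O/F/S): like–like 25.0,
E–O 38.5, E–F 78.0, O–F 89.4, O–S 26.0.  E–S and F–S are the morphology
control parameters; they default to the strongly solvophobic values used in
the formation experiments (a_ES = 97.9, a_FS = 125.0) and are overridden in
sweeps (a_ES ∈ [26, 97.9], a_FS ∈ [26, 125]).

## Integration

Groot–Warren modified velocity-Verlet with λ = ½ and Δt = 0.04: half-kick,
drift with periodic wrap, one force evaluation at the new positions using the
half-kicked (predicted) velocities, half-kick.  With λ = ½ the predicted
velocity equals the half-kick velocity, so one force evaluation per step
suffices.  Known artifact: at Δt = 0.04 this scheme equilibrates the
interacting fluid ≈2–3% above the target temperature; the package's
thermostat check measures ≈1.028 kBT for the pure-solvent fluid, inside the
3% band the reduced-unit parameterisation assumes.  Kinetic temperature is
reported as Σ m v² / (3N − 3): the momentum-conserving thermostat freezes the
centre-of-mass degrees of freedom, which are removed.

### Noise stream

The per-pair random variate ξ_ij for step s is a counter-based hash of
(seed, s, min(i,j), max(i,j)) mapped to a uniform variate on [−√3, √3]
(zero mean, unit variance; the thermostat constrains only the first two
moments).  Consequences, all load-bearing:

* ξ_ij = ξ_ji exactly (pairwise antisymmetry of F_R, hence momentum
  conservation to rounding error);
* the cell-list and the O(N²) all-pairs force paths consume the identical
  noise and agree to < 10⁻¹⁰ per component (they differ only in summation
  order);
* trajectories are bit-reproducible for a fixed seed and restartable from
  any snapshot that stores positions, velocities and forces — no generator
  state needs saving.

### Neighbour search

A cell list with cell edge ≥ rc, counting-sorted per step; beads are gathered
into cell-sorted scratch arrays so neighbour scans are contiguous, and each
neighbour cell's periodic image shift is precomputed so the inner loop
carries no minimum-image branches.  The all-pairs path is retained as an
independent oracle, not a fallback.  All kernels are numba-compiled;
throughput on one CPU core is ≈0.3 µs per bead-step at ρ = 3.

## Initialization

round(ρL³) beads; round(fp·ρL³/20) molecules grown as compact random walks
(bonded spacing 0.8 rc) from uniform anchors, remaining beads solvent.  "vol
%" is read as bead fraction (uniform bead volume).  Velocities are
Maxwell–Boltzmann at kBT with total momentum shifted to exactly zero.  The
zero-rest-length springs admit any bounded starting bond length, so compact
walks avoid step-0 force spikes without biasing the assembly (soft cores
relax overlaps within a few steps).

## Analysis operators

**Clustering.**  Aggregates are connected components of the contact graph
over solvophobic (E, F) beads at distance < rc (periodic k-d tree), extended
to whole molecules; components sharing a molecule merge.  An O(N²)
union–find oracle backs the implementation in tests.

**Unwrapping and percolation.**  Before any tensor or profile, a cluster is
unwrapped by breadth-first walk over its contact graph (plus bonds),
placing each bead at the minimum image of an already-placed neighbour.  A
bead reached twice with positions differing by a box vector means the
cluster touches its own periodic image: it percolates (→ "network").

**Shape.**  Principal moments of inertia I₁ ≤ I₂ ≤ I₃ about the centre of
mass (unit masses), summarised by I₂/I₁ and I₃/I₁.  Thresholds (chosen to
separate the analytic fixtures with wide margins; the field convention gives
no numeric cutoffs): sphere I₃/I₁ < 1.2; cylinder I₂/I₁ > 1.5 with
I₃/I₂ < 1.2; disk I₂/I₁ < 1.2 with I₃/I₁ > 1.5; otherwise irregular.

**Radial density profile.**  Per-species counts in spherical shells around
the aggregate centre, divided by shell volume.  A vesicle shows bimodal O
(and F) profiles — linings on both membrane faces — and a unimodal E
profile; a solid micelle shows E filling the centre.

**Interior census.**  The box is voxelised (default voxel 0.5 rc); a voxel
is wall when its centre lies within 0.5 rc of any solvophobic bead of the
aggregate, so the wall is a union of spheres that stays watertight as voxels
shrink.  Free voxels are labelled by connected components (6-connectivity,
periodic merge across faces); the component of the free voxel farthest from
the aggregate centre is the solvent-accessible exterior; remaining free
voxels are interior.  φ_O = interior O beads as percent of the aggregate's O
beads; φ_W = interior solvent as percent of the structure's beads (aggregate
polymer + enclosed solvent — "the structure" is read as including its
cargo).  An aggregate that encloses nothing (micelle, disk, bowl) has
interior solvent 0 by construction.  The census is undefined (an error, not
a zero) when walls fill the box.

**Morphology cascade.**  Per aggregate: disordered (≤ 5 molecules) →
network (percolating) → vesicle if enclosed solvent ≥ 1 bead
(vesicle_with_core when ≥ 10 F beads sit in the lumen) → else the inertia
shape mapped to spherical/cylindrical micelle or disk.

**Fusion metrics.**  Percent change of summed enclosed solvent between the
pre-fusion pair and the post-fusion frame, plus the F-bump count (connected
components of the aggregate's F beads) whose decrease tracks bump
coalescence at the contact zone.

## Synthetic fixtures

Analytic configurations carry their ground truth:

* ideal fluid — uniform positions, Maxwell–Boltzmann velocities (thermostat
  and momentum test bed);
* hollow vesicle — E shell (dense enough that the 0.5 rc wall spheres seal
  it), O linings on both faces, F beads in k surface bumps, an exact count
  of lumen solvent kept clear of the wall region, exterior solvent at ρ;
* rod / disk — solid cylinders filled with scrambled-Sobol points, whose
  inertia ratios match the continuum closed forms to ~0.1% at a few
  thousand beads (plain Monte Carlo noise would exceed the 1% tolerance).

Fixtures are geometric, not thermodynamic: densities are not equilibrated,
so under dynamics a fixture shell swells toward ρ = 3 within a few τ and its
census seal opens.  Static analysis tests therefore use fixtures directly;
dynamic tests assert only interaction-range physics (e.g. copies placed many
rc apart do not merge).

## Experiments and scales

Three drivers reproduce the study design: the (a_ES, a_FS) morphology sweep
at fp = 0.10; formation runs at fp = 0.10/0.15 logging label, inertia
ratios, φ_O/φ_W, enclosed solvent and F-bump count per snapshot; and the
two-vesicle fusion protocol (duplicate one vesicle with its lumen contents,
place copies gap = 1 rc apart, colour by provenance tag, fill with fresh
solvent, run).  Published-scale presets carry the original conditions
verbatim — L = 40, 5–8×10⁵ steps for formation (192k–288k beads);
L = 70, 2×10⁷ steps for fusion — and their documented expected outcomes
(φ_O plateau ≈ 2.1% during the fp = 0.10 run; +0.24% solvent after fusion).
These are days-to-weeks of single-core compute and are provided as runnable
configurations, not as tests.  Desk-scale presets (minutes) are labelled
`scaled_down`.

### Finite-size limits of the desk scale

Scaled-down formation boxes (L = 15–20 at fp = 0.15) hold 76–180 molecules.
The desk self-assembly check (L = 15, 2×10⁵ steps, every snapshot
classified) reproducibly ends in a single compact solid-core micelle with
zero enclosed solvent in every frame: the radial profile shows E filling the
centre, O confined to the corona and F at the E/O interface.  This is the
expected finite-size outcome, not a failure of the dynamics — an E₁₂ arm
(contour ≈ 9.6 rc) spans the whole radius of a 76-molecule aggregate, so a
filled core costs no stretching, while hollowness pays bending and surface
energy that only aggregates much larger than single-chain reach recover;
the published-scale vesicles hold on the order of 10³ molecules.  An
enclosing vesicle at desk scale is therefore a rare stochastic event, not
the expected outcome, and the desk suite validates the machinery (forces,
thermostat, clustering, census) and the micelle-regime physics rather than
vesicle formation itself, which needs the larger presets.

## Numerical choices and degenerate inputs

* Exact bead overlap (r = 0): force undefined; treated as zero with a
  warning (probability-zero under continuous dynamics, transient under soft
  repulsion).
* Non-finite coordinates abort integration with an error naming the step;
  cell indexing is clamped so corrupted states cannot write out of bounds.
* Clusters of < 3 beads have no shape: degenerate-geometry error.
* Temperature of < 2 beads is undefined: error.
* Eigenvalues are clipped at zero before ratios; an exactly-degenerate
  smallest moment uses the smallest positive float as denominator.
* Problem sizes in the test suite: thermostat 3000 beads × 2.5×10⁴ steps;
  oracle equivalence N ≤ 2000; the desk formation run 10 125 beads ×
  2×10⁵ steps — sizes at which every stage of the pipeline is exercised on
  one CPU core in minutes.

## Known limitations

* NVT only; no barostat, electrostatics or angle potentials.
* The λ = ½ integrator's +2–3% temperature offset at Δt = 0.04 is inherited
  from the scheme, not corrected for.
* The interior census is voxel-geometric; its wall radius (0.5 rc) is an
  operational definition of "inside", and φ_O/φ_W inherit it.
* Single seed per state-diagram cell by default; morphology boundaries are
  stochastic and can shift between seeds.
* Desk-scale runs cannot reach the vesicle regime (see finite-size section).
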