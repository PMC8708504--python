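"""Numba kernels for the DPD force field and integrator.

Design notes
------------
* The pairwise random force uses a counter-based noise stream: the variate
  for pair (i, j) at integration step s is a pure function of
  (seed, s, min(i,j), max(i,j)).  This enforces the per-pair symmetry
  xi_ij = xi_ji exactly, makes the cell-list and all-pairs force paths share
  one noise stream regardless of traversal order, and makes long runs
  restartable from any snapshot.
* Variates are uniform on [-sqrt(3), sqrt(3)] (zero mean, unit variance); the
  thermostat requires only the first two moments of xi.
* The integrator is the Groot–Warren modified velocity-Verlet with
  lambda = 1/2: the predicted velocity entering the post-drift force
  evaluation is exactly the half-kicked velocity, so one force evaluation
  per step suffices.
"""

import numpy as np
from numba import njit

U64 = np.uint64
_M1 = U64(0x9E3779B97F4A7C15)
_M2 = U64(0xBF58476D1CE4E5B9)
_M3 = U64(0x94D049BB133111EB)
_MI = U64(0x85EBCA77C2B2AE63)
_MJ = U64(0xC2B2AE3D27D4EB4F)
_SQRT3 = np.sqrt(3.0)
_INV2_53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z ^ (z >> U64(30))) * _M2
    z = (z ^ (z >> U64(27))) * _M3
    return z ^ (z >> U64(31))


@njit(cache=True, inline="always")
def pair_noise(seed, step, i, j):
    """Unit-variance zero-mean variate for ordered pair (i < j) at a step."""
    z = (U64(seed) + U64(step) * _M1) ^ (U64(i) * _MI + U64(j) * _MJ)
    z = _mix64(z)
    u = float(z >> U64(11)) * _INV2_53  # uniform [0, 1)
    return (2.0 * u - 1.0) * _SQRT3


@njit(cache=True)
def _build_cells(pos, L, ncell):
    """Counting-sort beads into an ncell^3 periodic grid (edge >= r_cut)."""
    n = pos.shape[0]
    inv_edge = ncell / L
    cell_of = np.empty(n, dtype=np.int64)
    ncell3 = ncell * ncell * ncell
    count = np.zeros(ncell3 + 1, dtype=np.int64)
    for b in range(n):
        cx = int(pos[b, 0] * inv_edge)
        cy = int(pos[b, 1] * inv_edge)
        cz = int(pos[b, 2] * inv_edge)
        # clamp: guards x == L after wrap rounding, and keeps indexing
        # memory-safe for non-finite coordinates (caught by the blow-up check)
        if cx < 0:
            cx = 0
        elif cx >= ncell:
            cx = ncell - 1
        if cy < 0:
            cy = 0
        elif cy >= ncell:
            cy = ncell - 1
        if cz < 0:
            cz = 0
        elif cz >= ncell:
            cz = ncell - 1
        c = (cx * ncell + cy) * ncell + cz
        cell_of[b] = c
        count[c + 1] += 1
    for c in range(ncell3):
        count[c + 1] += count[c]
    order = np.empty(n, dtype=np.int64)
    fill = count[:ncell3].copy()
    for b in range(n):
        c = cell_of[b]
        order[fill[c]] = b
        fill[c] += 1
    return count, order


@njit(cache=True, inline="always")
def _pair_force(i, j, pos, vel, species, a_tab, gamma, sigma_dt, rc, L, halfL,
                seed, step, forces):
    """Accumulate conservative + dissipative + random force for one pair."""
    dx = pos[i, 0] - pos[j, 0]
    dy = pos[i, 1] - pos[j, 1]
    dz = pos[i, 2] - pos[j, 2]
    if dx > halfL:
        dx -= L
    elif dx < -halfL:
        dx += L
    if dy > halfL:
        dy -= L
    elif dy < -halfL:
        dy += L
    if dz > halfL:
        dz -= L
    elif dz < -halfL:
        dz += L
    r2 = dx * dx + dy * dy + dz * dz
    if r2 >= rc * rc:
        return
    if r2 <= 0.0:
        return  # exact overlap: force undefined, skip (soft potential)
    r = np.sqrt(r2)
    w = 1.0 - r / rc
    ex = dx / r
    ey = dy / r
    ez = dz / r
    vdotr = ((vel[i, 0] - vel[j, 0]) * ex
             + (vel[i, 1] - vel[j, 1]) * ey
             + (vel[i, 2] - vel[j, 2]) * ez)
    if i < j:
        xi = pair_noise(seed, step, i, j)
    else:
        xi = pair_noise(seed, step, j, i)
    a = a_tab[species[i], species[j]]
    fmag = a * w - gamma * w * w * vdotr + sigma_dt * w * xi
    fx = fmag * ex
    fy = fmag * ey
    fz = fmag * ez
    forces[i, 0] += fx
    forces[i, 1] += fy
    forces[i, 2] += fz
    forces[j, 0] -= fx
    forces[j, 1] -= fy
    forces[j, 2] -= fz


@njit(cache=True)
def nonbonded_forces_cells(pos, vel, species, a_tab, gamma, sigma, rc, L, dt,
                           seed, step, forces):
    """Cell-list nonbonded forces; accumulates into ``forces`` (not zeroed).

    Beads are gathered into cell-sorted scratch arrays so that each neighbour
    scan is a contiguous sweep, and the periodic image shift of a neighbour
    cell is precomputed so the inner loop carries no minimum-image branches.
    Noise keys use the original bead indices, so the result is independent of
    the cell traversal order up to floating-point summation order.
    """
    n = pos.shape[0]
    ncell = int(L / rc)
    if ncell < 3:
        # degenerate small box: fall back to all pairs
        nonbonded_forces_bruteforce(pos, vel, species, a_tab, gamma, sigma, rc,
                                    L, dt, seed, step, forces)
        return
    rc2 = rc * rc
    sigma_dt = sigma / np.sqrt(dt)
    start, order = _build_cells(pos, L, ncell)

    # gather into cell-sorted structure-of-arrays scratch
    xs = np.empty(n)
    ys = np.empty(n)
    zs = np.empty(n)
    vxs = np.empty(n)
    vys = np.empty(n)
    vzs = np.empty(n)
    sps = np.empty(n, dtype=np.int8)
    for u in range(n):
        b = order[u]
        xs[u] = pos[b, 0]
        ys[u] = pos[b, 1]
        zs[u] = pos[b, 2]
        vxs[u] = vel[b, 0]
        vys[u] = vel[b, 1]
        vzs[u] = vel[b, 2]
        sps[u] = species[b]
    fxs = np.zeros(n)
    fys = np.zeros(n)
    fzs = np.zeros(n)

    # half stencil: self cell (u<v within) + 13 forward neighbours
    offs = np.empty((13, 3), dtype=np.int64)
    k = 0
    for ox in range(-1, 2):
        for oy in range(-1, 2):
            for oz in range(-1, 2):
                if ox == 0 and oy == 0 and oz == 0:
                    continue
                if ox > 0 or (ox == 0 and (oy > 0 or (oy == 0 and oz > 0))):
                    offs[k, 0] = ox
                    offs[k, 1] = oy
                    offs[k, 2] = oz
                    k += 1

    for cx in range(ncell):
        for cy in range(ncell):
            for cz in range(ncell):
                c = (cx * ncell + cy) * ncell + cz
                a0 = start[c]
                a1 = start[c + 1]
                for q in range(14):
                    if q == 13:  # self cell
                        b0 = a0
                        b1 = a1
                        sx = 0.0
                        sy = 0.0
                        sz = 0.0
                    else:
                        nx = cx + offs[q, 0]
                        ny = cy + offs[q, 1]
                        nz = cz + offs[q, 2]
                        sx = 0.0
                        sy = 0.0
                        sz = 0.0
                        if nx < 0:
                            nx += ncell
                            sx = L
                        elif nx >= ncell:
                            nx -= ncell
                            sx = -L
                        if ny < 0:
                            ny += ncell
                            sy = L
                        elif ny >= ncell:
                            ny -= ncell
                            sy = -L
                        if nz < 0:
                            nz += ncell
                            sz = L
                        elif nz >= ncell:
                            nz -= ncell
                            sz = -L
                        d = (nx * ncell + ny) * ncell + nz
                        b0 = start[d]
                        b1 = start[d + 1]
                    for u in range(a0, a1):
                        xi = xs[u] + sx
                        yi = ys[u] + sy
                        zi = zs[u] + sz
                        v0 = u + 1 if q == 13 else b0
                        for v in range(v0, b1):
                            dx = xi - xs[v]
                            dy = yi - ys[v]
                            dz = zi - zs[v]
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 >= rc2 or r2 <= 0.0:
                                continue
                            r = np.sqrt(r2)
                            w = 1.0 - r / rc
                            ex = dx / r
                            ey = dy / r
                            ez = dz / r
                            vdotr = ((vxs[u] - vxs[v]) * ex
                                     + (vys[u] - vys[v]) * ey
                                     + (vzs[u] - vzs[v]) * ez)
                            i = order[u]
                            j = order[v]
                            if i < j:
                                xi_n = pair_noise(seed, step, i, j)
                            else:
                                xi_n = pair_noise(seed, step, j, i)
                            a = a_tab[sps[u], sps[v]]
                            fmag = (a * w - gamma * w * w * vdotr
                                    + sigma_dt * w * xi_n)
                            fx = fmag * ex
                            fy = fmag * ey
                            fz = fmag * ez
                            fxs[u] += fx
                            fys[u] += fy
                            fzs[u] += fz
                            fxs[v] -= fx
                            fys[v] -= fy
                            fzs[v] -= fz

    for u in range(n):
        b = order[u]
        forces[b, 0] += fxs[u]
        forces[b, 1] += fys[u]
        forces[b, 2] += fzs[u]


@njit(cache=True)
def nonbonded_forces_bruteforce(pos, vel, species, a_tab, gamma, sigma, rc, L,
                                dt, seed, step, forces):
    """O(N^2) all-pairs oracle sharing the cell-list noise stream."""
    n = pos.shape[0]
    halfL = 0.5 * L
    sigma_dt = sigma / np.sqrt(dt)
    for i in range(n):
        for j in range(i + 1, n):
            _pair_force(i, j, pos, vel, species, a_tab, gamma, sigma_dt, rc, L,
                        halfL, seed, step, forces)


@njit(cache=True)
def bond_forces(pos, bonds, spring_C, L, forces):
    """Zero-rest-length harmonic bonds: each partner pulled toward the other
    with magnitude C*r_ij (minimum image)."""
    halfL = 0.5 * L
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if dx > halfL:
            dx -= L
        elif dx < -halfL:
            dx += L
        if dy > halfL:
            dy -= L
        elif dy < -halfL:
            dy += L
        if dz > halfL:
            dz -= L
        elif dz < -halfL:
            dz += L
        forces[i, 0] -= spring_C * dx
        forces[i, 1] -= spring_C * dy
        forces[i, 2] -= spring_C * dz
        forces[j, 0] += spring_C * dx
        forces[j, 1] += spring_C * dy
        forces[j, 2] += spring_C * dz


@njit(cache=True)
def total_forces(pos, vel, species, bonds, a_tab, gamma, sigma, rc, L, dt,
                 spring_C, seed, step):
    forces = np.zeros_like(pos)
    nonbonded_forces_cells(pos, vel, species, a_tab, gamma, sigma, rc, L, dt,
                           seed, step, forces)
    if bonds.shape[0] > 0:
        bond_forces(pos, bonds, spring_C, L, forces)
    return forces


@njit(cache=True)
def step_kernel(pos, vel, forces, species, bonds, a_tab, gamma, sigma, rc, L,
                dt, mass, spring_C, seed, step_index):
    """One Groot–Warren modified velocity-Verlet step (lambda = 1/2), in place.

    ``forces`` must hold the forces consistent with the current state (noise
    key ``step_index``); on return it holds the forces at the new state (noise
    key ``step_index + 1``).  Returns nothing; mutates pos, vel, forces.
    """
    n = pos.shape[0]
    half_dt_m = 0.5 * dt / mass
    for b in range(n):
        for d in range(3):
            vel[b, d] += half_dt_m * forces[b, d]
            x = pos[b, d] + dt * vel[b, d]
            x -= np.floor(x / L) * L
            pos[b, d] = x
    forces[:, :] = 0.0
    nonbonded_forces_cells(pos, vel, species, a_tab, gamma, sigma, rc, L, dt,
                           seed, step_index + 1, forces)
    if bonds.shape[0] > 0:
        bond_forces(pos, bonds, spring_C, L, forces)
    for b in range(n):
        for d in range(3):
            vel[b, d] += half_dt_m * forces[b, d]


@njit(cache=True)
def run_kernel(pos, vel, forces, species, bonds, a_tab, gamma, sigma, rc, L,
               dt, mass, spring_C, seed, step_offset, n_steps, log_every):
    """Advance ``n_steps`` steps; log kinetic temperature and momentum.

    Returns (log_steps, log_temperature, log_momentum_norm, blowup_step);
    blowup_step is -1 on success, else the first step with non-finite state.
    """
    n = pos.shape[0]
    n_logs = n_steps // log_every + 1
    log_steps = np.empty(n_logs, dtype=np.int64)
    log_temp = np.empty(n_logs, dtype=np.float64)
    log_mom = np.empty(n_logs, dtype=np.float64)
    nlog = 0
    for s in range(n_steps):
        step_kernel(pos, vel, forces, species, bonds, a_tab, gamma, sigma, rc,
                    L, dt, mass, spring_C, seed, step_offset + s)
        if (s + 1) % log_every == 0 or s == n_steps - 1:
            px = 0.0
            py = 0.0
            pz = 0.0
            ke = 0.0
            ok = True
            for b in range(n):
                vx = vel[b, 0]
                vy = vel[b, 1]
                vz = vel[b, 2]
                if not (np.isfinite(vx) and np.isfinite(pos[b, 0])):
                    ok = False
                px += mass * vx
                py += mass * vy
                pz += mass * vz
                ke += mass * (vx * vx + vy * vy + vz * vz)
            if not ok:
                return (log_steps[:nlog], log_temp[:nlog], log_mom[:nlog],
                        step_offset + s + 1)
            if nlog < n_logs:
                log_steps[nlog] = step_offset + s + 1
                log_temp[nlog] = ke / (3.0 * n - 3.0)
                log_mom[nlog] = np.sqrt(px * px + py * py + pz * pz)
                nlog += 1
    return log_steps[:nlog], log_temp[:nlog], log_mom[:nlog], -1
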