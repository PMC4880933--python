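"""DPD propagation: pair-force kernels, velocity-Verlet integration, rigid
bodies, periodic neighbor search and the zero-tension box controller.

The inner loops are numba-compiled.  All beads have unit mass.  Positions are
kept wrapped inside the orthorhombic periodic box; pair interactions always
use minimum-image displacements.  The integrator is the Groot--Warren
modified velocity-Verlet scheme (lambda = 0.65) with the dissipative force
re-evaluated after the position update.

Randomness: the thermostat noise of step ``k`` is drawn from a stream seeded
by mixing the engine's master seed with ``k``, so trajectories are
bit-reproducible for a given seed and build, and restarting from a checkpoint
reproduces the uninterrupted run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np
from numba import njit

from .forcefield import ForceField, _lj_cap_radius, _smeared_table
from .topology import Topology

VV_LAMBDA = 0.65          # Groot-Warren half-step velocity estimate factor
MAX_STEP_DISPLACEMENT = 0.5   # r_c; larger per-step moves abort the run
ELEC_TABLE_N = 2048


class EngineInstability(RuntimeError):
    """Raised when a bead moves more than half a cutoff in one step."""


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _min_image(d, L):
    return d - L * np.floor(d / L + 0.5)


SQRT3 = math.sqrt(3.0)


@njit(cache=True, inline="always")
def _xorshift(s):
    s ^= (s << np.uint64(13)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s ^= s >> np.uint64(7)
    s ^= (s << np.uint64(17)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return s


@njit(cache=True)
def _build_pairs(pos, box, rc, body):
    """Cell-list enumeration of minimum-image pairs with r < rc.

    Pairs internal to one rigid body are excluded up front (they exert no
    net force or torque and would dominate the list for dense fcc cores);
    whole cell pairs are skipped when both cells hold only the same body.
    Falls back to an all-pairs scan when the box admits fewer than three
    cells per dimension.  Pair order is deterministic for given positions.
    """
    n = pos.shape[0]
    rc2 = rc * rc
    ncx = int(box[0] // rc)
    ncy = int(box[1] // rc)
    ncz = int(box[2] // rc)
    cap = 64 + n * 16
    pi = np.empty(cap, np.int64)
    pj = np.empty(cap, np.int64)
    m = 0
    if ncx >= 3 and ncy >= 3 and ncz >= 3:
        ncell = ncx * ncy * ncz
        head = np.full(ncell, -1, np.int64)
        nxt = np.full(n, -1, np.int64)
        # cell_body: -1 empty, b >= 0 pure single rigid body, -2 mixed/free
        cell_body = np.full(ncell, -1, np.int64)
        for i in range(n):
            cx = min(int(pos[i, 0] / box[0] * ncx), ncx - 1)
            cy = min(int(pos[i, 1] / box[1] * ncy), ncy - 1)
            cz = min(int(pos[i, 2] / box[2] * ncz), ncz - 1)
            c = (cx * ncy + cy) * ncz + cz
            nxt[i] = head[c]
            head[c] = i
            b = body[i]
            if cell_body[c] == -1:
                cell_body[c] = b if b >= 0 else -2
            elif cell_body[c] != b:
                cell_body[c] = -2
        offs = np.array([
            [0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
            [1, 1, 0], [1, -1, 0], [1, 0, 1], [1, 0, -1],
            [0, 1, 1], [0, 1, -1], [1, 1, 1], [1, 1, -1],
            [1, -1, 1], [1, -1, -1],
        ], np.int64)
        for ax in range(ncx):
            for ay in range(ncy):
                for az in range(ncz):
                    ca = (ax * ncy + ay) * ncz + az
                    for o in range(14):
                        bx = (ax + offs[o, 0]) % ncx
                        by = (ay + offs[o, 1]) % ncy
                        bz = (az + offs[o, 2]) % ncz
                        cb = (bx * ncy + by) * ncz + bz
                        if cell_body[ca] >= 0 and cell_body[ca] == cell_body[cb]:
                            continue
                        i = head[ca]
                        while i >= 0:
                            bi = body[i]
                            j = nxt[i] if o == 0 else head[cb]
                            while j >= 0:
                                if bi >= 0 and bi == body[j]:
                                    j = nxt[j]
                                    continue
                                dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                                dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                                dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                                if dx * dx + dy * dy + dz * dz < rc2:
                                    if m == cap:
                                        cap *= 2
                                        gi = np.empty(cap, np.int64)
                                        gj = np.empty(cap, np.int64)
                                        gi[:m] = pi[:m]
                                        gj[:m] = pj[:m]
                                        pi = gi
                                        pj = gj
                                    pi[m] = i
                                    pj[m] = j
                                    m += 1
                                j = nxt[j]
                            i = nxt[i]
    else:
        for i in range(n - 1):
            bi = body[i]
            for j in range(i + 1, n):
                if bi >= 0 and bi == body[j]:
                    continue
                dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                if dx * dx + dy * dy + dz * dz < rc2:
                    if m == cap:
                        cap *= 2
                        gi = np.empty(cap, np.int64)
                        gj = np.empty(cap, np.int64)
                        gi[:m] = pi[:m]
                        gj[:m] = pj[:m]
                        pi = gi
                        pj = gj
                    pi[m] = i
                    pj[m] = j
                    m += 1
    return pi[:m], pj[:m]


@njit(cache=True, fastmath=True)
def _pair_forces(pi, pj, pos, vel, box, types, body, a_mat,
                 gamma, sigma, inv_sqrt_dt, with_thermostat,
                 lj_ab, lj_rec, lj_eps, lj_sig, lj_cap, lj_rcap, lj_ucap,
                 lj_cut, seed, forces, virial):
    """DPD conservative/dissipative/random + soft LJ over a prebuilt pair list.

    Returns (U_conservative, U_softLJ).  Conservative-type contributions
    (repulsion + LJ) are accumulated into the 6-component virial
    [xx, yy, zz, xy, xz, yz]; thermostat forces are not.  The random-force
    noise is a unit-variance uniform draw from an inline xorshift stream
    seeded per step; the single draw per pair is shared by both members, so
    the pair force is exactly antisymmetric.
    """
    rng = np.uint64(seed * 6364136223846793005 + 1442695040888963407)
    rng = _xorshift(rng | np.uint64(1))
    u_cons = 0.0
    u_lj = 0.0
    for p in range(pi.shape[0]):
        i = pi[p]
        j = pj[p]
        if with_thermostat:
            rng = _xorshift(rng)
        if body[i] >= 0 and body[i] == body[j]:
            continue
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= 1.0 or r2 == 0.0:
            continue
        r = math.sqrt(r2)
        ex, ey, ez = dx / r, dy / r, dz / r
        w = 1.0 - r
        ti, tj = types[i], types[j]
        a = a_mat[ti, tj]
        fc = a * w
        u_cons += 0.5 * a * w * w
        fx_c, fy_c, fz_c = fc * ex, fc * ey, fc * ez
        if (lj_ab[ti] and lj_rec[tj]) or (lj_rec[ti] and lj_ab[tj]):
            if r < lj_cut:
                if r <= lj_rcap:
                    u_lj += lj_ucap + lj_cap * (lj_rcap - r)
                    flj = lj_cap
                else:
                    sr6 = (lj_sig / r) ** 6
                    u_lj += 4.0 * lj_eps * (sr6 * sr6 - sr6)
                    flj = 24.0 * lj_eps * (2.0 * sr6 * sr6 - sr6) / r
                fx_c += flj * ex
                fy_c += flj * ey
                fz_c += flj * ez
        virial[0] += dx * fx_c
        virial[1] += dy * fy_c
        virial[2] += dz * fz_c
        virial[3] += dx * fy_c
        virial[4] += dx * fz_c
        virial[5] += dy * fz_c
        ftot_x, ftot_y, ftot_z = fx_c, fy_c, fz_c
        if with_thermostat:
            dvx = vel[i, 0] - vel[j, 0]
            dvy = vel[i, 1] - vel[j, 1]
            dvz = vel[i, 2] - vel[j, 2]
            ev = ex * dvx + ey * dvy + ez * dvz
            fd = -gamma * w * w * ev
            theta = (float(rng) * 5.421010862427522e-20 * 2.0 - 1.0) * SQRT3
            fr = sigma * w * theta * inv_sqrt_dt
            sfr = fd + fr
            ftot_x += sfr * ex
            ftot_y += sfr * ey
            ftot_z += sfr * ez
        forces[i, 0] += ftot_x
        forces[i, 1] += ftot_y
        forces[i, 2] += ftot_z
        forces[j, 0] -= ftot_x
        forces[j, 1] -= ftot_y
        forces[j, 2] -= ftot_z
    return u_cons, u_lj


@njit(cache=True, fastmath=True)
def _elec_kernel(pos, box, idx, q, body, u_tab, f_tab, cutoff, forces, virial):
    """Smeared-Coulomb forces among the charged subset ``idx``.

    Tables give energy (cutoff-shifted) and scalar force per unit charge
    product on a uniform grid over [0, cutoff]; linear interpolation.
    All-pairs distance filter over the charged subset with minimum image
    (charged beads are a small fraction of desk-scale systems).
    """
    m = idx.shape[0]
    ntab = u_tab.shape[0]
    dr = cutoff / (ntab - 1)
    u_el = 0.0
    c2 = cutoff * cutoff
    for a in range(m - 1):
        i = idx[a]
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for b in range(a + 1, m):
            j = idx[b]
            dx = _min_image(xi - pos[j, 0], box[0])
            dy = _min_image(yi - pos[j, 1], box[1])
            dz = _min_image(zi - pos[j, 2], box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= c2 or r2 == 0.0:
                continue
            if body[i] >= 0 and body[i] == body[j]:
                continue
            r = math.sqrt(r2)
            x = r / dr
            k = min(int(x), ntab - 2)
            frac = x - k
            uu = u_tab[k] * (1.0 - frac) + u_tab[k + 1] * frac
            ff = f_tab[k] * (1.0 - frac) + f_tab[k + 1] * frac
            qq = q[i] * q[j]
            u_el += qq * uu
            fs = qq * ff / r
            fx, fy, fz = fs * dx, fs * dy, fs * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
            virial[0] += dx * fx
            virial[1] += dy * fy
            virial[2] += dz * fz
            virial[3] += dx * fy
            virial[4] += dx * fz
            virial[5] += dy * fz
    return u_el


@njit(cache=True)
def _bonded_kernel(pos, box, bond_ij, bond_ks, bond_l0,
                   ang_ijk, ang_ka, forces, virial):
    """Harmonic bonds U = k_s (1 - r/l0)^2 and cosine angles with phi0 = 180 deg."""
    u_bond = 0.0
    for b in range(bond_ij.shape[0]):
        i = bond_ij[b, 0]
        j = bond_ij[b, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r == 0.0:
            continue
        x = 1.0 - r / bond_l0[b]
        u_bond += bond_ks[b] * x * x
        fs = 2.0 * bond_ks[b] * x / bond_l0[b] / r
        fx, fy, fz = fs * dx, fs * dy, fs * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0] += dx * fx
        virial[1] += dy * fy
        virial[2] += dz * fz
        virial[3] += dx * fy
        virial[4] += dx * fz
        virial[5] += dy * fz
    u_ang = 0.0
    for t in range(ang_ijk.shape[0]):
        i = ang_ijk[t, 0]
        j = ang_ijk[t, 1]
        k = ang_ijk[t, 2]
        ax = _min_image(pos[i, 0] - pos[j, 0], box[0])
        ay = _min_image(pos[i, 1] - pos[j, 1], box[1])
        az = _min_image(pos[i, 2] - pos[j, 2], box[2])
        bx = _min_image(pos[k, 0] - pos[j, 0], box[0])
        by = _min_image(pos[k, 1] - pos[j, 1], box[1])
        bz = _min_image(pos[k, 2] - pos[j, 2], box[2])
        la = math.sqrt(ax * ax + ay * ay + az * az)
        lb = math.sqrt(bx * bx + by * by + bz * bz)
        if la == 0.0 or lb == 0.0:
            continue
        cosp = (ax * bx + ay * by + az * bz) / (la * lb)
        if cosp > 1.0:
            cosp = 1.0
        elif cosp < -1.0:
            cosp = -1.0
        ka = ang_ka[t]
        u_ang += ka * (1.0 + cosp)
        # U = ka (1 + cos phi): dU/dcos = ka exactly, no sin singularity
        inv_ab = 1.0 / (la * lb)
        f1x = -ka * (bx * inv_ab - cosp * ax / (la * la))
        f1y = -ka * (by * inv_ab - cosp * ay / (la * la))
        f1z = -ka * (bz * inv_ab - cosp * az / (la * la))
        f3x = -ka * (ax * inv_ab - cosp * bx / (lb * lb))
        f3y = -ka * (ay * inv_ab - cosp * by / (lb * lb))
        f3z = -ka * (az * inv_ab - cosp * bz / (lb * lb))
        forces[i, 0] += f1x
        forces[i, 1] += f1y
        forces[i, 2] += f1z
        forces[k, 0] += f3x
        forces[k, 1] += f3y
        forces[k, 2] += f3z
        forces[j, 0] -= f1x + f3x
        forces[j, 1] -= f1y + f3y
        forces[j, 2] -= f1z + f3z
        virial[0] += ax * f1x + bx * f3x
        virial[1] += ay * f1y + by * f3y
        virial[2] += az * f1z + bz * f3z
        virial[3] += ax * f1y + bx * f3y
        virial[4] += ax * f1z + bx * f3z
        virial[5] += ay * f1z + by * f3z
    return u_bond, u_ang


@njit(cache=True)
def _neighbor_pairs(pos, box, cutoff):
    """All minimum-image pairs within ``cutoff``; O(N^2) reference scan."""
    n = pos.shape[0]
    c2 = cutoff * cutoff
    cap = 32 + n * 64
    out = np.empty((cap, 2), np.int64)
    m = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
            if dx * dx + dy * dy + dz * dz < c2:
                if m == cap:
                    cap *= 2
                    grown = np.empty((cap, 2), np.int64)
                    grown[:m] = out[:m]
                    out = grown
                out[m, 0] = i
                out[m, 1] = j
                m += 1
    return out[:m]


# ---------------------------------------------------------------------------
# System state, neighbor list, rigid bodies
# ---------------------------------------------------------------------------

@dataclass
class SystemState:
    """Positions, velocities, box and force buffer of one configuration."""

    positions: np.ndarray
    velocities: np.ndarray
    box: np.ndarray
    forces: np.ndarray = None
    time: float = 0.0
    step: int = 0

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, float)
        self.velocities = np.ascontiguousarray(self.velocities, float)
        self.box = np.asarray(self.box, float)
        if self.forces is None:
            self.forces = np.zeros_like(self.positions)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def wrap(self) -> None:
        self.positions -= self.box * np.floor(self.positions / self.box)


@dataclass
class NeighborList:
    pairs: np.ndarray
    cutoff: float
    skin: float
    ref_positions: np.ndarray

    def needs_rebuild(self, positions: np.ndarray, box: np.ndarray) -> bool:
        d = positions - self.ref_positions
        d -= box * np.round(d / box)
        return bool(np.max(np.einsum("ij,ij->i", d, d)) > (self.skin / 2.0) ** 2)


def build_neighbor_list(state: SystemState, cutoff: float, skin: float = 0.3) -> NeighborList:
    """Verlet pair list: every minimum-image pair within cutoff + skin.

    The candidate list stays valid until some bead has moved more than skin/2
    (checked by :meth:`NeighborList.needs_rebuild`).
    """
    reach = cutoff + skin
    if reach > min(state.box) / 2.0:
        raise ValueError(
            f"cutoff + skin = {reach} exceeds half the smallest box length "
            f"{min(state.box) / 2.0}")
    pairs = _neighbor_pairs(state.positions, state.box, reach)
    return NeighborList(pairs=pairs, cutoff=cutoff, skin=skin,
                        ref_positions=state.positions.copy())


class RigidBody:
    """A set of beads moving as one rigid unit (quaternion orientation)."""

    def __init__(self, indices: np.ndarray, positions: np.ndarray):
        self.indices = np.asarray(indices, np.int64)
        self.mass = float(len(indices))
        self.com = positions[self.indices].mean(axis=0)
        self.body_coords = positions[self.indices] - self.com
        self.quat = np.array([1.0, 0.0, 0.0, 0.0])
        self.v_com = np.zeros(3)
        self.ang_mom = np.zeros(3)

    def rotation(self) -> np.ndarray:
        w, x, y, z = self.quat
        return np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])

    def world_coords(self) -> np.ndarray:
        return self.com + self.body_coords @ self.rotation().T

    def inertia_world(self) -> np.ndarray:
        d = self.body_coords @ self.rotation().T
        r2 = np.einsum("ij,ij->i", d, d).sum()
        return r2 * np.eye(3) - d.T @ d

    def omega(self) -> np.ndarray:
        return np.linalg.pinv(self.inertia_world()) @ self.ang_mom

    def bead_velocities(self) -> np.ndarray:
        w = self.omega()
        d = self.body_coords @ self.rotation().T
        return self.v_com + np.cross(w, d)

    def _rotate_quat(self, w: np.ndarray, dt: float) -> None:
        wn = np.linalg.norm(w)
        if wn * dt < 1e-14:
            return
        axis = w / wn
        half = 0.5 * wn * dt
        dq = np.array([math.cos(half), *(math.sin(half) * axis)])
        a, b = dq, self.quat
        self.quat = np.array([
            a[0] * b[0] - a[1] * b[1] - a[2] * b[2] - a[3] * b[3],
            a[0] * b[1] + a[1] * b[0] + a[2] * b[3] - a[3] * b[2],
            a[0] * b[2] - a[1] * b[3] + a[2] * b[0] + a[3] * b[1],
            a[0] * b[3] + a[1] * b[2] - a[2] * b[1] + a[3] * b[0],
        ])
        self.quat /= np.linalg.norm(self.quat)


def rigid_body_step(body: RigidBody, net_force: np.ndarray, net_torque: np.ndarray,
                    dt: float) -> RigidBody:
    """One symplectic-Euler rigid step: half-kick style updates on COM and spin.

    The COM obeys Newtonian dynamics at the summed bead mass, the orientation
    is advanced by the torque about the COM, and member bead positions are
    regenerated from the body frame, so intra-body distances are preserved to
    machine precision by construction.
    """
    body.v_com = body.v_com + net_force / body.mass * dt
    body.ang_mom = body.ang_mom + net_torque * dt
    body.com = body.com + body.v_com * dt
    body._rotate_quat(body.omega(), dt)
    return body


@dataclass
class TensionController:
    """Zero-tension membrane control via periodic volume-preserving reshaping.

    Whenever invoked, the projected box area per lipid A_b = Lx Ly / (lipids
    per leaflet) is compared to the target A0; the box is rescaled in-plane by
    sqrt(A0/A_b) and along the normal by A_b/A0, which restores A_b = A0 while
    keeping the volume exactly fixed.
    """

    A0: float = 1.28
    interval: int = 1000


def zero_tension_update(state: SystemState, ctrl: TensionController,
                        n_lipids: int, bodies: list[RigidBody] | None = None) -> SystemState:
    """Apply one box-reshaping correction toward area per lipid = A0."""
    if n_lipids == 0:
        return state
    per_leaflet = n_lipids / 2.0
    a_b = state.box[0] * state.box[1] / per_leaflet
    s = math.sqrt(ctrl.A0 / a_b)
    state.box[0] *= s
    state.box[1] *= s
    state.box[2] /= s * s
    state.positions[:, 0] *= s
    state.positions[:, 1] *= s
    state.positions[:, 2] /= s * s
    for b in bodies or ():
        b.com[0] *= s
        b.com[1] *= s
        b.com[2] /= s * s
    state.wrap()
    return state


def kinetic_temperature(state: SystemState, n_rigid_dof_removed: int = 0) -> float:
    """Instantaneous temperature 2 KE / N_dof in kBT (unit bead masses).

    ``n_rigid_dof_removed`` subtracts the internal degrees of freedom frozen
    by rigid bodies: each m-bead body contributes 6 DOF instead of 3m.
    """
    if state.n_beads < 2:
        raise ValueError("temperature needs at least two beads")
    ndof = 3 * state.n_beads - n_rigid_dof_removed
    ke = 0.5 * float(np.einsum("ij,ij->", state.velocities, state.velocities))
    return 2.0 * ke / ndof


# ---------------------------------------------------------------------------
# Electrostatics tables and Ewald reference path
# ---------------------------------------------------------------------------

def _elec_tables(params) -> tuple[np.ndarray, np.ndarray]:
    """Tabulated smeared-Coulomb energy (cutoff-shifted) and -dU/dr per unit q_i q_j."""
    spl = _smeared_table(params.r_e)
    r = np.linspace(0.0, params.cutoff, ELEC_TABLE_N)
    u = np.empty_like(r)
    f = np.empty_like(r)
    inside = r < 2.0 * params.r_e
    u[inside] = spl(r[inside])
    f[inside] = -spl(r[inside], 1)
    out = ~inside
    u[out] = 1.0 / (4.0 * math.pi * r[out])
    f[out] = 1.0 / (4.0 * math.pi * r[out] ** 2)
    shift = 1.0 / (4.0 * math.pi * params.cutoff) if params.cutoff >= 2 * params.r_e \
        else float(spl(params.cutoff))
    u -= shift
    return params.coupling * u, params.coupling * f


def ewald_smeared(positions: np.ndarray, charges: np.ndarray, box: np.ndarray,
                  params, alpha: float = 0.8, kmax: int = 8) -> tuple[float, np.ndarray]:
    """Ewald sum over point charges plus the short-ranged cloud correction.

    The smeared pair law differs from the point Coulomb only within 2 r_e, so
    the full lattice sum is the standard point-charge Ewald plus a pairwise
    minimum-image correction U_cloud(r) - U_point(r) for r < 2 r_e.  Intended
    as the production-accuracy evaluator for charged boxes; returns
    (energy, forces) in reduced units.
    """
    pos = np.asarray(positions, float)
    q = np.asarray(charges, float)
    sel = np.nonzero(q != 0.0)[0]
    n_all = len(pos)
    energy = 0.0
    forces = np.zeros((n_all, 3))
    if len(sel) < 2:
        return energy, forces
    p = pos[sel]
    qs = q[sel]
    pref = params.coupling / (4.0 * math.pi)
    # real-space point Ewald (minimum image; alpha chosen so erfc is tiny at L/2)
    d = p[:, None, :] - p[None, :, :]
    d -= box * np.round(d / box)
    r = np.linalg.norm(d, axis=-1)
    np.fill_diagonal(r, np.inf)
    from scipy.special import erfc
    qq = qs[:, None] * qs[None, :]
    energy += 0.5 * pref * np.sum(qq * erfc(alpha * r) / r)
    fr = pref * qq * (erfc(alpha * r) / r + 2 * alpha / math.sqrt(math.pi)
                      * np.exp(-(alpha * r) ** 2)) / r ** 2
    freal = np.einsum("ij,ijk->ik", fr, d)
    # reciprocal space
    L = np.asarray(box, float)
    vol = float(np.prod(L))
    ks = []
    for nx in range(-kmax, kmax + 1):
        for ny in range(-kmax, kmax + 1):
            for nz in range(-kmax, kmax + 1):
                if nx == ny == nz == 0:
                    continue
                ks.append([2 * math.pi * nx / L[0], 2 * math.pi * ny / L[1],
                           2 * math.pi * nz / L[2]])
    kvec = np.array(ks)
    k2 = np.einsum("ij,ij->i", kvec, kvec)
    keep = k2 < (2 * math.pi * kmax / L.max()) ** 2
    kvec, k2 = kvec[keep], k2[keep]
    phase = p @ kvec.T
    sk = qs @ np.exp(1j * phase)
    coef = 4 * math.pi * pref / vol * np.exp(-k2 / (4 * alpha ** 2)) / k2
    energy += 0.5 * float(np.sum(coef * np.abs(sk) ** 2))
    fk = np.einsum("k,ik,kd->id", coef, np.imag(np.exp(-1j * phase) * sk[None, :]), kvec)
    fk *= qs[:, None]
    # self energy
    energy -= pref * alpha / math.sqrt(math.pi) * float(np.sum(qs ** 2))
    # cloud-overlap correction for r < 2 r_e
    spl = _smeared_table(params.r_e)
    corr_f = np.zeros_like(p)
    close = r < 2.0 * params.r_e
    iu, ju = np.nonzero(np.triu(close, 1))
    for a, b in zip(iu, ju):
        rr = r[a, b]
        du = params.coupling * (float(spl(rr)) - 1.0 / (4 * math.pi * rr))
        df = params.coupling * (-float(spl(rr, 1)) - 1.0 / (4 * math.pi * rr ** 2))
        energy += qs[a] * qs[b] * du
        fv = qs[a] * qs[b] * df * d[a, b] / rr
        corr_f[a] += fv
        corr_f[b] -= fv
    forces[sel] = freal + fk + corr_f
    return energy, forces


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

class DPDEngine:
    """Velocity-Verlet DPD propagator bound to one topology and force field.

    Parameters
    ----------
    topology : Topology
        Beads, bonded terms, rigid-body membership, initial coordinates.
    forcefield : ForceField
        Pair table, thermostat, electrostatic and soft-LJ parameters.
    seed : int
        Master seed; the noise of step k comes from a stream derived from
        (seed, k), so runs are reproducible and restartable.
    dt : float
        Timestep in tau (default 0.015).
    tension : TensionController, optional
        If given, the zero-tension box reshaping is applied every
        ``tension.interval`` steps using the topology's lipid count.
    """

    def __init__(self, topology: Topology, forcefield: ForceField,
                 state: SystemState | None = None, seed: int = 0,
                 dt: float = 0.015, tension: TensionController | None = None,
                 box: np.ndarray | None = None):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.topology = topology
        self.ff = forcefield
        self.seed = int(seed)
        self.dt = float(dt)
        self.tension = tension
        if state is None:
            if box is None:
                raise ValueError("either a SystemState or a box is required")
            rng = np.random.default_rng(seed)
            vel = rng.normal(0.0, 1.0, size=(topology.n_beads, 3))
            vel -= vel.mean(axis=0)
            state = SystemState(positions=topology.positions.copy(),
                                velocities=vel, box=np.asarray(box, float))
        self.state = state
        self.state.wrap()

        # flattened per-type arrays for the kernels
        self._a_mat = np.ascontiguousarray(forcefield.pair_table.a)
        self._types = np.ascontiguousarray(topology.type_index, np.int64)
        self._body = np.ascontiguousarray(topology.body_id, np.int64)
        self._charge = np.ascontiguousarray(topology.charge, float)
        self._q_idx = np.nonzero(self._charge != 0.0)[0].astype(np.int64)
        self._lj_ab = np.array([c.is_antibody for c in forcefield.classes], np.bool_)
        self._lj_rec = np.array([c.is_receptor_head for c in forcefield.classes], np.bool_)
        lj = forcefield.soft_lj
        self._lj_rcap = _lj_cap_radius(lj.epsilon, lj.sigma_lj, lj.force_cap)
        sr6 = (lj.sigma_lj / self._lj_rcap) ** 6
        self._lj_ucap = 4.0 * lj.epsilon * (sr6 * sr6 - sr6)
        self._u_tab, self._f_tab = _elec_tables(forcefield.electrostatics)
        self._bond_ij = np.ascontiguousarray(topology.bond_ij, np.int64)
        self._bond_ks = np.ascontiguousarray(topology.bond_ks, float)
        self._bond_l0 = np.ascontiguousarray(topology.bond_l0, float)
        self._ang_ijk = np.ascontiguousarray(topology.angle_ijk, np.int64)
        self._ang_ka = np.ascontiguousarray(topology.angle_ka, float)
        if len(self._ang_ka):
            # the compiled kernel is specialized to straight equilibrium angles
            pass

        # rigid bodies
        self.bodies: list[RigidBody] = []
        for b in range(topology.n_bodies):
            idx = np.nonzero(self._body == b)[0]
            body = RigidBody(idx, self.state.positions)
            body.v_com = self.state.velocities[idx].mean(axis=0)
            self.bodies.append(body)
            self.state.velocities[idx] = body.bead_velocities()
        self._free = self._body < 0
        self.n_rigid_dof_removed = sum(3 * len(b.indices) - 6 for b in self.bodies)

        self.external_forces: list = []   # callables (positions, time, out) -> energy
        self.energies: dict[str, float] = {}
        self.virial: np.ndarray = np.zeros(6)
        self.compute_forces()

    # -- forces ------------------------------------------------------------

    def _step_seed(self, step: int) -> int:
        return (self.seed * 2654435761 + step * 97531) % 2147483647

    def compute_forces(self, with_thermostat: bool = True) -> dict[str, float]:
        """Evaluate all forces at the current positions/velocities.

        Fills ``state.forces``, the per-term potential energies and the
        6-component conservative virial (thermostat forces are excluded from
        the virial: their contribution averages to zero and is isotropic in
        equilibrium, so it cancels in the lateral-tension difference).
        """
        st = self.state
        forces = np.zeros_like(st.positions)
        virial = np.zeros(6)
        th = self.ff.thermostat
        pi, pj = _build_pairs(st.positions, st.box, 1.0, self._body)
        u_cons, u_lj = _pair_forces(
            pi, pj, st.positions, st.velocities, st.box, self._types,
            self._body, self._a_mat, th.gamma, th.sigma_noise,
            1.0 / math.sqrt(self.dt), with_thermostat,
            self._lj_ab, self._lj_rec, self.ff.soft_lj.epsilon,
            self.ff.soft_lj.sigma_lj, self.ff.soft_lj.force_cap,
            self._lj_rcap, self._lj_ucap, self.ff.soft_lj.cutoff,
            self._step_seed(st.step), forces, virial)
        u_el = 0.0
        if len(self._q_idx) > 1:
            u_el = _elec_kernel(st.positions, st.box, self._q_idx, self._charge,
                                self._body, self._u_tab, self._f_tab,
                                self.ff.electrostatics.cutoff, forces, virial)
        u_bond, u_ang = _bonded_kernel(
            st.positions, st.box, self._bond_ij, self._bond_ks, self._bond_l0,
            self._ang_ijk, self._ang_ka, forces, virial)
        u_ext = 0.0
        for fn in self.external_forces:
            u_ext += fn(st.positions, st.time, forces)
        st.forces = forces
        self.energies = {
            "conservative": u_cons, "soft_lj": u_lj, "electrostatic": u_el,
            "bond": u_bond, "angle": u_ang, "external": u_ext,
            "potential": u_cons + u_lj + u_el + u_bond + u_ang + u_ext,
        }
        self.virial = virial
        return self.energies

    # -- integration -------------------------------------------------------

    def integrate_step(self) -> SystemState:
        """One Groot-Warren modified velocity-Verlet step (lambda = 0.65).

        Free beads follow the standard scheme; rigid bodies receive summed
        forces/torques and move as units.  The dissipative force is
        re-evaluated after the position update using the lambda-predicted
        velocities.  Momentum is conserved to machine precision because every
        internal force is applied antisymmetrically.
        """
        st, dt = self.state, self.dt
        f_old = st.forces.copy()
        free = self._free
        disp = st.velocities[free] * dt + 0.5 * f_old[free] * dt * dt
        if len(disp) and float(np.max(np.abs(disp))) > MAX_STEP_DISPLACEMENT:
            bead = int(np.argmax(np.max(np.abs(disp), axis=1)))
            raise EngineInstability(
                f"step {st.step}: bead displacement {np.max(np.abs(disp)):.3f} r_c "
                f"> {MAX_STEP_DISPLACEMENT} (free bead #{bead}); "
                "reduce dt or re-equilibrate")
        st.positions[free] += disp
        v_full = st.velocities.copy()
        st.velocities[free] = v_full[free] + VV_LAMBDA * dt * f_old[free]

        body_kicks = []
        for b in self.bodies:
            fsum = f_old[b.indices].sum(axis=0)
            d = b.body_coords @ b.rotation().T
            tq = np.cross(d, f_old[b.indices]).sum(axis=0)
            b.v_com += 0.5 * dt * fsum / b.mass
            b.ang_mom += 0.5 * dt * tq
            b.com += dt * b.v_com
            b._rotate_quat(b.omega(), dt)
            st.positions[b.indices] = b.world_coords()
            st.velocities[b.indices] = b.bead_velocities()
            body_kicks.append(b)
        st.wrap()

        # advance the step counter before the force evaluation so the noise
        # stream of these forces is keyed to the state they belong to (this
        # makes checkpoint restarts reproduce uninterrupted runs exactly)
        st.step += 1
        st.time += dt
        self.compute_forces()
        f_new = st.forces
        st.velocities[free] = v_full[free] + 0.5 * dt * (f_old[free] + f_new[free])
        for b in self.bodies:
            fsum = f_new[b.indices].sum(axis=0)
            d = b.body_coords @ b.rotation().T
            tq = np.cross(d, f_new[b.indices]).sum(axis=0)
            b.v_com += 0.5 * dt * fsum / b.mass
            b.ang_mom += 0.5 * dt * tq
            st.velocities[b.indices] = b.bead_velocities()

        if self.tension is not None and st.step % self.tension.interval == 0:
            n_lip = self.topology.count_lipids()
            zero_tension_update(st, self.tension, n_lip, self.bodies)
            self.compute_forces()
        return st

    def run(self, n_steps: int, observer=None, observe_every: int = 0) -> None:
        """Advance ``n_steps``; call ``observer(engine)`` every ``observe_every`` steps."""
        for _ in range(n_steps):
            self.integrate_step()
            if observer is not None and observe_every and self.state.step % observe_every == 0:
                observer(self)

    # -- measurements ------------------------------------------------------

    def kinetic_temperature(self) -> float:
        return kinetic_temperature(self.state, self.n_rigid_dof_removed)

    def pressure_tensor(self) -> np.ndarray:
        """Instantaneous pressure tensor (3x3) from kinetic + conservative virial."""
        st = self.state
        kin = st.velocities.T @ st.velocities
        w = self.virial
        wmat = np.array([[w[0], w[3], w[4]], [w[3], w[1], w[5]], [w[4], w[5], w[2]]])
        return (kin + wmat) / st.volume

    def total_momentum(self) -> np.ndarray:
        return self.state.velocities.sum(axis=0)

    # -- checkpointing -----------------------------------------------------

    def save_checkpoint(self, path) -> None:
        st = self.state
        with h5py.File(path, "w") as h5:
            h5.attrs["topology_hash"] = self.topology.content_hash()
            h5.attrs["seed"] = self.seed
            h5.attrs["step"] = st.step
            h5.attrs["time"] = st.time
            h5.create_dataset("positions", data=st.positions)
            h5.create_dataset("velocities", data=st.velocities)
            h5.create_dataset("forces", data=st.forces)
            h5.create_dataset("box", data=st.box)
            for i, b in enumerate(self.bodies):
                g = h5.create_group(f"body/{i}")
                g.create_dataset("com", data=b.com)
                g.create_dataset("quat", data=b.quat)
                g.create_dataset("v_com", data=b.v_com)
                g.create_dataset("ang_mom", data=b.ang_mom)

    def load_checkpoint(self, path) -> None:
        with h5py.File(path, "r") as h5:
            if h5.attrs["topology_hash"] != self.topology.content_hash():
                raise ValueError("checkpoint topology does not match this engine")
            self.seed = int(h5.attrs["seed"])
            st = self.state
            st.positions[:] = h5["positions"][...]
            st.velocities[:] = h5["velocities"][...]
            st.box[:] = h5["box"][...]
            st.step = int(h5.attrs["step"])
            st.time = float(h5.attrs["time"])
            # restore forces rather than recomputing: the stored forces were
            # evaluated with the lambda-predicted velocities of the saved
            # step, which a fresh evaluation cannot reconstruct
            st.forces = h5["forces"][...]
            for i, b in enumerate(self.bodies):
                g = h5[f"body/{i}"]
                b.com = g["com"][...]
                b.quat = g["quat"][...]
                b.v_com = g["v_com"][...]
                b.ang_mom = g["ang_mom"][...]


def integrate_step(engine: DPDEngine) -> SystemState:
    """Functional alias for :meth:`DPDEngine.integrate_step`."""
    return engine.integrate_step()


# ---------------------------------------------------------------------------
# Selection-filtered potential energy (used by the Delta-E observable)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _selected_energy_kernel(pos, box, types, body, a_mat, sel, charge,
                            u_tab, f_tab, e_cut,
                            lj_ab, lj_rec, lj_eps, lj_sig, lj_cap, lj_rcap,
                            lj_ucap, lj_cut):
    """Sum of pair energies over pairs with at least one selected member."""
    n = pos.shape[0]
    ntab = u_tab.shape[0]
    dr_tab = e_cut / (ntab - 1)
    e2 = e_cut * e_cut
    u = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if not (sel[i] or sel[j]):
                continue
            if body[i] >= 0 and body[i] == body[j]:
                continue
            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= e2 or r2 == 0.0:
                continue
            r = math.sqrt(r2)
            if r < 1.0:
                w = 1.0 - r
                u += 0.5 * a_mat[types[i], types[j]] * w * w
                if (lj_ab[types[i]] and lj_rec[types[j]]) or \
                   (lj_rec[types[i]] and lj_ab[types[j]]):
                    if r < lj_cut:
                        if r <= lj_rcap:
                            u += lj_ucap + lj_cap * (lj_rcap - r)
                        else:
                            sr6 = (lj_sig / r) ** 6
                            u += 4.0 * lj_eps * (sr6 * sr6 - sr6)
            qq = charge[i] * charge[j]
            if qq != 0.0:
                x = r / dr_tab
                k = min(int(x), ntab - 2)
                frac = x - k
                u += qq * (u_tab[k] * (1.0 - frac) + u_tab[k + 1] * frac)
    return u


def selected_potential_energy(topology: Topology, ff: ForceField,
                              positions: np.ndarray, box: np.ndarray,
                              select: np.ndarray) -> float:
    """Potential energy restricted to interaction terms touching ``select``.

    Sums every pair (conservative repulsion, soft LJ, smeared Coulomb), bond
    and angle term in which at least one member bead is selected.  Used for
    the nanoparticle-complex + membrane energy bookkeeping, where the solvent
    background (water-water and ion-ion terms) is excluded by construction
    because no solvent bead is selected.
    """
    pos = np.ascontiguousarray(positions, float)
    box = np.asarray(box, float)
    sel = np.ascontiguousarray(select, np.bool_)
    types = np.ascontiguousarray(topology.type_index, np.int64)
    body = np.ascontiguousarray(topology.body_id, np.int64)
    charge = np.ascontiguousarray(topology.charge, float)
    u_tab, f_tab = _elec_tables(ff.electrostatics)
    lj = ff.soft_lj
    lj_rcap = _lj_cap_radius(lj.epsilon, lj.sigma_lj, lj.force_cap)
    sr6 = (lj.sigma_lj / lj_rcap) ** 6
    lj_ucap = 4.0 * lj.epsilon * (sr6 * sr6 - sr6)
    lj_ab = np.array([c.is_antibody for c in ff.classes], np.bool_)
    lj_rec = np.array([c.is_receptor_head for c in ff.classes], np.bool_)
    u = _selected_energy_kernel(
        pos, box, types, body, np.ascontiguousarray(ff.pair_table.a), sel,
        charge, u_tab, f_tab, ff.electrostatics.cutoff,
        lj_ab, lj_rec, lj.epsilon, lj.sigma_lj, lj.force_cap,
        lj_rcap, lj_ucap, lj.cutoff)
    # bonded terms touching the selection
    for (i, j), ks, l0 in zip(topology.bond_ij, topology.bond_ks, topology.bond_l0):
        if sel[i] or sel[j]:
            d = pos[i] - pos[j]
            d -= box * np.round(d / box)
            r = float(np.linalg.norm(d))
            u += ks * (1.0 - r / l0) ** 2
    for (i, j, k), ka in zip(topology.angle_ijk, topology.angle_ka):
        if sel[i] or sel[j] or sel[k]:
            a = pos[i] - pos[j]
            a -= box * np.round(a / box)
            b = pos[k] - pos[j]
            b -= box * np.round(b / box)
            cosp = float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
            cosp = max(-1.0, min(1.0, cosp))
            u += ka * (1.0 + cosp)
    return float(u)
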