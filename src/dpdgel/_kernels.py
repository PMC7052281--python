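"""Numba-compiled inner loops: cell-list pair forces and the DPD integrator.

Single-threaded on purpose: with one RNG stream and a fixed pair-enumeration
order the trajectories are bit-reproducible for a given seed.  The pair
interaction is written out inline in the hot loops (a function call per pair
costs more than the arithmetic).
"""
from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_UNSTABLE = 1
STATUS_NONFINITE = 2
STATUS_DEGENERATE_BOND = 3

#: half-stencil of neighbour-cell offsets: the 13 lexicographically positive
#: (x fastest) of the 26 neighbours plus the self cell as entry 13, so each
#: cell pair is visited exactly once.
_STENCIL = np.array(
    [[ox, oy, oz]
     for oz in (0, 1) for oy in (-1, 0, 1) for ox in (-1, 0, 1)
     if (oz > 0) or (oz == 0 and oy > 0) or (oz == 0 and oy == 0 and ox > 0)],
    dtype=np.int64)


@njit(cache=True)
def seed_rng(seed):
    """Seed numba's global RNG stream used for the random pair force."""
    np.random.seed(seed)


@njit(cache=True, fastmath=True)
def compute_forces(pos, vel, species, a, gamma, sigma, r_cut, bonds, bond_C,
                   bond_r0, box, inv_sqrt_dt, use_random, forces, virial):
    """All forces (pair + bond) into ``forces``; diagonal pair virial into ``virial``.

    Pair force on bead i from j (rhat pointing j -> i):
    a_ij*w - gamma*w^2*(rhat.v_ij) + sigma*w*alpha*dt^(-1/2), with
    w = 1 - r/R_c inside the cutoff and alpha ~ N(0,1) drawn once per pair.
    Forces are applied antisymmetrically so momentum is conserved exactly.

    Uses a linked-cell neighbour search when the box holds >= 3 cells per
    axis, otherwise an O(N^2) loop with the minimum-image convention.
    Periodic images are handled by shifting whole neighbour cells, so the
    inner pair loop is branch-free.  Returns a STATUS_* code.
    """
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    virial[0] = 0.0
    virial[1] = 0.0
    virial[2] = 0.0
    rc2 = r_cut * r_cut

    ncx = int(box[0] / r_cut)
    ncy = int(box[1] / r_cut)
    ncz = int(box[2] / r_cut)
    if ncx < 3 or ncy < 3 or ncz < 3:
        for i in range(n - 1):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                dx -= box[0] * np.round(dx / box[0])
                dy -= box[1] * np.round(dy / box[1])
                dz -= box[2] * np.round(dz / box[2])
                r2 = dx * dx + dy * dy + dz * dz
                if r2 >= rc2 or r2 < 1e-24:
                    continue
                r = np.sqrt(r2)
                inv_r = 1.0 / r
                w = 1.0 - r / r_cut
                ex = dx * inv_r
                ey = dy * inv_r
                ez = dz * inv_r
                rv = (ex * (vel[i, 0] - vel[j, 0])
                      + ey * (vel[i, 1] - vel[j, 1])
                      + ez * (vel[i, 2] - vel[j, 2]))
                fmag = a[species[i], species[j]] * w - gamma * w * w * rv
                if use_random:
                    fmag += sigma * w * np.random.standard_normal() * inv_sqrt_dt
                fx = fmag * ex
                fy = fmag * ey
                fz = fmag * ez
                forces[i, 0] += fx
                forces[i, 1] += fy
                forces[i, 2] += fz
                forces[j, 0] -= fx
                forces[j, 1] -= fy
                forces[j, 2] -= fz
                virial[0] += dx * fx
                virial[1] += dy * fy
                virial[2] += dz * fz
    else:
        ncell = ncx * ncy * ncz
        cell_of = np.empty(n, dtype=np.int64)
        counts = np.zeros(ncell + 1, dtype=np.int64)
        inv_wx = ncx / box[0]
        inv_wy = ncy / box[1]
        inv_wz = ncz / box[2]
        for i in range(n):
            cx = int(pos[i, 0] * inv_wx)
            cy = int(pos[i, 1] * inv_wy)
            cz = int(pos[i, 2] * inv_wz)
            if cx >= ncx:
                cx = ncx - 1
            if cy >= ncy:
                cy = ncy - 1
            if cz >= ncz:
                cz = ncz - 1
            c = (cz * ncy + cy) * ncx + cx
            cell_of[i] = c
            counts[c + 1] += 1
        for c in range(ncell):
            counts[c + 1] += counts[c]
        order = np.empty(n, dtype=np.int64)
        fill = counts[:-1].copy()
        for i in range(n):
            c = cell_of[i]
            order[fill[c]] = i
            fill[c] += 1

        for cz in range(ncz):
            for cy in range(ncy):
                for cx in range(ncx):
                    c = (cz * ncy + cy) * ncx + cx
                    start = counts[c]
                    end = counts[c + 1]
                    for s in range(14):
                        if s == 13:  # pairs within the cell itself
                            s2 = start
                            e2 = end
                            sx = 0.0
                            sy = 0.0
                            sz = 0.0
                        else:  # half of the neighbouring cells, with the
                            #    periodic image shift constant per cell
                            nx = cx + _STENCIL[s, 0]
                            ny = cy + _STENCIL[s, 1]
                            nz = cz + _STENCIL[s, 2]
                            sx = 0.0
                            sy = 0.0
                            sz = 0.0
                            if nx < 0:
                                nx += ncx
                                sx = box[0]
                            elif nx >= ncx:
                                nx -= ncx
                                sx = -box[0]
                            if ny < 0:
                                ny += ncy
                                sy = box[1]
                            elif ny >= ncy:
                                ny -= ncy
                                sy = -box[1]
                            if nz >= ncz:
                                nz -= ncz
                                sz = -box[2]
                            c2 = (nz * ncy + ny) * ncx + nx
                            s2 = counts[c2]
                            e2 = counts[c2 + 1]
                        for ii in range(start, end):
                            i = order[ii]
                            px = pos[i, 0] + sx
                            py = pos[i, 1] + sy
                            pz = pos[i, 2] + sz
                            jlo = ii + 1 if s == 13 else s2
                            for jj in range(jlo, e2):
                                j = order[jj]
                                dx = px - pos[j, 0]
                                dy = py - pos[j, 1]
                                dz = pz - pos[j, 2]
                                r2 = dx * dx + dy * dy + dz * dz
                                if r2 >= rc2 or r2 < 1e-24:
                                    continue
                                r = np.sqrt(r2)
                                inv_r = 1.0 / r
                                w = 1.0 - r / r_cut
                                ex = dx * inv_r
                                ey = dy * inv_r
                                ez = dz * inv_r
                                rv = (ex * (vel[i, 0] - vel[j, 0])
                                      + ey * (vel[i, 1] - vel[j, 1])
                                      + ez * (vel[i, 2] - vel[j, 2]))
                                fmag = (a[species[i], species[j]] * w
                                        - gamma * w * w * rv)
                                if use_random:
                                    fmag += (sigma * w * inv_sqrt_dt
                                             * np.random.standard_normal())
                                fx = fmag * ex
                                fy = fmag * ey
                                fz = fmag * ez
                                forces[i, 0] += fx
                                forces[i, 1] += fy
                                forces[i, 2] += fz
                                forces[j, 0] -= fx
                                forces[j, 1] -= fy
                                forces[j, 2] -= fz
                                virial[0] += dx * fx
                                virial[1] += dy * fy
                                virial[2] += dz * fz

    # harmonic bonds: restoring force of magnitude C*(r - r0), attractive
    # for stretched bonds
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.round(dx / box[0])
        dy -= box[1] * np.round(dy / box[1])
        dz -= box[2] * np.round(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < 1e-24:
            if bond_C > 0.0:
                return STATUS_DEGENERATE_BOND
            continue
        r = np.sqrt(r2)
        fmag = -bond_C * (r - bond_r0) / r
        fx = fmag * dx
        fy = fmag * dy
        fz = fmag * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0] += dx * fx
        virial[1] += dy * fy
        virial[2] += dz * fz
    return STATUS_OK


@njit(cache=True, fastmath=True)
def run_chunk(pos, upos, vel, forces, species, a, gamma, sigma, r_cut, bonds,
              bond_C, bond_r0, box, dt, n_steps, srx, sry, srz, use_random,
              lam_vv):
    """Advance ``n_steps`` of modified velocity-Verlet DPD integration.

    ``forces`` must hold the forces at the current state on entry and holds
    the forces at the final state on exit.  ``(srx, sry, srz)`` are constant
    true strain rates applied as a per-step affine rescaling of box and
    coordinates (exponential stretch schedule).  ``lam_vv`` is the half-step
    velocity-prediction parameter (0.5 is standard for DPD).

    Returns (status, steps_done, virial_sum, kinetic_sum) where the last two
    are per-axis sums over all executed steps, for time-averaged stress.
    """
    n = pos.shape[0]
    virial = np.zeros(3)
    w_sum = np.zeros(3)
    k_sum = np.zeros(3)
    inv_sqrt_dt = 1.0 / np.sqrt(dt)
    half = 0.5 * dt
    vpred = np.empty_like(vel)
    fold = np.empty_like(forces)
    strain = (srx != 0.0) or (sry != 0.0) or (srz != 0.0)
    gx = np.exp(srx * dt)
    gy = np.exp(sry * dt)
    gz = np.exp(srz * dt)

    for step in range(n_steps):
        if strain:
            box[0] *= gx
            box[1] *= gy
            box[2] *= gz
            for i in range(n):
                pos[i, 0] *= gx
                pos[i, 1] *= gy
                pos[i, 2] *= gz
                upos[i, 0] *= gx
                upos[i, 1] *= gy
                upos[i, 2] *= gz
        hx = 0.5 * box[0]
        hy = 0.5 * box[1]
        hz = 0.5 * box[2]
        for i in range(n):
            ddx = dt * vel[i, 0] + half * dt * forces[i, 0]
            ddy = dt * vel[i, 1] + half * dt * forces[i, 1]
            ddz = dt * vel[i, 2] + half * dt * forces[i, 2]
            if not (np.isfinite(ddx) and np.isfinite(ddy) and np.isfinite(ddz)):
                return STATUS_NONFINITE, step, w_sum, k_sum
            if abs(ddx) > hx or abs(ddy) > hy or abs(ddz) > hz:
                return STATUS_UNSTABLE, step, w_sum, k_sum
            x = pos[i, 0] + ddx
            y = pos[i, 1] + ddy
            z = pos[i, 2] + ddz
            x -= np.floor(x / box[0]) * box[0]
            y -= np.floor(y / box[1]) * box[1]
            z -= np.floor(z / box[2]) * box[2]
            if x >= box[0]:
                x -= box[0]
            if y >= box[1]:
                y -= box[1]
            if z >= box[2]:
                z -= box[2]
            pos[i, 0] = x
            pos[i, 1] = y
            pos[i, 2] = z
            upos[i, 0] += ddx
            upos[i, 1] += ddy
            upos[i, 2] += ddz
            vpred[i, 0] = vel[i, 0] + lam_vv * dt * forces[i, 0]
            vpred[i, 1] = vel[i, 1] + lam_vv * dt * forces[i, 1]
            vpred[i, 2] = vel[i, 2] + lam_vv * dt * forces[i, 2]
            fold[i, 0] = forces[i, 0]
            fold[i, 1] = forces[i, 1]
            fold[i, 2] = forces[i, 2]
        status = compute_forces(pos, vpred, species, a, gamma, sigma, r_cut,
                                bonds, bond_C, bond_r0, box, inv_sqrt_dt,
                                use_random, forces, virial)
        if status != STATUS_OK:
            return status, step, w_sum, k_sum
        for i in range(n):
            vel[i, 0] += half * (fold[i, 0] + forces[i, 0])
            vel[i, 1] += half * (fold[i, 1] + forces[i, 1])
            vel[i, 2] += half * (fold[i, 2] + forces[i, 2])
            k_sum[0] += vel[i, 0] * vel[i, 0]
            k_sum[1] += vel[i, 1] * vel[i, 1]
            k_sum[2] += vel[i, 2] * vel[i, 2]
        w_sum[0] += virial[0]
        w_sum[1] += virial[1]
        w_sum[2] += virial[2]
    return STATUS_OK, n_steps, w_sum, k_sum
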