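"""DPD integrator and force evaluation.

The production path runs through numba cell-list kernels (`_kernels`); a
plain-numpy all-pairs implementation of the same forces (`pair_forces`,
`bond_force`) is kept as the reference oracle for tests and for one-shot
stress evaluations on small systems.

Interaction model (reduced units, weight w(r) = 1 - r/R_c inside the cutoff):

* conservative:  F^C = a_ij * w(r) * rhat            (soft repulsion)
* dissipative:   F^D = -gamma * w(r)^2 * (rhat . v_ij) * rhat
* random:        F^R = sigma * w(r) * alpha * dt^(-1/2) * rhat,
                 alpha ~ N(0,1), one draw per interacting pair per step
* bond:          restoring force of magnitude C * (r - r0) along the bond.

The dissipative/random pair is a momentum-conserving thermostat when
sigma^2 = 2 kT gamma.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .errors import (ConfigurationError, DegenerateBondError, InstabilityError,
                     StateError)
from .state import BeadSystem, ForceField

_SEEDED = False


def seed(value: int) -> None:
    """Seed the global random-force stream.  Must be called before dynamics."""
    global _SEEDED
    K.seed_rng(int(value))
    _SEEDED = True


def weight_function(r, r_cut: float):
    """DPD weight w(r) = 1 - r/R_c for r <= R_c, else 0.

    Continuous, non-negative and bounded by 1.  Vectorised over ``r``.
    """
    if r_cut <= 0:
        raise ValueError("r_cut must be positive")
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    w = np.where(r <= r_cut, 1.0 - r / r_cut, 0.0)
    return w if w.ndim else float(w)


def pair_forces(system: BeadSystem, ff: ForceField,
                rng: np.random.Generator | None = None,
                alpha: np.ndarray | None = None):
    """Reference all-pairs conservative+dissipative+random forces.

    ``alpha`` may supply a symmetric (N, N) matrix of standard-normal draws
    (one per pair, applied antisymmetrically); otherwise draws come from
    ``rng``.  With ``ff.sigma > 0`` one of the two must be given, since an
    unseeded random force is a configuration error.

    Returns ``(forces, virial)`` where ``virial`` is the diagonal of
    sum_pairs r_ij (x) F_ij (force-on-i convention, each pair once).
    """
    pos = system.positions
    n = system.n_beads
    if not np.all(np.isfinite(pos)):
        raise StateError("non-finite coordinates")
    if ff.sigma > 0 and rng is None and alpha is None:
        raise ConfigurationError(
            "random force requested without a seeded rng or alpha matrix")
    forces = np.zeros((n, 3))
    virial = np.zeros(3)
    inv_sqrt_dt = 1.0 / np.sqrt(ff.dt)
    for i in range(n - 1):
        d = pos[i] - pos[i + 1:]
        d -= system.box * np.round(d / system.box)
        r = np.linalg.norm(d, axis=1)
        close = np.nonzero((r < ff.r_cut) & (r > 1e-12))[0]
        for k in close:
            j = i + 1 + int(k)
            rij = r[k]
            e = d[k] / rij
            w = 1.0 - rij / ff.r_cut
            vij = system.velocities[i] - system.velocities[j]
            fmag = ff.a[system.species[i], system.species[j]] * w \
                - ff.gamma * w * w * float(e @ vij)
            if ff.sigma > 0:
                al = alpha[i, j] if alpha is not None else rng.standard_normal()
                fmag += ff.sigma * w * al * inv_sqrt_dt
            f = fmag * e
            forces[i] += f
            forces[j] -= f
            virial += d[k] * f
    return forces, virial


def bond_force(system: BeadSystem, ff: ForceField):
    """Harmonic bond forces: magnitude C*(r - r0), attractive when r > r0.

    Returns ``(forces, virial)``.  A zero-length bond with C > 0 has no
    defined direction and raises :class:`DegenerateBondError`.
    """
    n = system.n_beads
    forces = np.zeros((n, 3))
    virial = np.zeros(3)
    if len(system.bonds) == 0 or ff.bond_C == 0.0:
        return forces, virial
    i, j = system.bonds[:, 0], system.bonds[:, 1]
    d = system.minimum_image(system.positions[i] - system.positions[j])
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-12):
        raise DegenerateBondError("bond of zero length with nonzero stiffness")
    f = (-ff.bond_C * (r - ff.bond_r0) / r)[:, None] * d
    np.add.at(forces, i, f)
    np.add.at(forces, j, -f)
    virial = (d * f).sum(axis=0)
    return forces, virial


def compute_forces(system: BeadSystem, ff: ForceField, random: bool = False):
    """Total force and pair virial via the production cell-list kernel.

    With ``random=False`` the stochastic term is omitted, which makes the
    result directly comparable with :func:`pair_forces` + :func:`bond_force`.
    """
    if random and not _SEEDED:
        raise ConfigurationError("call engine.seed() before drawing random forces")
    forces = np.empty_like(system.positions)
    virial = np.empty(3)
    status = K.compute_forces(
        system.positions, system.velocities, system.species, ff.a, ff.gamma,
        ff.sigma, ff.r_cut, system.bonds, ff.bond_C, ff.bond_r0, system.box,
        1.0 / np.sqrt(ff.dt), random, forces, virial)
    _raise_for_status(status, 0)
    return forces, virial


def kinetic_temperature(system: BeadSystem) -> float:
    """Equipartition temperature sum(m v^2) / (3 (N - 1))."""
    n = system.n_beads
    if n < 2:
        raise StateError("kinetic temperature needs at least 2 beads")
    return float(system.mass * np.sum(system.velocities**2) / (3.0 * (n - 1)))


def total_momentum(system: BeadSystem) -> np.ndarray:
    return system.mass * system.velocities.sum(axis=0)


@dataclass
class Trajectory:
    """Thinned per-interval records from a dynamics run.

    ``stress`` holds tension-positive Cauchy stress diagonals averaged over
    each sampling interval; ``frames``/``frame_times`` hold unwrapped
    coordinates of the selected beads for transport observables.
    """

    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    kinetic_T: np.ndarray = field(default_factory=lambda: np.empty(0))
    stress: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    box: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    frames: np.ndarray | None = None
    frame_times: np.ndarray | None = None

    @property
    def mean_kinetic_T(self) -> float:
        return float(self.kinetic_T.mean()) if len(self.kinetic_T) else np.nan


def _raise_for_status(status: int, step: int):
    if status == K.STATUS_OK:
        return
    if status == K.STATUS_DEGENERATE_BOND:
        raise DegenerateBondError(f"zero-length bond at step {step}")
    if status == K.STATUS_NONFINITE:
        raise InstabilityError(f"non-finite state at step {step}", step=step)
    raise InstabilityError(
        f"per-step displacement exceeded box/2 at step {step}", step=step)


def advance(system: BeadSystem, ff: ForceField, n_steps: int, *,
            seed_value: int | None = None, sample_every: int = 0,
            strain_rates=(0.0, 0.0, 0.0), record_species: int | None = None,
            record_all: bool = False, lam_vv: float = 0.5,
            t0: float = 0.0) -> Trajectory:
    """Advance the system in place and return thinned records.

    Parameters
    ----------
    sample_every : record one entry per this many steps (0 = once at the end).
    strain_rates : constant true strain rates per axis; the box and all
        coordinates are rescaled affinely by exp(rate*dt) every step.
    record_species / record_all : capture unwrapped coordinates of the
        selected beads at every sample point (for MSD).
    seed_value : seed the random stream first; if None the existing stream
        continues (it must have been seeded once).
    """
    global _SEEDED
    if seed_value is not None:
        seed(seed_value)
    elif not _SEEDED:
        raise ConfigurationError("random stream never seeded; pass seed_value "
                                 "or call engine.seed() first")
    if not np.all(np.isfinite(system.positions)):
        raise StateError("non-finite coordinates")
    n_steps = int(n_steps)
    traj = Trajectory()
    if n_steps == 0:
        return traj

    chunk = int(sample_every) if sample_every else n_steps
    mask = None
    if record_all:
        mask = np.arange(system.n_beads)
    elif record_species is not None:
        mask = np.nonzero(system.species == record_species)[0]

    forces = np.empty_like(system.positions)
    virial = np.empty(3)
    status = K.compute_forces(
        system.positions, system.velocities, system.species, ff.a, ff.gamma,
        ff.sigma, ff.r_cut, system.bonds, ff.bond_C, ff.bond_r0, system.box,
        1.0 / np.sqrt(ff.dt), ff.sigma > 0, forces, virial)
    _raise_for_status(status, 0)

    times, temps, stresses, boxes, frames, ftimes = [], [], [], [], [], []
    if mask is not None:
        frames.append(system.unwrapped[mask].copy())
        ftimes.append(t0)
    done = 0
    srx, sry, srz = (float(s) for s in strain_rates)
    while done < n_steps:
        k = min(chunk, n_steps - done)
        status, steps, w_sum, k_sum = K.run_chunk(
            system.positions, system.unwrapped, system.velocities, forces,
            system.species, ff.a, ff.gamma, ff.sigma, ff.r_cut, system.bonds,
            ff.bond_C, ff.bond_r0, system.box, ff.dt, k, srx, sry, srz,
            ff.sigma > 0, lam_vv)
        _raise_for_status(status, done + steps)
        done += k
        t = t0 + done * ff.dt
        vol = system.volume
        times.append(t)
        temps.append(system.mass * k_sum.sum() / (3.0 * (system.n_beads - 1) * k))
        stresses.append(-(system.mass * k_sum + w_sum) / (k * vol))
        boxes.append(system.box.copy())
        if mask is not None:
            frames.append(system.unwrapped[mask].copy())
            ftimes.append(t)

    traj.times = np.asarray(times)
    traj.kinetic_T = np.asarray(temps)
    traj.stress = np.asarray(stresses)
    traj.box = np.asarray(boxes)
    if mask is not None:
        traj.frames = np.asarray(frames)
        traj.frame_times = np.asarray(ftimes)
    return traj


def integrate_step(system: BeadSystem, ff: ForceField,
                   seed_value: int | None = None) -> BeadSystem:
    """One modified velocity-Verlet step (lambda = 0.5), in place."""
    advance(system, ff, 1, seed_value=seed_value)
    return system


def run_nvt(system: BeadSystem, ff: ForceField, n_steps: int,
            target_kT: float | None = None, **kwargs) -> Trajectory:
    """NVT run: plain `advance` after checking the thermostat contract.

    If ``target_kT`` is given, the force field must satisfy
    sigma^2 = 2 * target_kT * gamma.
    """
    if target_kT is not None:
        if not np.isclose(ff.sigma**2, 2.0 * target_kT * ff.gamma, rtol=1e-9):
            raise ConfigurationError(
                f"force field not a thermostat at kT={target_kT}: "
                f"sigma^2={ff.sigma**2}, 2*kT*gamma={2 * target_kT * ff.gamma}")
    return advance(system, ff, n_steps, **kwargs)
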