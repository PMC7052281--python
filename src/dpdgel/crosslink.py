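"""Gelation protocol: relax, periodic bond creation under valence caps, cool.

Crosslinking is modelled as simultaneous bonding: every
``bond_attempt_interval`` steps, polymer-bead pairs closer than one cutoff
bond greedily (shortest pair first) as long as both partners have spare
valence (AAM holds at most 2 bonds, MBAA at most 4).  Water never bonds and
bonds are never removed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import engine
from .errors import CompositionError
from .state import AAM, MBAA, WATER, VALENCE, BeadSystem, ForceField


@dataclass
class CrosslinkSchedule:
    """Step counts and parameters of the gelation protocol (reduced units)."""

    relax_steps: int = 10_000
    bond_attempt_interval: int = 10
    crosslink_steps: int = 500_000
    bond_cutoff: float = 1.0
    cross_temperature: float = 9.0
    cool_steps: int = 100_000
    final_relax_steps: int = 100_000
    dt: float = 0.01
    valence: dict = field(default_factory=lambda: dict(VALENCE))
    #: stop the bond-attempt phase early once every valence is filled
    stop_when_saturated: bool = True

    def __post_init__(self):
        for name in ("relax_steps", "crosslink_steps", "cool_steps",
                     "final_relax_steps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.bond_attempt_interval < 1:
            raise ValueError("bond_attempt_interval must be >= 1")
        if self.bond_cutoff <= 0:
            raise ValueError("bond_cutoff must be positive")
        if min(self.valence.get(AAM, 0), self.valence.get(MBAA, 0)) < 1:
            raise ValueError("polymer valences must be >= 1")


@dataclass
class BondLog:
    """Append-only record of created bonds: (step, i, j, distance)."""

    steps: list = field(default_factory=list)
    bead_i: list = field(default_factory=list)
    bead_j: list = field(default_factory=list)
    distances: list = field(default_factory=list)

    def append(self, step: int, i: int, j: int, distance: float):
        self.steps.append(step)
        self.bead_i.append(i)
        self.bead_j.append(j)
        self.distances.append(distance)

    def __len__(self):
        return len(self.steps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"step": self.steps, "bead_i": self.bead_i,
                             "bead_j": self.bead_j,
                             "distance": self.distances})

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


def spare_valence(system: BeadSystem, valence=None) -> np.ndarray:
    """Remaining bonding capacity per bead (0 for water)."""
    valence = dict(VALENCE) if valence is None else valence
    caps = np.array([valence.get(int(s), 0) for s in system.species],
                    dtype=np.int64)
    return caps - system.bond_degrees()


def is_saturated(system: BeadSystem, valence=None) -> bool:
    """True when no bead has spare valence left."""
    return bool(np.all(spare_valence(system, valence) <= 0))


def attempt_bonds(system: BeadSystem, schedule: CrosslinkSchedule) -> list[tuple[int, int, float]]:
    """One bond-creation pass; returns the new bonds as (i, j, distance).

    Candidate polymer-polymer pairs within ``bond_cutoff`` are bonded
    greedily in increasing-distance order (ties broken by bead index), each
    bond consuming one unit of valence on both partners, skipping pairs that
    are already bonded.  The system is modified in place.
    """
    poly = np.nonzero(system.species != WATER)[0]
    if len(poly) == 0:
        return []
    spare = spare_valence(system, schedule.valence)
    open_beads = poly[spare[poly] > 0]
    if len(open_beads) < 2:
        return []
    # cKDTree with a periodic box needs coordinates strictly inside [0, L)
    system.wrap()
    tree = cKDTree(system.positions[open_beads], boxsize=system.box)
    pairs = tree.query_pairs(schedule.bond_cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return []
    gi = open_beads[pairs[:, 0]]
    gj = open_beads[pairs[:, 1]]
    d = system.minimum_image(system.positions[gi] - system.positions[gj])
    dist = np.linalg.norm(d, axis=1)
    lo = np.minimum(gi, gj)
    hi = np.maximum(gi, gj)
    order = np.lexsort((hi, lo, dist))
    existing = {(int(a), int(b)) for a, b in system.bonds}
    created = []
    for k in order:
        i, j = int(lo[k]), int(hi[k])
        if spare[i] <= 0 or spare[j] <= 0 or (i, j) in existing:
            continue
        spare[i] -= 1
        spare[j] -= 1
        existing.add((i, j))
        created.append((i, j, float(dist[k])))
    if created:
        system.add_bonds([(i, j) for i, j, _ in created])
    return created


def crosslink_rate(system: BeadSystem) -> float:
    """Crosslinking rate N_bond / (N_AAm + 2 N_MBAA)."""
    counts = system.species_counts()
    denom = counts[AAM] + 2 * counts[MBAA]
    if denom == 0:
        raise CompositionError("crosslink rate undefined without polymer beads")
    return len(system.bonds) / denom


def run_crosslinking(system: BeadSystem, ff: ForceField,
                     schedule: CrosslinkSchedule, seed: int,
                     cool_chunks: int = 100) -> BondLog:
    """Execute the full gelation protocol in place; returns the bond log.

    Phases: relax at the crosslinking temperature; dynamics with a bond
    attempt every ``bond_attempt_interval`` steps; linear temperature ramp
    down to kT = 1 (repulsion table rescaled with kT, gamma follows the
    fluctuation-dissipation balance); final relax at kT = 1.

    ``ff`` must be the force field at the crosslinking temperature with the
    soft gelation bond stiffness (C = 4).
    """
    if not np.isclose(ff.kT, schedule.cross_temperature):
        raise ValueError("force field temperature must match the schedule")
    engine.seed(seed)
    log = BondLog()
    if schedule.relax_steps:
        engine.advance(system, ff, schedule.relax_steps)

    interval = schedule.bond_attempt_interval
    step = 0
    while step < schedule.crosslink_steps:
        k = min(interval, schedule.crosslink_steps - step)
        engine.advance(system, ff, k)
        step += k
        for i, j, d in attempt_bonds(system, schedule):
            log.append(step, i, j, d)
        if schedule.stop_when_saturated and is_saturated(system, schedule.valence):
            break

    if schedule.cool_steps:
        n_chunks = min(cool_chunks, schedule.cool_steps)
        per = schedule.cool_steps // n_chunks
        extra = schedule.cool_steps - per * n_chunks
        for c in range(n_chunks):
            frac = (c + 1) / n_chunks
            kT = ff.kT + (1.0 - ff.kT) * frac
            engine.advance(system, ff.at_temperature(kT),
                           per + (extra if c == n_chunks - 1 else 0))
    if schedule.final_relax_steps:
        engine.advance(system, ff.at_temperature(1.0),
                       schedule.final_relax_steps)
    return log
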