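"""Deterministic miniature systems for tests and demonstrations.

Everything here is tiny (<= 1,000 beads) and fully determined by its seed.
"""
from __future__ import annotations

import numpy as np

from . import builder
from .state import AAM, MBAA, WATER, BeadSystem


def pure_water(n: int = 512, seed: int = 0, kT: float = 1.0) -> BeadSystem:
    """Small water box at the standard density."""
    return builder.water_box(n, seed=seed, kT=kT)


def small_mixture(n: int = 512, seed: int = 0, water_fraction: float = 0.8,
                  mass_ratio: float = 0.01, kT: float = 1.0) -> BeadSystem:
    """Small precursor mixture solved by the composition solver.

    The default mass ratio 0.01 keeps at least one crosslinker bead at this
    size (the production ratio 0.002 needs >= ~1,400 beads for that).
    """
    cg = builder.CoarseGrainMap()
    comp = builder.solve_composition(n, water_fraction, mass_ratio, cg)
    edge = builder.box_edge(n, cg.box_density)
    return builder.random_mixture(comp, edge, seed=seed, kT=kT)


def ring(n: int = 6, radius: float | None = None, box: float = 12.0,
         species: int = AAM) -> BeadSystem:
    """A closed n-bead loop with unit bond spacing, inside the box."""
    if radius is None:
        radius = 0.5 / np.sin(np.pi / n)  # unit chord length
    angles = 2.0 * np.pi * np.arange(n) / n
    centre = box / 2.0
    pos = np.stack([centre + radius * np.cos(angles),
                    centre + radius * np.sin(angles),
                    np.full(n, centre)], axis=1)
    bonds = [(i, (i + 1) % n) for i in range(n)]
    return BeadSystem(positions=pos, velocities=np.zeros((n, 3)),
                      species=np.full(n, species, dtype=np.int64),
                      box=np.full(3, box), bonds=np.asarray(bonds))


def star(arms: int = 4, arm_length: int = 3, box: float = 20.0) -> BeadSystem:
    """One MBAA hub with ``arms`` straight AAM arms (a tree)."""
    pos = [[box / 2, box / 2, box / 2]]
    species = [MBAA]
    bonds = []
    for a in range(arms):
        phi = 2.0 * np.pi * a / arms
        direction = np.array([np.cos(phi), np.sin(phi), 0.0])
        prev = 0
        for k in range(1, arm_length + 1):
            pos.append(list(pos[0] + k * direction))
            species.append(AAM)
            bonds.append((prev, len(pos) - 1))
            prev = len(pos) - 1
    n = len(pos)
    return BeadSystem(positions=np.asarray(pos, dtype=float),
                      velocities=np.zeros((n, 3)),
                      species=np.asarray(species, dtype=np.int64),
                      box=np.full(3, box), bonds=np.asarray(bonds))


def lattice(n_side: int = 4, bond_fraction: float = 1.0,
            seed: int = 0) -> BeadSystem:
    """Periodic cubic lattice of AAM beads with randomly diluted bonds.

    With ``bond_fraction = 1`` the lattice percolates along every axis;
    dilution makes it a percolation test bed.  Spacing is 1, box edge
    ``n_side``.
    """
    rng = np.random.default_rng(seed)
    coords = np.array([[x, y, z] for z in range(n_side)
                       for y in range(n_side) for x in range(n_side)],
                      dtype=float) + 0.5
    n = len(coords)

    def idx(x, y, z):
        return (z % n_side * n_side + y % n_side) * n_side + x % n_side

    bonds = []
    for z in range(n_side):
        for y in range(n_side):
            for x in range(n_side):
                i = idx(x, y, z)
                for dx, dy, dz in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
                    j = idx(x + dx, y + dy, z + dz)
                    if i == j or {i, j} in [set(b) for b in bonds]:
                        continue
                    if rng.uniform() < bond_fraction:
                        bonds.append((i, j))
    # valence note: lattice beads can exceed the AAM cap; this fixture is a
    # percolation test bed, not a chemically valid gel
    return BeadSystem(positions=coords, velocities=np.zeros((n, 3)),
                      species=np.full(n, AAM, dtype=np.int64),
                      box=np.full(3, float(n_side)),
                      bonds=np.asarray(bonds, dtype=np.int64))


def spanning_chain(n: int = 5, axis: int = 0) -> BeadSystem:
    """A straight bonded chain spanning the box and closing onto its image.

    Percolates along ``axis`` only: the constructed winding-cycle fixture.
    """
    box = float(n)
    pos = np.full((n, 3), box / 2.0)
    pos[:, axis] = np.arange(n) + 0.5
    bonds = [(i, (i + 1) % n) for i in range(n)]
    return BeadSystem(positions=pos, velocities=np.zeros((n, 3)),
                      species=np.full(n, AAM, dtype=np.int64),
                      box=np.full(3, box), bonds=np.asarray(bonds))
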