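"""Text I/O: LAMMPS data files (atoms + bonds), dump frames and XYZ.

Data files use the ``molecular`` atom style (``id mol type x y z``) with
1-based atom IDs and species types 1=water, 2=AAM, 3=MBAA; internal bead
indices are 0-based, the conversion lives entirely in this module.
"""
from __future__ import annotations

import numpy as np

from .errors import ParseError
from .state import BeadSystem

_TYPE_TO_SPECIES = {1: 0, 2: 1, 3: 2}
_SPECIES_TO_TYPE = {v: k for k, v in _TYPE_TO_SPECIES.items()}

_SECTIONS = ("Masses", "Atoms", "Velocities", "Bonds")


def write_data(system: BeadSystem, path, comment: str = "") -> None:
    """Write the system as a LAMMPS data file (Atoms + Velocities + Bonds)."""
    n = system.n_beads
    lines = [f"# dpdgel data file {comment}".rstrip(), ""]
    lines.append(f"{n} atoms")
    lines.append(f"{len(system.bonds)} bonds")
    lines.append("3 atom types")
    lines.append("1 bond types")
    lines.append("")
    for k, ax in enumerate("xyz"):
        lines.append(f"0.0 {system.box[k]:.12g} {ax}lo {ax}hi")
    lines.append("")
    lines.append("Masses")
    lines.append("")
    for t in (1, 2, 3):
        lines.append(f"{t} {system.mass:.12g}")
    lines.append("")
    lines.append("Atoms # molecular")
    lines.append("")
    for i in range(n):
        x, y, z = system.positions[i]
        lines.append(f"{i + 1} 1 {_SPECIES_TO_TYPE[int(system.species[i])]} "
                     f"{x:.12g} {y:.12g} {z:.12g}")
    lines.append("")
    lines.append("Velocities")
    lines.append("")
    for i in range(n):
        vx, vy, vz = system.velocities[i]
        lines.append(f"{i + 1} {vx:.12g} {vy:.12g} {vz:.12g}")
    if len(system.bonds):
        lines.append("")
        lines.append("Bonds")
        lines.append("")
        for b, (i, j) in enumerate(system.bonds):
            lines.append(f"{b + 1} 1 {i + 1} {j + 1}")
    lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_data(path) -> BeadSystem:
    """Parse a LAMMPS data file written by :func:`write_data`.

    Tolerates arbitrary section ordering and blank lines; raises
    :class:`ParseError` with the offending line number on malformed input.
    """
    with open(path) as fh:
        raw = fh.readlines()

    n_atoms = n_bonds = None
    box = np.zeros(3)
    box_seen = [False] * 3
    section = None
    atoms, velocities, bonds, masses = {}, {}, [], {}

    it = iter(enumerate(raw, start=1))
    for ln, line in it:
        text = line.split("#")[0].strip()
        if ln == 1 or not text:
            continue
        parts = text.split()
        if text in _SECTIONS:
            section = text
            continue
        if section is None:
            try:
                if len(parts) == 2 and parts[1] == "atoms":
                    n_atoms = int(parts[0])
                elif len(parts) == 2 and parts[1] == "bonds":
                    n_bonds = int(parts[0])
                elif len(parts) == 3 and parts[1] == "atom" and parts[2] == "types":
                    continue
                elif len(parts) == 3 and parts[1] == "bond" and parts[2] == "types":
                    continue
                elif len(parts) == 4 and parts[2].endswith("lo"):
                    ax = "xyz".index(parts[2][0])
                    box[ax] = float(parts[1]) - float(parts[0])
                    box_seen[ax] = True
                else:
                    raise ValueError(text)
            except ValueError as exc:
                raise ParseError(f"unrecognised header entry {text!r}",
                                 line=ln) from exc
            continue
        try:
            if section == "Masses":
                masses[int(parts[0])] = float(parts[1])
            elif section == "Atoms":
                aid = int(parts[0])
                atoms[aid] = (int(parts[2]),
                              (float(parts[3]), float(parts[4]),
                               float(parts[5])))
            elif section == "Velocities":
                velocities[int(parts[0])] = (float(parts[1]),
                                             float(parts[2]),
                                             float(parts[3]))
            elif section == "Bonds":
                bonds.append((int(parts[2]) - 1, int(parts[3]) - 1))
        except (ValueError, IndexError) as exc:
            raise ParseError(f"malformed {section} entry {text!r}",
                             line=ln) from exc

    if n_atoms is None or not all(box_seen):
        raise ParseError("missing atom count or box bounds in header")
    if len(atoms) != n_atoms:
        raise ParseError(f"header declares {n_atoms} atoms, found {len(atoms)}")
    if n_bonds is not None and len(bonds) != n_bonds:
        raise ParseError(f"header declares {n_bonds} bonds, found {len(bonds)}")
    if n_atoms == 0:
        return BeadSystem(positions=np.empty((0, 3)),
                          velocities=np.empty((0, 3)),
                          species=np.empty(0, dtype=np.int64), box=box)

    ids = sorted(atoms)
    if ids != list(range(1, n_atoms + 1)):
        raise ParseError("atom IDs must be 1..N")
    species = np.empty(n_atoms, dtype=np.int64)
    pos = np.empty((n_atoms, 3))
    vel = np.zeros((n_atoms, 3))
    for aid in ids:
        t, xyz = atoms[aid]
        if t not in _TYPE_TO_SPECIES:
            raise ParseError(f"unknown atom type {t}")
        species[aid - 1] = _TYPE_TO_SPECIES[t]
        pos[aid - 1] = xyz
        if aid in velocities:
            vel[aid - 1] = velocities[aid]
    mass = masses.get(1, 1.0)
    return BeadSystem(positions=pos, velocities=vel, species=species,
                      box=box, bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
                      mass=mass)


def write_xyz(system: BeadSystem, path, comment: str = "") -> None:
    """Minimal XYZ frame (species name as the element column)."""
    from .state import SPECIES_NAMES

    with open(path, "w") as fh:
        fh.write(f"{system.n_beads}\n{comment}\n")
        for i in range(system.n_beads):
            name = SPECIES_NAMES[int(system.species[i])][0]
            x, y, z = system.positions[i]
            fh.write(f"{name} {x:.8g} {y:.8g} {z:.8g}\n")


def write_dump_frame(system: BeadSystem, fh, step: int = 0) -> None:
    """Append one LAMMPS text-dump frame (`id type x y z` + box bounds)."""
    fh.write("ITEM: TIMESTEP\n%d\n" % step)
    fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % system.n_beads)
    fh.write("ITEM: BOX BOUNDS pp pp pp\n")
    for k in range(3):
        fh.write(f"0.0 {system.box[k]:.12g}\n")
    fh.write("ITEM: ATOMS id type x y z\n")
    for i in range(system.n_beads):
        x, y, z = system.positions[i]
        fh.write(f"{i + 1} {_SPECIES_TO_TYPE[int(system.species[i])]} "
                 f"{x:.8g} {y:.8g} {z:.8g}\n")
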