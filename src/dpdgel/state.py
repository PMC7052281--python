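"""Core simulation state: force-field parameters and the bead system.

All quantities are in reduced DPD units: the bead mass m, the thermal energy
kT at the reference temperature, and the interaction cutoff R_c are all 1.
T = 1 corresponds to 300 K.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import StateError

# Species codes. Acrylamide (AAM) and the crosslinker
# N,N'-methylenebisacrylamide (MBAA) interact as one "polymer" species but
# keep distinct labels because they carry different bonding valences.
WATER = 0
AAM = 1
MBAA = 2
SPECIES_NAMES = {WATER: "WATER", AAM: "AAM", MBAA: "MBAA"}

#: Maximum number of bonds a bead of each species may hold.  One AAM bead is
#: two acrylamide monomers (two open vinyl half-bonds); one MBAA bead is a
#: tetrafunctional crosslinker; water never bonds.
VALENCE = {WATER: 0, AAM: 2, MBAA: 4}


@dataclass
class ForceField:
    """Pairwise and bonded DPD interaction parameters (reduced units).

    Attributes
    ----------
    a : (3, 3) array
        Conservative repulsion amplitude by species pair.  Must be symmetric
        and non-negative.
    gamma : float
        Dissipative (friction) coefficient.
    sigma : float
        Random-force amplitude.  The pair (gamma, sigma) acts as a
        thermostat when sigma**2 == 2 * kT * gamma.
    r_cut : float
        Interaction cutoff R_c (= 1 in reduced units).
    bond_C : float
        Harmonic bond stiffness C; 4.0 during gelation, 116000 in tension.
    bond_r0 : float
        Equilibrium bond length (= R_c = 1).
    kT : float
        Target thermal energy of the thermostat.
    dt : float
        Integration time step.
    """

    a: np.ndarray
    gamma: float
    sigma: float
    kT: float
    dt: float
    r_cut: float = 1.0
    bond_C: float = 0.0
    bond_r0: float = 1.0

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=np.float64)
        if self.a.shape != (3, 3):
            raise StateError("repulsion table must be 3x3 (species WATER/AAM/MBAA)")
        if not np.allclose(self.a, self.a.T):
            raise StateError("repulsion table must be symmetric in the species pair")
        if np.any(self.a < 0):
            raise StateError("repulsion amplitudes must be non-negative")
        if self.r_cut <= 0 or self.dt <= 0:
            raise StateError("r_cut and dt must be positive")
        if self.bond_C < 0:
            raise StateError("bond stiffness must be non-negative")

    def thermostat_consistent(self, rtol: float = 1e-9) -> bool:
        """Whether the fluctuation-dissipation balance sigma^2 = 2 kT gamma holds."""
        return bool(np.isclose(self.sigma**2, 2.0 * self.kT * self.gamma, rtol=rtol))

    def with_(self, **changes) -> "ForceField":
        """Return a copy with the given fields replaced."""
        import dataclasses

        return dataclasses.replace(self, **changes)

    def at_temperature(self, kT: float) -> "ForceField":
        """Retarget the thermostat: gamma follows sigma^2 = 2 kT gamma at
        fixed sigma.  The repulsion table is a material property and does
        not rescale with the thermostat target."""
        return self.with_(kT=kT, gamma=self.sigma**2 / (2.0 * kT))


@dataclass
class BeadSystem:
    """Mutable bead-spring simulation state in an orthogonal periodic box.

    ``positions`` are wrapped into [0, L) per axis; ``unwrapped`` tracks the
    same trajectory without wrapping for transport observables.  ``bonds`` is
    an (M, 2) array of unordered bead-index pairs (stored i < j); bonds are
    only ever added by the crosslinker, never removed by dynamics.
    """

    positions: np.ndarray
    velocities: np.ndarray
    species: np.ndarray
    box: np.ndarray
    bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    unwrapped: np.ndarray | None = None
    mass: float = 1.0
    rng_seed: int | None = None

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.species = np.ascontiguousarray(self.species, dtype=np.int64)
        self.box = np.asarray(self.box, dtype=np.float64)
        self.bonds = np.ascontiguousarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        if self.unwrapped is None:
            self.unwrapped = self.positions.copy()
        else:
            self.unwrapped = np.ascontiguousarray(self.unwrapped, dtype=np.float64)
        n = len(self.positions)
        if self.velocities.shape != (n, 3) or self.species.shape != (n,):
            raise StateError("positions, velocities and species must agree in length")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise StateError("box must be three positive edge lengths")
        self._validate_bonds()
        self.wrap()

    def _validate_bonds(self):
        if len(self.bonds) == 0:
            return
        b = np.sort(self.bonds, axis=1)
        if np.any(b[:, 0] == b[:, 1]):
            raise StateError("self-bonds are not allowed")
        if b.min() < 0 or b.max() >= len(self.positions):
            raise StateError("bond references a bead index out of range")
        uniq = np.unique(b, axis=0)
        if len(uniq) != len(b):
            raise StateError("duplicate bond pairs are not allowed")
        self.bonds = b

    # -- basic queries -------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def species_counts(self) -> dict[int, int]:
        return {s: int(np.sum(self.species == s)) for s in (WATER, AAM, MBAA)}

    def bond_degrees(self) -> np.ndarray:
        """Number of bonds held by each bead."""
        deg = np.zeros(self.n_beads, dtype=np.int64)
        if len(self.bonds):
            np.add.at(deg, self.bonds.ravel(), 1)
        return deg

    # -- geometry ------------------------------------------------------
    def wrap(self):
        """Wrap positions into [0, L) per axis (robust to r == L round-off)."""
        self.positions -= np.floor(self.positions / self.box) * self.box
        # floating point can yield exactly L after the subtraction
        for k in range(3):
            col = self.positions[:, k]
            col[col >= self.box[k]] -= self.box[k]

    def minimum_image(self, dvec: np.ndarray) -> np.ndarray:
        """Apply the minimum-image convention to displacement vectors."""
        return dvec - self.box * np.round(dvec / self.box)

    def copy(self) -> "BeadSystem":
        return BeadSystem(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            species=self.species.copy(),
            box=self.box.copy(),
            bonds=self.bonds.copy(),
            unwrapped=self.unwrapped.copy(),
            mass=self.mass,
            rng_seed=self.rng_seed,
        )

    def add_bonds(self, new_bonds) -> None:
        new_bonds = np.asarray(new_bonds, dtype=np.int64).reshape(-1, 2)
        if len(new_bonds) == 0:
            return
        self.bonds = np.vstack([self.bonds, np.sort(new_bonds, axis=1)])
        self._validate_bonds()
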