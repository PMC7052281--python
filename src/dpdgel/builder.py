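"""Precursor-mixture construction: composition, box sizing, force field.

The coarse-grain map lumps 8 water molecules into one water bead, 2
acrylamide monomers into one AAM bead and 1 methylenebisacrylamide molecule
into one MBAA bead, so that bead masses are comparable and can all be set
to m = 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CompositionError
from .state import AAM, MBAA, WATER, BeadSystem, ForceField


@dataclass(frozen=True)
class CoarseGrainMap:
    """Coarse-graining rules and the parameters feeding the force field.

    ``rho_for_a`` is the bead number density entering the like-species
    repulsion rule a_ii = 75 kT / rho.  ``box_density`` is the density used
    to size the simulation box; its default sqrt(2) corresponds to unit
    nearest-neighbour spacing under closest packing, where the soft
    repulsion between touching beads just vanishes.  The two are distinct
    knobs on purpose.
    """

    waters_per_bead: int = 8
    aam_monomers_per_bead: int = 2
    mbaa_molecules_per_bead: int = 1
    mw_water: float = 18.02
    mw_aam_monomer: float = 71.08
    mw_mbaa: float = 154.17
    chi: float = 0.57
    rho_for_a: float = 2.0
    box_density: float = float(np.sqrt(2.0))

    def __post_init__(self):
        if min(self.waters_per_bead, self.aam_monomers_per_bead,
               self.mbaa_molecules_per_bead) < 1:
            raise ValueError("coarse-grain counts must be >= 1")
        if not np.isfinite(self.chi):
            raise ValueError("chi must be finite")
        if self.rho_for_a <= 0 or self.box_density <= 0:
            raise ValueError("densities must be positive")


@dataclass(frozen=True)
class Composition:
    """Bead counts of one precursor mixture."""

    n_water: int
    n_aam: int
    n_mbaa: int

    @property
    def total(self) -> int:
        return self.n_water + self.n_aam + self.n_mbaa

    @property
    def n_polymer(self) -> int:
        return self.n_aam + self.n_mbaa

    @property
    def max_bonds(self) -> int:
        """Maximum bond count N_AAm + 2 N_MBAA allowed by the valences."""
        return self.n_aam + 2 * self.n_mbaa

    def mass_ratio(self, cg: CoarseGrainMap) -> float:
        """Realised precursor mass ratio MBAA : AAm."""
        return (self.n_mbaa * cg.mw_mbaa) / (
            self.n_aam * cg.aam_monomers_per_bead * cg.mw_aam_monomer)


def solve_composition(total_beads: int, water_fraction: float,
                      mass_ratio_mbaa_to_aam: float,
                      cg: CoarseGrainMap = CoarseGrainMap()) -> Composition:
    """Split ``total_beads`` into water/AAM/MBAA bead counts.

    Water content is a bead-number fraction (all beads have equal mass, so
    number and mass fractions coincide at bead level).  The polymer beads
    are split so that the MBAA:AAm precursor mass ratio matches the request,
    rounded to whole beads with AAM absorbing the remainder.
    """
    if not 0.0 < water_fraction < 1.0:
        raise CompositionError("water fraction must lie in (0, 1)")
    if mass_ratio_mbaa_to_aam <= 0:
        raise CompositionError("mass ratio must be positive")
    n_water = round(water_fraction * total_beads)
    n_poly = total_beads - n_water
    if n_poly < 2:
        raise CompositionError("too few polymer beads")
    # n_mbaa * mw_mbaa = ratio * n_aam * monomers_per_bead * mw_aam
    q = mass_ratio_mbaa_to_aam * cg.aam_monomers_per_bead * \
        cg.mw_aam_monomer / cg.mw_mbaa
    n_mbaa = round(n_poly * q / (1.0 + q))
    if n_mbaa < 1:
        raise CompositionError(
            f"rounding leaves {n_mbaa} crosslinker beads; increase the system "
            "size or the mass ratio")
    n_aam = n_poly - n_mbaa
    if n_aam < 1:
        raise CompositionError("rounding leaves no AAM beads")
    return Composition(n_water=n_water, n_aam=n_aam, n_mbaa=n_mbaa)


def box_edge(total_beads: int, box_density: float) -> float:
    """Cubic box edge (total_beads / density)^(1/3), reduced length."""
    if total_beads <= 0 or box_density <= 0:
        raise ValueError("arguments must be positive")
    return float((total_beads / box_density) ** (1.0 / 3.0))


def mean_polymer_spacing(n_polymer: int, edge: float) -> float:
    """Mean polymer-bead spacing (V / N_polymer)^(1/3)."""
    return float((edge**3 / n_polymer) ** (1.0 / 3.0))


def expected_effective_contour(comp: Composition) -> float:
    """Mean effective-chain bond count expected from the precursor ratio.

    Each tetrafunctional MBAA bead terminates four chain arms, so the AAM
    beads distribute over 2*N_MBAA chains: N_AAm / (2 N_MBAA).
    """
    return comp.n_aam / (2.0 * comp.n_mbaa)


def build_forcefield(cg: CoarseGrainMap, kT: float, sigma: float = 3.0,
                     bond_C: float = 4.0, dt: float = 0.01,
                     bond_r0: float = 1.0,
                     reference_kT: float = 1.0) -> ForceField:
    """Assemble the force field from the coarse-grain mapping rules.

    The repulsion table is a material property evaluated at the reference
    temperature (kT = 1, i.e. 300 K): a_ii = 75 kT_ref / rho for
    water-water and polymer-polymer (AAM and MBAA interact as one
    species), plus the Flory-Huggins increment 3.27 kT_ref chi for
    polymer-water.  ``kT`` is the thermostat target -- elevated
    crosslinking temperatures are a transport device and do not rescale
    the repulsions -- and only gamma tracks it through the
    fluctuation-dissipation balance sigma^2 = 2 kT gamma at fixed sigma.
    """
    if kT <= 0 or sigma <= 0:
        raise ValueError("kT and sigma must be positive")
    a_ii = 75.0 * reference_kT / cg.rho_for_a
    a_pw = a_ii + 3.27 * reference_kT * cg.chi
    a = np.full((3, 3), a_ii)
    a[WATER, AAM] = a[AAM, WATER] = a_pw
    a[WATER, MBAA] = a[MBAA, WATER] = a_pw
    gamma = sigma**2 / (2.0 * kT)
    return ForceField(a=a, gamma=gamma, sigma=sigma, kT=kT, dt=dt,
                      r_cut=1.0, bond_C=bond_C, bond_r0=bond_r0)


def maxwell_velocities(n: int, kT: float, rng: np.random.Generator,
                       mass: float = 1.0) -> np.ndarray:
    """Maxwell-Boltzmann velocities at kT with centre-of-mass motion removed."""
    v = rng.normal(0.0, np.sqrt(kT / mass), size=(n, 3))
    return v - v.mean(axis=0)


def random_mixture(comp: Composition, box, seed: int,
                   kT: float = 1.0) -> BeadSystem:
    """Uniformly random precursor mixture (soft potentials tolerate overlap).

    Beads are placed uniformly in the box, species assigned in blocks
    (water, AAM, MBAA), velocities Maxwellian at ``kT``.  Deterministic for
    a given seed.
    """
    box = np.broadcast_to(np.asarray(box, dtype=np.float64), (3,)).copy()
    rng = np.random.default_rng(seed)
    n = comp.total
    pos = rng.uniform(0.0, 1.0, size=(n, 3)) * box
    species = np.concatenate([
        np.full(comp.n_water, WATER, dtype=np.int64),
        np.full(comp.n_aam, AAM, dtype=np.int64),
        np.full(comp.n_mbaa, MBAA, dtype=np.int64),
    ])
    vel = maxwell_velocities(n, kT, rng)
    return BeadSystem(positions=pos, velocities=vel, species=species,
                      box=box, rng_seed=seed)


def water_box(n: int, seed: int, kT: float = 1.0,
              box_density: float | None = None) -> BeadSystem:
    """Pure water-bead fluid at the standard box density."""
    density = CoarseGrainMap().box_density if box_density is None else box_density
    edge = box_edge(n, density)
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, edge, size=(n, 3))
    return BeadSystem(positions=pos,
                      velocities=maxwell_velocities(n, kT, rng),
                      species=np.full(n, WATER, dtype=np.int64),
                      box=np.full(3, edge), rng_seed=seed)
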