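"""Shared fixtures: force fields and small crosslinked gels.

Session-scoped gels are expensive (tens of seconds of DPD time stepping);
tests must copy them before mutating.
"""
from __future__ import annotations

import numpy as np
import pytest

from dpdgel import builder, crosslink, mechanics


@pytest.fixture(scope="session")
def cg_map():
    return builder.CoarseGrainMap()


@pytest.fixture(scope="session")
def ff_water(cg_map):
    """Water-only force field at kT = 1 (gelation time step)."""
    return builder.build_forcefield(cg_map, kT=1.0)


@pytest.fixture(scope="session")
def small_gel(cg_map):
    """2,000-bead 80%-water gel crosslinked to saturation at kT = 9.

    Cooled to kT = 1 with a short ramp; soft gelation bonds (C = 4).
    """
    comp = builder.solve_composition(2000, 0.8, 0.002, cg_map)
    system = builder.random_mixture(
        comp, builder.box_edge(2000, cg_map.box_density), seed=42, kT=9.0)
    ff = builder.build_forcefield(cg_map, kT=9.0)
    schedule = crosslink.CrosslinkSchedule(
        relax_steps=2000, crosslink_steps=120_000, cool_steps=4000,
        final_relax_steps=4000)
    log = crosslink.run_crosslinking(system, ff, schedule, seed=42)
    return system, log, comp


@pytest.fixture(scope="session")
def tension_gel(cg_map):
    """500-bead gel (mass ratio 0.01) cooled and annealed to stiff bonds.

    Returns (system, stiff force field, effective-chain records); the
    higher crosslinker content keeps >= 1 MBAA bead at this small size.

    Sample preparation: in a box this small a winding bond cycle can close
    with fewer bonds than its periodic span needs, leaving the network
    permanently taut (residually stressed) once the bonds stiffen.  Such
    geometrically frustrated samples are not valid undeformed reference
    states, so candidates whose maximum bond stretch exceeds 1.1 after
    stiffening are rejected and the next seed is tried.
    """
    import numpy as np

    from dpdgel import engine, topology

    comp = builder.solve_composition(500, 0.8, 0.01, cg_map)
    ff9 = builder.build_forcefield(cg_map, kT=9.0)
    schedule = crosslink.CrosslinkSchedule(
        relax_steps=2000, crosslink_steps=80_000, cool_steps=4000,
        final_relax_steps=4000)
    for seed in (11, 12, 13, 14, 15):
        system = builder.random_mixture(
            comp, builder.box_edge(500, cg_map.box_density), seed=seed,
            kT=9.0)
        crosslink.run_crosslinking(system, ff9, schedule, seed=seed)
        ff1 = builder.build_forcefield(cg_map, kT=1.0, dt=0.001)
        ff_stiff = mechanics.prepare_for_tension(
            system, ff1, stages=10, steps_per_stage=1500, seed=seed)
        i, j = system.bonds[:, 0], system.bonds[:, 1]
        lengths = np.linalg.norm(system.minimum_image(
            system.positions[i] - system.positions[j]), axis=1)
        if lengths.max() <= 1.1 * ff_stiff.bond_r0:
            break
    # bond-mode energy couples weakly to the pair thermostat (the
    # dissipative weight vanishes at r = r0): give it time to drain
    engine.advance(system, ff_stiff, 25_000)
    records = [r for r in
               topology.classify_chains(topology.build_polymer_graph(system))
               if r.chain_class == topology.EFFECTIVE]
    return system, ff_stiff, records
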