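"""Network topology: percolation by box winding and chain classification."""
from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from dpdgel import fixtures, topology
from dpdgel.errors import TopologyError
from dpdgel.state import AAM, MBAA, WATER, BeadSystem
from dpdgel.topology import (BRANCH, CROSSLINKING_LOOP, EFFECTIVE,
                             ISOLATED_CHAIN, ISOLATED_LOOP)


def _beads(positions, species, bonds, box=10.0):
    pos = np.asarray(positions, dtype=float)
    return BeadSystem(positions=pos, velocities=np.zeros_like(pos),
                      species=np.asarray(species, dtype=np.int64),
                      box=np.full(3, box),
                      bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2))


def classes(records):
    return sorted((r.chain_class, r.n_bonds) for r in records)


class TestGraphConstruction:
    def test_no_bonds_gives_edgeless_graph(self):
        system = fixtures.small_mixture(300, seed=0)
        g = topology.build_polymer_graph(system)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == int(np.sum(system.species != WATER))

    def test_linear_chain_is_path_graph(self):
        pos = [[i + 1.0, 1, 1] for i in range(5)]
        system = _beads(pos, [AAM] * 5, [(i, i + 1) for i in range(4)])
        g = topology.build_polymer_graph(system)
        assert g.number_of_edges() == 4
        assert sorted(d for _, d in g.degree()) == [1, 1, 2, 2, 2]

    def test_water_bond_rejected(self):
        system = _beads([[1, 1, 1], [2, 1, 1]], [WATER, AAM], [(0, 1)])
        with pytest.raises(TopologyError):
            topology.build_polymer_graph(system)


class TestPercolation:
    def test_interior_ring_does_not_percolate(self):
        g = topology.build_polymer_graph(fixtures.ring(8))
        _, flags = topology.percolating_components(g)
        assert not flags[0].any()

    @pytest.mark.parametrize("axis", [0, 1, 2])
    def test_spanning_chain_percolates_on_its_axis(self, axis):
        g = topology.build_polymer_graph(fixtures.spanning_chain(6, axis=axis))
        _, flags = topology.percolating_components(g)
        assert flags[0][axis]
        assert flags[0].sum() == 1

    @pytest.mark.parametrize("fraction,seed", [(1.0, 0), (0.7, 1), (0.5, 2),
                                               (0.35, 3), (0.25, 4),
                                               (0.2, 5), (0.55, 6)])
    def test_diluted_lattice_agrees_with_supercell_oracle(self, fraction, seed):
        """Winding-cycle percolation vs brute-force 3x3x3 tiling search."""
        system = fixtures.lattice(4, bond_fraction=fraction, seed=seed)
        g = topology.build_polymer_graph(system)
        labels, flags = topology.percolating_components(g)
        for cid in range(len(flags)):
            nodes = [n for n, c in labels.items() if c == cid]
            oracle = _supercell_percolates(system, nodes)
            assert tuple(flags[cid]) == oracle, (fraction, seed, cid)


def _supercell_percolates(system: BeadSystem, nodes):
    """Oracle: tile the box 3x per axis; a component percolates on an axis
    when a bead connects to its own translated copy along that axis."""
    import networkx as nx

    node_set = set(nodes)
    bonds = [(int(i), int(j)) for i, j in system.bonds
             if int(i) in node_set and int(j) in node_set]
    L = system.box
    shifts = [(a, b, c) for a in range(3) for b in range(3) for c in range(3)]
    g = nx.Graph()
    for a, b, c in shifts:
        for i, j in bonds:
            # connect copies through the bond's minimum image
            d = system.positions[j] - system.positions[i]
            img = np.round(d / L).astype(int)  # which copy j falls into
            ca = (a - img[0]) % 3, (b - img[1]) % 3, (c - img[2]) % 3
            g.add_edge((i, (a, b, c)), (j, ca))
    result = []
    for axis in range(3):
        hit = False
        for n in nodes:
            base = (n, (0, 0, 0))
            shifted = [0, 0, 0]
            shifted[axis] = 1
            other = (n, tuple(shifted))
            if g.has_node(base) and g.has_node(other) and \
                    nx.has_path(g, base, other):
                hit = True
                break
        result.append(hit)
    return tuple(result)


class TestClassification:
    def test_isolated_aam_cycle(self):
        records = topology.classify_chains(
            topology.build_polymer_graph(fixtures.ring(3)))
        assert classes(records) == [(ISOLATED_LOOP, 3)]
        assert records[0].l0 == 0.0
        assert np.linalg.norm(records[0].end_to_end) == 0.0

    def test_cycle_with_crosslinker_is_crosslinking_loop(self):
        system = fixtures.ring(6)
        system.species[0] = MBAA
        records = topology.classify_chains(
            topology.build_polymer_graph(system))
        assert classes(records) == [(CROSSLINKING_LOOP, 6)]

    def test_detached_tree_is_isolated_chain(self):
        records = topology.classify_chains(
            topology.build_polymer_graph(fixtures.star(arms=3, arm_length=2)))
        assert classes(records) == [(ISOLATED_CHAIN, 6)]

    def test_dangling_tail_on_percolating_backbone_is_branch(self):
        pos = [[i + 0.5, 1, 1] for i in range(5)] + \
              [[2.5, 2 + j, 1] for j in range(4)]
        bonds = [(i, (i + 1) % 5) for i in range(5)] + \
                [(2, 5), (5, 6), (6, 7), (7, 8)]
        system = _beads(pos, [AAM] * 9, bonds, box=5.0)
        records = topology.classify_chains(
            topology.build_polymer_graph(system))
        assert classes(records) == [(BRANCH, 4), (EFFECTIVE, 5)]

    def test_pendant_loop_on_bridge_is_branch(self):
        pos = [[i + 0.5, 1, 1] for i in range(5)] + \
              [[2.5, 2.2, 1], [2.2, 3.0, 1], [2.8, 3.0, 1]]
        bonds = [(i, (i + 1) % 5) for i in range(5)] + \
                [(2, 5), (5, 6), (6, 7), (5, 7)]
        system = _beads(pos, [AAM] * 8, bonds, box=5.0)
        records = topology.classify_chains(
            topology.build_polymer_graph(system))
        assert classes(records) == [(BRANCH, 4), (EFFECTIVE, 5)]

    def test_junction_segmentation_partitions_bonds(self):
        # a winding backbone with a parallel detour: three effective chains
        pos = [[i + 0.5, 1, 1] for i in range(5)] + \
              [[1.5, 2, 1], [2.5, 2, 1], [3.5, 2, 1]]
        bonds = [(i, (i + 1) % 5) for i in range(5)] + \
                [(1, 5), (5, 6), (6, 7), (7, 4)]
        system = _beads(pos, [AAM] * 8, bonds, box=5.0)
        g = topology.build_polymer_graph(system)
        records = topology.classify_chains(g)
        assert [r.chain_class for r in records] == [EFFECTIVE] * 3
        assert sum(r.n_bonds for r in records) == g.number_of_edges()

    def test_invariant_under_relabelling_and_translation(self):
        system = fixtures.star(arms=4, arm_length=3)
        extra = fixtures.ring(5)
        # merge star + shifted ring into one system
        n0 = system.n_beads
        pos = np.vstack([system.positions, extra.positions + 3.0])
        species = np.concatenate([system.species, extra.species])
        bonds = np.vstack([system.bonds, extra.bonds + n0])
        merged = _beads(pos, species, bonds, box=20.0)
        base = classes(topology.classify_chains(
            topology.build_polymer_graph(merged)))

        rng = np.random.default_rng(4)
        perm = rng.permutation(merged.n_beads)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        shuffled = _beads((pos[perm] + 7.3) % 20.0, species[perm],
                          inv[bonds], box=20.0)
        assert classes(topology.classify_chains(
            topology.build_polymer_graph(shuffled))) == base


class TestStatistics:
    def test_single_chain_has_unit_fraction(self):
        records = topology.classify_chains(
            topology.build_polymer_graph(fixtures.spanning_chain(6)))
        stats = topology.chain_statistics(records)
        assert stats.length_fraction[EFFECTIVE] == 1.0
        assert stats.number_fraction[EFFECTIVE] == 1.0

    def test_fractions_partition_gel(self, small_gel):
        system, _, comp = small_gel
        g = topology.build_polymer_graph(system)
        records = topology.classify_chains(g)
        stats = topology.chain_statistics(records)
        assert sum(stats.number_fraction.values()) == pytest.approx(1.0,
                                                                    abs=1e-12)
        assert sum(stats.length_fraction.values()) == pytest.approx(1.0,
                                                                    abs=1e-12)
        assert sum(stats.bond_counts.values()) == g.number_of_edges()
        # every chain's l0 stays within [0, 1]
        assert all(0.0 <= r.l0 <= 1.0 + 1e-9 for r in records)

    def test_isotropic_orientations_match_expected_distributions(self):
        """theta uniform and phi sine-distributed for isotropic chains."""
        rng = np.random.default_rng(8)
        vecs = rng.normal(size=(100_000, 3))
        records = [topology.ChainRecord(
            chain_class=EFFECTIVE, bead_path=[0, 1], n_bonds=1,
            end_to_end=v, l0=0.5, theta=topology._orientation(v)[0],
            phi=topology._orientation(v)[1]) for v in vecs]
        stats = topology.chain_statistics(records)
        # azimuth: chi^2 against uniform bins
        counts, _ = np.histogram(stats.theta_values,
                                 bins=18, range=(0, 2 * np.pi))
        assert sps.chisquare(counts).pvalue > 1e-3
        # polar: chi^2 against sin(phi)-weighted bins
        edges = np.linspace(0, np.pi, 19)
        counts, _ = np.histogram(stats.phi_values, bins=edges)
        expected = np.diff(-np.cos(edges)) / 2.0 * len(stats.phi_values)
        assert sps.chisquare(counts, expected).pvalue > 1e-3
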