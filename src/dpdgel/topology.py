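"""Network topology: percolation analysis and the five chain classes.

A crosslinked gel is analysed as a graph over polymer beads whose edges
carry the periodic image shift of their bond.  A connected component is
*network-forming* when some cycle accumulates a nonzero net image shift
(it winds around the periodic box), which is the wrap-independent notion of
percolation.  Chains are then classified as

* EFFECTIVE        — load-bearing segments of the percolating core,
* BRANCH           — dangling material attached to the core (free ends or
                     pendant loops hanging by a single bridge bond),
* ISOLATED_CHAIN   — acyclic components not attached to the core,
* CROSSLINKING_LOOP— cyclic detached components that contain a crosslinker,
* ISOLATED_LOOP    — cyclic detached components of monomer beads only.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import TopologyError
from .state import MBAA, WATER, BeadSystem

EFFECTIVE = "EFFECTIVE"
BRANCH = "BRANCH"
ISOLATED_CHAIN = "ISOLATED_CHAIN"
CROSSLINKING_LOOP = "CROSSLINKING_LOOP"
ISOLATED_LOOP = "ISOLATED_LOOP"
CHAIN_CLASSES = (EFFECTIVE, BRANCH, ISOLATED_CHAIN, CROSSLINKING_LOOP,
                 ISOLATED_LOOP)


@dataclass
class ChainRecord:
    """One topological chain and its geometry.

    ``n_bonds`` is the contour length in bond counts; ``end_to_end`` the
    minimum-image-consistent end-to-end vector (zero for loops);
    ``l0 = |end_to_end| / (n_bonds * r0)`` the initial length ratio; theta
    (azimuth, [0, 2pi)) and phi (polar, [0, pi]) orient the end-to-end
    vector and are NaN when it vanishes.
    """

    chain_class: str
    bead_path: list
    n_bonds: int
    end_to_end: np.ndarray
    l0: float
    theta: float
    phi: float


@dataclass
class NetworkStats:
    """Aggregate per-class statistics of a classified network."""

    n_chains: dict
    number_fraction: dict
    bond_counts: dict
    length_fraction: dict
    mean_contour: dict
    mean_end_to_end_effective: float
    l0_values: np.ndarray
    theta_values: np.ndarray
    phi_values: np.ndarray
    crosslink_rate: float | None = None

    def to_json(self, path=None) -> str:
        payload = {
            "n_chains": self.n_chains,
            "number_fraction": self.number_fraction,
            "bond_counts": self.bond_counts,
            "length_fraction": self.length_fraction,
            "mean_contour": self.mean_contour,
            "mean_end_to_end_effective": self.mean_end_to_end_effective,
            "crosslink_rate": self.crosslink_rate,
            "l0_mean": float(np.mean(self.l0_values)) if len(self.l0_values) else None,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def build_polymer_graph(system: BeadSystem) -> nx.Graph:
    """Graph over polymer beads; edges annotated with periodic image shifts.

    The edge attribute ``shift`` is the integer image offset such that the
    bond vector from u to v (stored with u < v) is
    pos[v] - pos[u] + shift * box.
    """
    g = nx.Graph()
    poly = np.nonzero(system.species != WATER)[0]
    for i in poly:
        g.add_node(int(i), species=int(system.species[i]))
    for u, v in system.bonds:
        u, v = int(u), int(v)
        if system.species[u] == WATER or system.species[v] == WATER:
            raise TopologyError(f"bond ({u}, {v}) references a water bead")
        d = system.positions[v] - system.positions[u]
        img = np.round(d / system.box).astype(np.int64)
        g.add_edge(u, v, shift=-img)
    g.graph["box"] = system.box.copy()
    g.graph["positions"] = system.positions
    return g


def _edge_shift(g: nx.Graph, u: int, v: int) -> np.ndarray:
    """Image shift for traversal u -> v (edges store the u < v orientation)."""
    s = g.edges[u, v]["shift"]
    return s if u < v else -s


def _component_winding(g: nx.Graph, nodes) -> np.ndarray:
    """Per-axis percolation flags of one connected node set.

    BFS assigns each node an integer box offset; every non-tree edge whose
    offsets disagree closes a cycle with nonzero net image shift, i.e. a
    cycle that winds the box along that axis.
    """
    winding = np.zeros(3, dtype=bool)
    nodes = list(nodes)
    offset = {nodes[0]: np.zeros(3, dtype=np.int64)}
    stack = [nodes[0]]
    sub = set(nodes)
    while stack:
        u = stack.pop()
        for v in g.neighbors(u):
            if v not in sub:
                continue
            o = offset[u] + _edge_shift(g, u, v)
            if v in offset:
                winding |= offset[v] != o
            else:
                offset[v] = o
                stack.append(v)
    return winding


def percolating_components(g: nx.Graph, box=None):
    """Label connected components and flag box-winding (percolation) per axis.

    Returns ``(labels, flags)`` where ``labels`` maps node -> component id
    and ``flags[cid]`` is a 3-vector of booleans; a component is
    network-forming when it percolates along at least one axis.
    """
    labels = {}
    flags = []
    for cid, comp in enumerate(nx.connected_components(g)):
        for n in comp:
            labels[n] = cid
        flags.append(_component_winding(g, comp))
    return labels, flags


def _path_vector(g: nx.Graph, path) -> np.ndarray:
    """Sum of minimum-image bond vectors along a bead path (consistent lift)."""
    pos = g.graph["positions"]
    box = g.graph["box"]
    vec = np.zeros(3)
    for u, v in zip(path[:-1], path[1:]):
        d = pos[v] - pos[u]
        vec += d + _edge_shift(g, u, v) * box
    return vec


def _orientation(vec: np.ndarray):
    r = float(np.linalg.norm(vec))
    if r < 1e-12:
        return float("nan"), float("nan")
    theta = float(np.arctan2(vec[1], vec[0]) % (2.0 * np.pi))
    phi = float(np.arccos(np.clip(vec[2] / r, -1.0, 1.0)))
    return theta, phi


def _make_record(g: nx.Graph, chain_class: str, path, n_bonds: int,
                 loop: bool, r0: float) -> ChainRecord:
    vec = np.zeros(3) if loop else _path_vector(g, path)
    l0 = 0.0 if loop else float(np.linalg.norm(vec) / (n_bonds * r0))
    theta, phi = _orientation(vec)
    return ChainRecord(chain_class=chain_class, bead_path=list(path),
                       n_bonds=n_bonds, end_to_end=vec, l0=l0,
                       theta=theta, phi=phi)


def _tree_diameter_path(tree: nx.Graph):
    """Longest path of an acyclic graph (double BFS)."""
    start = next(iter(tree))
    far1 = max(nx.single_source_shortest_path_length(tree, start).items(),
               key=lambda kv: kv[1])[0]
    paths = nx.single_source_shortest_path(tree, far1)
    far2 = max(paths.items(), key=lambda kv: len(kv[1]))[0]
    return paths[far2]


def _branch_record(g: nx.Graph, piece, anchor, r0: float) -> ChainRecord:
    """A pruned pendant piece plus its anchor bond, as one BRANCH record."""
    sub = g.subgraph(piece)
    n_bonds = sub.number_of_edges() + 1  # + the bond up to the anchor
    # end-to-end from the anchor to the graph-farthest bead of the piece
    lengths = nx.single_source_shortest_path(g.subgraph(set(piece) | {anchor}),
                                             anchor)
    far = max(lengths.items(), key=lambda kv: len(kv[1]))[0]
    path = lengths[far]
    vec = _path_vector(g, path)
    l0 = float(np.linalg.norm(vec) / (n_bonds * r0))
    theta, phi = _orientation(vec)
    return ChainRecord(chain_class=BRANCH, bead_path=list(piece),
                       n_bonds=n_bonds, end_to_end=vec, l0=l0, theta=theta,
                       phi=phi)


def _segment_core(g: nx.Graph, core: nx.Graph, r0: float) -> list[ChainRecord]:
    """Split a percolating core into effective chains between junctions.

    Junctions are core nodes of degree >= 3; maximal junction-to-junction
    paths through degree-2 interiors become one EFFECTIVE record each; core
    components without junctions are pure cycles and yield one record whose
    end-to-end vector is the cycle's net winding displacement.
    """
    records = []
    for comp in nx.connected_components(core):
        sub = core.subgraph(comp)
        junctions = [n for n in sub if sub.degree(n) >= 3]
        if not junctions:
            # pure cycle (every node degree 2): walk it once
            start = next(iter(sub))
            path = [start]
            prev = None
            node = start
            while True:
                nbrs = [n for n in sub.neighbors(node) if n != prev]
                nxt = nbrs[0] if nbrs else prev
                path.append(nxt)
                prev, node = node, nxt
                if node == start:
                    break
            vec = _path_vector(g, path)
            n_bonds = sub.number_of_edges()
            l0 = float(np.linalg.norm(vec) / (n_bonds * r0))
            theta, phi = _orientation(vec)
            records.append(ChainRecord(chain_class=EFFECTIVE,
                                       bead_path=path[:-1], n_bonds=n_bonds,
                                       end_to_end=vec, l0=l0, theta=theta,
                                       phi=phi))
            continue
        visited = set()
        for j in junctions:
            for nb in sub.neighbors(j):
                edge = frozenset((j, nb))
                if edge in visited:
                    continue
                path = [j, nb]
                visited.add(edge)
                prev, node = j, nb
                while node not in junctions:
                    nxt = next(n for n in sub.neighbors(node) if n != prev
                               or sub.degree(node) == 1)
                    visited.add(frozenset((node, nxt)))
                    path.append(nxt)
                    prev, node = node, nxt
                loop = path[0] == path[-1]
                vec = _path_vector(g, path)
                n_bonds = len(path) - 1
                l0 = (0.0 if loop and np.linalg.norm(vec) < 1e-9
                      else float(np.linalg.norm(vec) / (n_bonds * r0)))
                theta, phi = _orientation(vec)
                records.append(ChainRecord(chain_class=EFFECTIVE,
                                           bead_path=path, n_bonds=n_bonds,
                                           end_to_end=vec, l0=l0,
                                           theta=theta, phi=phi))
    return records


def classify_chains(g: nx.Graph, percolation=None, r0: float = 1.0) -> list[ChainRecord]:
    """Partition the polymer graph into the five chain classes.

    Every bond is counted in exactly one record.  ``percolation`` may carry
    precomputed ``(labels, flags)`` from :func:`percolating_components`.
    """
    if percolation is None:
        percolation = percolating_components(g)
    labels, flags = percolation
    records: list[ChainRecord] = []

    for cid, comp in enumerate(nx.connected_components(g)):
        comp = set(comp)
        sub = g.subgraph(comp)
        if not flags[cid].any():
            # detached component: one record for the whole piece
            n_edges = sub.number_of_edges()
            if n_edges == 0:
                continue  # unreacted single bead: not a chain
            is_cyclic = n_edges >= len(comp)
            if not is_cyclic:
                path = _tree_diameter_path(sub)
                records.append(_make_record(g, ISOLATED_CHAIN, path, n_edges,
                                            loop=False, r0=r0))
            else:
                has_mbaa = any(g.nodes[n]["species"] == MBAA for n in comp)
                cls = CROSSLINKING_LOOP if has_mbaa else ISOLATED_LOOP
                records.append(_make_record(g, cls, sorted(comp), n_edges,
                                            loop=True, r0=r0))
            continue

        # percolating component: peel off dangling material
        core = g.subgraph(comp).copy()
        while True:
            # iterative leaf pruning; group the removed forest into pieces
            leaves = [n for n in core if core.degree(n) <= 1]
            pruned = set()
            while leaves:
                nxt = set()
                for n in leaves:
                    if core.degree(n) <= 1 and core.number_of_nodes() > 1:
                        nbrs = list(core.neighbors(n))
                        pruned.add(n)
                        core.remove_node(n)
                        for m in nbrs:
                            if core.has_node(m) and core.degree(m) <= 1:
                                nxt.add(m)
                leaves = sorted(nxt)
            if pruned:
                forest = g.subgraph(pruned)
                for piece in nx.connected_components(forest):
                    anchors = {m for n in piece for m in g.neighbors(n)
                               if m not in piece}
                    anchor = sorted(anchors)[0]
                    records.append(_branch_record(g, sorted(piece), anchor,
                                                  r0))
            # detach pendant subgraphs hanging from one bridge whose removal
            # leaves them non-percolating (covers pendant loops)
            detached = False
            for u, v in list(nx.bridges(core)):
                core.remove_edge(u, v)
                side_u = nx.node_connected_component(core, u)
                side_v = nx.node_connected_component(core, v)
                perc_u = _component_winding(g, side_u).any()
                perc_v = _component_winding(g, side_v).any()
                if perc_u and not perc_v:
                    piece, anchor = side_v, u
                elif perc_v and not perc_u:
                    piece, anchor = side_u, v
                else:
                    core.add_edge(u, v, **g.edges[u, v])
                    continue
                sub_piece = g.subgraph(piece)
                rec = ChainRecord(chain_class=BRANCH,
                                  bead_path=sorted(piece),
                                  n_bonds=sub_piece.number_of_edges() + 1,
                                  end_to_end=np.zeros(3), l0=0.0,
                                  theta=float("nan"), phi=float("nan"))
                # orientation/extension from the anchor where meaningful
                records.append(_fill_branch_geometry(g, rec, anchor, r0))
                core.remove_nodes_from(piece)
                detached = True
                break
            if not detached:
                # pruning was exhaustive and no bridge detaches: core final
                break
        records.extend(_segment_core(g, core, r0))
    return records


def _fill_branch_geometry(g: nx.Graph, rec: ChainRecord, anchor: int,
                          r0: float) -> ChainRecord:
    nodes = set(rec.bead_path) | {anchor}
    paths = nx.single_source_shortest_path(g.subgraph(nodes), anchor)
    far = max(paths.items(), key=lambda kv: len(kv[1]))[0]
    vec = _path_vector(g, paths[far])
    rec.end_to_end = vec
    rec.l0 = float(np.linalg.norm(vec) / (rec.n_bonds * r0))
    rec.theta, rec.phi = _orientation(vec)
    return rec


def chain_statistics(records: list[ChainRecord],
                     crosslink_rate: float | None = None) -> NetworkStats:
    """Aggregate counts, fractions and geometry over chain records.

    Number fractions are chain counts over total chains; length fractions
    are per-class bond counts over total bonds (the chain length is counted
    as the bond number of the chain).  l0 and orientation angles are
    collected over effective chains.
    """
    if not records:
        raise ValueError("no chain records to aggregate")
    n_chains = {c: 0 for c in CHAIN_CLASSES}
    bonds = {c: 0 for c in CHAIN_CLASSES}
    for r in records:
        n_chains[r.chain_class] += 1
        bonds[r.chain_class] += r.n_bonds
    total_chains = sum(n_chains.values())
    total_bonds = sum(bonds.values())
    number_fraction = {c: n_chains[c] / total_chains for c in CHAIN_CLASSES}
    length_fraction = {c: bonds[c] / total_bonds for c in CHAIN_CLASSES}
    mean_contour = {c: (bonds[c] / n_chains[c] if n_chains[c] else float("nan"))
                    for c in CHAIN_CLASSES}
    eff = [r for r in records if r.chain_class == EFFECTIVE]
    mean_e2e = (float(np.mean([np.linalg.norm(r.end_to_end) for r in eff]))
                if eff else float("nan"))
    l0 = np.array([r.l0 for r in eff])
    theta = np.array([r.theta for r in eff if np.isfinite(r.theta)])
    phi = np.array([r.phi for r in eff if np.isfinite(r.phi)])
    return NetworkStats(n_chains=n_chains, number_fraction=number_fraction,
                        bond_counts=bonds, length_fraction=length_fraction,
                        mean_contour=mean_contour,
                        mean_end_to_end_effective=mean_e2e,
                        l0_values=l0, theta_values=theta, phi_values=phi,
                        crosslink_rate=crosslink_rate)


def records_to_frame(records: list[ChainRecord]) -> pd.DataFrame:
    """Per-chain table (class, n_bonds, end-to-end, l0, theta, phi)."""
    return pd.DataFrame({
        "chain_class": [r.chain_class for r in records],
        "n_bonds": [r.n_bonds for r in records],
        "end_to_end": [float(np.linalg.norm(r.end_to_end)) for r in records],
        "l0": [r.l0 for r in records],
        "theta": [r.theta for r in records],
        "phi": [r.phi for r in records],
    })
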