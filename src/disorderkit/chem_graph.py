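"""Geometric bond perception, molecule partitioning and 1-2/1-3 pair lists.

Connectivity is perceived from a single conformer's Cartesian geometry
with the Cordero (2008) single-bond covalent radii and a fixed 0.40 A
tolerance.  Perception never mixes atoms of different disorder groups:
alternative disorder components are alternative realities and each
archetype is bonded on its own geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

#: Cordero et al. (2008) single-bond covalent radii, Angstrom.
COVALENT_RADII = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Sc": 1.70, "Ti": 1.60, "V": 1.53, "Cr": 1.39,
    "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24, "Cu": 1.32, "Zn": 1.22,
    "Ga": 1.22, "Ge": 1.20, "As": 1.19, "Se": 1.20, "Br": 1.20, "Kr": 1.16,
    "Rb": 2.20, "Sr": 1.95, "Y": 1.90, "Zr": 1.75, "Nb": 1.64, "Mo": 1.54,
    "Ru": 1.46, "Rh": 1.42, "Pd": 1.39, "Ag": 1.45, "Cd": 1.44, "In": 1.42,
    "Sn": 1.39, "Sb": 1.39, "Te": 1.38, "I": 1.39, "Xe": 1.40,
    "Cs": 2.44, "Ba": 2.15, "Pt": 1.36, "Au": 1.36, "Hg": 1.32, "Pb": 1.46,
    "Bi": 1.48, "U": 1.96,
}

#: Distance tolerance added to the radii sum, Angstrom.
BOND_TOLERANCE = 0.40


def covalent_radius(element: str) -> float:
    try:
        return COVALENT_RADII[element]
    except KeyError:
        raise KeyError(f"no covalent radius for element {element!r}")


@dataclass
class BondGraph:
    """Covalent connectivity over an indexed atom list."""

    elements: list
    positions: np.ndarray
    edges: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.edges = {tuple(sorted(e)) for e in self.edges}
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-edge in bond graph")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def neighbors(self, i: int) -> list:
        return sorted(j for a, b in self.edges for j in (a, b)
                      if (a == i or b == i) and j != i)

    def degree(self, i: int) -> int:
        return sum(1 for e in self.edges if i in e)

    def adjacency(self) -> list:
        adj = [[] for _ in range(self.n_atoms)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return [sorted(a) for a in adj]

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.positions[i] - self.positions[j]))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class MoleculeComponent:
    """A connected molecule: an index set into the parent site list."""

    component_id: int
    atoms: frozenset

    def __len__(self) -> int:
        return len(self.atoms)

    def sorted_atoms(self) -> list:
        return sorted(self.atoms)


def perceive_bonds(elements: Sequence[str], positions: np.ndarray,
                   tolerance: float = BOND_TOLERANCE,
                   extra_bonds: Optional[Iterable] = None,
                   removed_bonds: Optional[Iterable] = None) -> BondGraph:
    """Perceive covalent bonds: d(i,j) <= r_cov(i) + r_cov(j) + tolerance.

    A hydrogen that acquires more than one candidate bond keeps only the
    shortest.  ``extra_bonds`` / ``removed_bonds`` are user override hooks
    for cases where the distance rule gets the chemistry wrong.
    """
    elements = [e for e in elements]
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    radii = np.array([covalent_radius(e) for e in elements])
    n = len(elements)
    edges = set()
    if n > 1:
        tree = cKDTree(positions)
        rmax = 2.0 * radii.max() + tolerance
        for i, j in tree.query_pairs(rmax):
            d = np.linalg.norm(positions[i] - positions[j])
            if d <= radii[i] + radii[j] + tolerance:
                edges.add((min(i, j), max(i, j)))
    # hydrogens bond to their single nearest candidate only
    for h in [i for i, e in enumerate(elements) if e == "H"]:
        cand = [e for e in edges if h in e]
        if len(cand) > 1:
            keep = min(cand, key=lambda e: np.linalg.norm(
                positions[e[0]] - positions[e[1]]))
            edges -= {e for e in cand if e != keep}
    if removed_bonds:
        edges -= {tuple(sorted(b)) for b in removed_bonds}
    if extra_bonds:
        edges |= {tuple(sorted(b)) for b in extra_bonds}
    return BondGraph(elements=elements, positions=positions, edges=edges)


def molecule_components(graph: BondGraph) -> list:
    """Connected components, deterministically ordered by smallest member."""
    comps = sorted((sorted(c) for c in
                    nx.connected_components(graph.to_networkx())),
                   key=lambda c: c[0])
    return [MoleculeComponent(component_id=k, atoms=frozenset(c))
            for k, c in enumerate(comps)]


def one_two_pairs(graph: BondGraph) -> list:
    """Bonded (1-2) pairs, sorted."""
    return sorted(graph.edges)

def one_three_pairs(graph: BondGraph) -> list:
    """Angle-defining (1-3) pairs: a shared bonded neighbour, not bonded.

    A pair closing a three-membered ring is both 1-2 and 1-3; it is
    reported only as 1-2 (distance restraint targets must not conflict).
    """
    adj = graph.adjacency()
    pairs = set()
    for j in range(graph.n_atoms):
        for i, k in combinations(adj[j], 2):
            e = (min(i, k), max(i, k))
            if e not in graph.edges:
                pairs.add(e)
    return sorted(pairs)
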