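"""Independent reference implementations used to cross-check the package.

The fingerprint oracle enumerates every unordered heavy-atom pair and
takes shortest-path lengths from networkx, sharing no code with the
implementation under test beyond the per-atom typing functions.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from qsardnn.molgraph import (
    Bond,
    BondOrder,
    Atom,
    MolecularGraph,
    ap_atom_type,
    bp_atom_type,
)

ELEMENTS = ["C", "C", "C", "N", "O", "S", "F", "Cl"]
ORDERS = [
    BondOrder.SINGLE,
    BondOrder.SINGLE,
    BondOrder.DOUBLE,
    BondOrder.TRIPLE,
    BondOrder.AROMATIC,
]


def to_networkx(graph: MolecularGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_atoms))
    g.add_edges_from((b.i, b.j) for b in graph.bonds)
    return g


def brute_force_fingerprint(
    graph: MolecularGraph, scheme: str, max_distance: int
) -> dict[str, int]:
    """Pair enumeration + networkx shortest paths, as text-keyed counts."""
    if scheme == "AP":
        types = [str(ap_atom_type(graph, i)) for i in range(graph.n_atoms)]
    else:
        types = [str(bp_atom_type(graph, i)) for i in range(graph.n_atoms)]
    lengths = dict(nx.all_pairs_shortest_path_length(to_networkx(graph)))
    counts: dict[str, int] = {}
    for i in range(graph.n_atoms):
        for j in range(i + 1, graph.n_atoms):
            d = lengths.get(i, {}).get(j)
            if d is None or d < 1 or d > max_distance:
                continue
            a, b = sorted((types[i], types[j]))
            key = f"{scheme}|{a}|{d}|{b}"
            counts[key] = counts.get(key, 0) + 1
    return counts


def random_graph(rng: np.random.Generator, max_atoms: int = 12) -> MolecularGraph:
    """Random small molecule-like graph; mostly connected, sometimes not."""
    n = int(rng.integers(1, max_atoms + 1))
    atoms = [
        Atom(
            element=str(rng.choice(ELEMENTS)),
            formal_charge=int(rng.choice([0, 0, 0, 0, 1, -1])),
            attached_hydrogens=int(rng.integers(0, 4)),
        )
        for _ in range(n)
    ]
    bonds = []
    seen = set()
    for j in range(1, n):
        if rng.random() < 0.9:  # occasionally leave a fragment disconnected
            i = int(rng.integers(0, j))
            bonds.append(Bond(i, j, ORDERS[rng.integers(len(ORDERS))]))
            seen.add((i, j))
    n_extra = int(rng.integers(0, max(1, n // 3) + 1)) if n >= 2 else 0
    for _ in range(n_extra):
        i, j = sorted(rng.choice(n, size=2, replace=False).tolist())
        if (i, j) not in seen:
            bonds.append(Bond(i, j, ORDERS[rng.integers(len(ORDERS))]))
            seen.add((i, j))
    return MolecularGraph(atoms=atoms, bonds=bonds)
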