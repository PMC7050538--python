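"""Hydrogen-suppressed molecular graphs and pair-count fingerprints.

A molecule is represented as a graph over its heavy (non-hydrogen) atoms;
hydrogens are folded into an ``attached_hydrogens`` count on each atom.
From this graph two families of count fingerprints are generated:

* **Atom Pair (AP)** — atoms are typed by element, heavy-atom degree and
  number of pi electrons, written ``El(d,pi)``, e.g. ``C(2,0)``.
* **Binding Property (BP)** — also called donor-acceptor pair typing;
  atoms fall into exactly one of seven pharmacophoric categories
  (cation, anion, neutral donor, neutral acceptor, polar, hydrophobic,
  other).

A pair descriptor is ``type_i - distance_in_bonds - type_j`` where the
distance is the length of the shortest bond path between the two atoms.
The fingerprint of a molecule counts how often each descriptor occurs
over all unordered heavy-atom pairs within a distance cutoff.

Pi-electron convention (configurable in spirit, fixed here): each double
bond contributes 1 pi electron to both of its atoms, a triple bond 2,
and an aromatic bond 1. This matches common atom-pair implementations;
the original descriptor generators never published their exact counts.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "BondOrder",
    "Atom",
    "Bond",
    "MolecularGraph",
    "APAtomType",
    "BPCategory",
    "PairDescriptorKey",
    "FingerprintVector",
    "ap_atom_type",
    "bp_atom_type",
    "topological_distances",
    "generate_fingerprint",
    "merge_fingerprints",
    "graph_from_rdkit",
    "read_sdf",
]

# pi electrons contributed to each end atom, by bond order
_PI_CONTRIBUTION = {"single": 0, "double": 1, "triple": 2, "aromatic": 1}

HALOGENS = frozenset({"F", "Cl", "Br", "I"})


class BondOrder(str, enum.Enum):
    SINGLE = "single"
    DOUBLE = "double"
    TRIPLE = "triple"
    AROMATIC = "aromatic"


@dataclass(frozen=True)
class Atom:
    """One heavy atom; hydrogens live in ``attached_hydrogens``."""

    element: str
    formal_charge: int = 0
    attached_hydrogens: int = 0

    def __post_init__(self) -> None:
        if not self.element or self.element == "H":
            raise ValueError(
                "explicit hydrogen atoms are not allowed in a "
                "hydrogen-suppressed graph"
            )
        if self.attached_hydrogens < 0:
            raise ValueError("attached_hydrogens must be >= 0")


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: BondOrder = BondOrder.SINGLE

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError(f"self-bond on atom {self.i}")
        object.__setattr__(self, "order", BondOrder(self.order))


@dataclass
class MolecularGraph:
    """Hydrogen-suppressed molecule: typed heavy atoms plus bonds.

    Invariants enforced on construction: at least one atom, bond indices
    in range, no self-bonds, no duplicate unordered bond pairs.
    """

    atoms: list[Atom]
    bonds: list[Bond] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a molecular graph needs at least one atom")
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i},{b.j}) out of range for {n} atoms")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, atom_index: int) -> list[int]:
        self._check_index(atom_index)
        out = []
        for b in self.bonds:
            if b.i == atom_index:
                out.append(b.j)
            elif b.j == atom_index:
                out.append(b.i)
        return out

    def heavy_degree(self, atom_index: int) -> int:
        """Number of bonded non-hydrogen neighbours."""
        return len(self.neighbors(atom_index))

    def pi_electrons(self, atom_index: int) -> int:
        """Pi electrons on an atom under the documented bond convention."""
        self._check_index(atom_index)
        total = 0
        for b in self.bonds:
            if atom_index in (b.i, b.j):
                total += _PI_CONTRIBUTION[b.order.value]
        return total

    def _check_index(self, atom_index: int) -> None:
        if not (0 <= atom_index < len(self.atoms)):
            raise IndexError(
                f"atom index {atom_index} out of range (n={len(self.atoms)})"
            )


@dataclass(frozen=True, order=True)
class APAtomType:
    """Atom-pair type: element, heavy degree, pi-electron count.

    The canonical text form is ``El(d,pi)`` and round-trips to the
    fields via :meth:`from_text`.
    """

    element: str
    heavy_degree: int
    pi_electrons: int

    def __str__(self) -> str:
        return f"{self.element}({self.heavy_degree},{self.pi_electrons})"

    @classmethod
    def from_text(cls, text: str) -> "APAtomType":
        el, rest = text.split("(", 1)
        d, pi = rest.rstrip(")").split(",")
        return cls(el, int(d), int(pi))


class BPCategory(str, enum.Enum):
    """The seven binding-property (donor-acceptor pair) classes."""

    CATION = "cation"
    ANION = "anion"
    NEUTRAL_DONOR = "neutral_donor"
    NEUTRAL_ACCEPTOR = "neutral_acceptor"
    POLAR = "polar"
    HYDROPHOBIC = "hydrophobic"
    OTHER = "other"

    def __str__(self) -> str:  # canonical text form used in descriptor keys
        return self.value


def ap_atom_type(graph: MolecularGraph, atom_index: int) -> APAtomType:
    """Atom-pair type of one atom: element, heavy degree, pi electrons."""
    graph._check_index(atom_index)
    return APAtomType(
        element=graph.atoms[atom_index].element,
        heavy_degree=graph.heavy_degree(atom_index),
        pi_electrons=graph.pi_electrons(atom_index),
    )


def bp_atom_type(graph: MolecularGraph, atom_index: int) -> BPCategory:
    """Binding-property category of one atom.

    Rule table, evaluated in fixed precedence order:

    1. formal charge > 0           -> cation
    2. formal charge < 0           -> anion
    3. N/O donor but not acceptor  -> neutral_donor
    4. N/O acceptor but not donor  -> neutral_acceptor
    5. donor and acceptor at once  -> polar  (e.g. hydroxyl oxygen)
    6. carbon or halogen           -> hydrophobic
    7. anything else               -> other

    Donor means an N or O carrying at least one hydrogen. Acceptor means
    an oxygen, or a nitrogen with an available lone pair — a nitrogen
    whose pi electrons are engaged while it also bears a hydrogen
    (pyrrole-like NH) is treated as donor-only.
    """
    graph._check_index(atom_index)
    atom = graph.atoms[atom_index]
    if atom.formal_charge > 0:
        return BPCategory.CATION
    if atom.formal_charge < 0:
        return BPCategory.ANION
    if atom.element in ("N", "O"):
        is_donor = atom.attached_hydrogens > 0
        if atom.element == "O":
            is_acceptor = True
        else:  # N: pyrrole-like NH has no available lone pair
            is_acceptor = not (graph.pi_electrons(atom_index) > 0 and is_donor)
        if is_donor and is_acceptor:
            return BPCategory.POLAR
        if is_donor:
            return BPCategory.NEUTRAL_DONOR
        return BPCategory.NEUTRAL_ACCEPTOR
    if atom.element == "C" or atom.element in HALOGENS:
        return BPCategory.HYDROPHOBIC
    return BPCategory.OTHER


def topological_distances(graph: MolecularGraph) -> np.ndarray:
    """All-pairs shortest bond-path lengths.

    Returns an ``(n, n)`` float matrix: symmetric, zero diagonal,
    ``np.inf`` for atom pairs in different connected components.
    """
    n = graph.n_atoms
    if not graph.bonds:
        d = np.full((n, n), np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    rows = [b.i for b in graph.bonds] + [b.j for b in graph.bonds]
    cols = [b.j for b in graph.bonds] + [b.i for b in graph.bonds]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return shortest_path(adj, method="BF", unweighted=True, directed=False)


@dataclass(frozen=True, order=True)
class PairDescriptorKey:
    """Canonical ``scheme | type_a | distance | type_b`` descriptor key.

    ``type_a <= type_b`` lexicographically; the text serialization
    (``AP|C(1,0)|2|C(2,0)``) is stable and usable as a CSV header.
    """

    scheme: str  # "AP" or "BP"
    type_a: str
    distance: int
    type_b: str

    def __post_init__(self) -> None:
        if self.scheme not in ("AP", "BP"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.distance < 1:
            raise ValueError("pair distance must be >= 1")
        if self.type_a > self.type_b:
            a, b = self.type_b, self.type_a
            object.__setattr__(self, "type_a", a)
            object.__setattr__(self, "type_b", b)

    @classmethod
    def make(cls, scheme: str, t1: str, t2: str, distance: int) -> "PairDescriptorKey":
        a, b = sorted((t1, t2))
        return cls(scheme=scheme, type_a=a, distance=distance, type_b=b)

    def to_text(self) -> str:
        return f"{self.scheme}|{self.type_a}|{self.distance}|{self.type_b}"

    @classmethod
    def from_text(cls, text: str) -> "PairDescriptorKey":
        scheme, a, d, b = text.split("|")
        return cls(scheme=scheme, type_a=a, distance=int(d), type_b=b)


class FingerprintVector:
    """Sparse non-negative integer counts keyed by canonical descriptors.

    Absent keys read as zero; stored counts are strictly positive.
    """

    def __init__(self, counts: dict[PairDescriptorKey, int] | None = None):
        self._counts: dict[PairDescriptorKey, int] = {}
        if counts:
            for k, v in counts.items():
                self.add(k, v)

    def add(self, key: PairDescriptorKey, count: int = 1) -> None:
        if count < 0:
            raise ValueError("fingerprint counts cannot be negative")
        if count == 0:
            return
        self._counts[key] = self._counts.get(key, 0) + count

    def __getitem__(self, key: PairDescriptorKey) -> int:
        return self._counts.get(key, 0)

    def __len__(self) -> int:
        return len(self._counts)

    def __iter__(self):
        return iter(self._counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FingerprintVector):
            return NotImplemented
        return self._counts == other._counts

    def __repr__(self) -> str:
        items = ", ".join(
            f"{k.to_text()}: {v}" for k, v in sorted(self._counts.items())
        )
        return f"FingerprintVector({{{items}}})"

    def items(self):
        return self._counts.items()

    def total(self) -> int:
        return sum(self._counts.values())

    @property
    def schemes(self) -> set[str]:
        return {k.scheme for k in self._counts}

    def to_text_counts(self) -> dict[str, int]:
        """Serialize to ``{key text: count}``, keys sorted."""
        return {k.to_text(): v for k, v in sorted(self._counts.items())}

    @classmethod
    def from_text_counts(cls, counts: dict[str, int]) -> "FingerprintVector":
        return cls({PairDescriptorKey.from_text(k): v for k, v in counts.items()})


def generate_fingerprint(
    graph: MolecularGraph, scheme: str = "AP", max_distance: int = 7
) -> FingerprintVector:
    """Count pair descriptors over all unordered heavy-atom pairs.

    One increment per pair at shortest-path distance ``1..max_distance``.
    For a connected graph whose diameter fits inside the cutoff the
    total count is therefore ``n(n-1)/2``.
    """
    if scheme not in ("AP", "BP"):
        raise ValueError(f"unknown scheme {scheme!r}; expected 'AP' or 'BP'")
    if max_distance < 1:
        raise ValueError("max_distance must be >= 1")
    n = graph.n_atoms
    if scheme == "AP":
        types = [str(ap_atom_type(graph, i)) for i in range(n)]
    else:
        types = [str(bp_atom_type(graph, i)) for i in range(n)]
    dist = topological_distances(graph)
    fp = FingerprintVector()
    for i, j in itertools.combinations(range(n), 2):
        d = dist[i, j]
        if np.isfinite(d) and 1 <= d <= max_distance:
            fp.add(PairDescriptorKey.make(scheme, types[i], types[j], int(d)))
    return fp


def merge_fingerprints(
    ap: FingerprintVector, bp: FingerprintVector
) -> FingerprintVector:
    """Unified AP+BP fingerprint: key-disjoint union of the two vectors."""
    if ap.schemes - {"AP"}:
        raise ValueError("first argument must contain only AP keys")
    if bp.schemes - {"BP"}:
        raise ValueError("second argument must contain only BP keys")
    merged = FingerprintVector()
    for k, v in ap.items():
        merged.add(k, v)
    for k, v in bp.items():
        merged.add(k, v)
    return merged


# -- RDKit bridge -----------------------------------------------------------

_RDKIT_BOND_ORDERS = {
    "SINGLE": BondOrder.SINGLE,
    "DOUBLE": BondOrder.DOUBLE,
    "TRIPLE": BondOrder.TRIPLE,
    "AROMATIC": BondOrder.AROMATIC,
}


def graph_from_rdkit(mol) -> MolecularGraph:
    """Convert an RDKit molecule to the internal hydrogen-suppressed graph."""
    from rdkit import Chem

    mol = Chem.RemoveHs(mol)
    index_map = {}
    atoms = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            continue
        index_map[atom.GetIdx()] = len(atoms)
        atoms.append(
            Atom(
                element=atom.GetSymbol(),
                formal_charge=atom.GetFormalCharge(),
                attached_hydrogens=atom.GetTotalNumHs(),
            )
        )
    bonds = []
    for bond in mol.GetBonds():
        bi, bj = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if bi not in index_map or bj not in index_map:
            continue
        order = _RDKIT_BOND_ORDERS.get(str(bond.GetBondType()))
        if order is None:
            raise ValueError(f"unsupported bond type {bond.GetBondType()}")
        bonds.append(Bond(index_map[bi], index_map[bj], order))
    return MolecularGraph(atoms=atoms, bonds=bonds)


def read_sdf(path) -> list[MolecularGraph]:
    """Read an SDF (MDL molfile, V2000) into molecular graphs."""
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    graphs = []
    for mol in supplier:
        if mol is None:
            raise ValueError(f"unparseable molecule record in {path}")
        graphs.append(graph_from_rdkit(mol))
    return graphs
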