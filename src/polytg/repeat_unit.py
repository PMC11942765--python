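"""Repeat-unit molecular graphs with the infinite-chain closure convention.

A polymer repeat unit is written as SMILES with exactly two ``[*]``
attachment points.  To recover every atom's environment in the infinite
chain, the two heavy atoms bonded to the wildcards are joined by a single
*virtual* closure bond: each attachment atom then has the degree it would
have mid-chain, and the inter-unit bond is counted exactly once per repeat
unit.  The closure bond may be a parallel edge (attachment atoms already
bonded, e.g. vinyl polymers) or a self-loop (single-atom units such as
polymethylene ``[*]C[*]``); a :class:`networkx.MultiGraph` represents both
correctly, and the self-loop contributes 2 to the degree as required.

Ring perception, aromaticity and substructure matching run on a "cyclized"
RDKit molecule (wildcards removed, closure bond installed) so that
functional groups spanning the unit boundary — e.g. the second ester of a
polyester written with the split across the ``[*]`` ends — are still seen.
Rings that exist only because of the closure bond (the macrocycle every
linear backbone becomes) are filtered out of all ring-based quantities.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import networkx as nx
from rdkit import Chem

from .elements import ATOMIC_WEIGHTS, SUPPORTED_ELEMENTS, kier_hall_valence_delta
from .errors import ParseError, StructureError, UnsupportedElementError

CLOSURE_KEY = "closure"


class RingClass(enum.Enum):
    NONE = "none"
    AROMATIC = "aromatic"
    SATURATED_ISOLATED = "saturated_isolated"
    OTHER = "other"


class BondOrder(enum.Enum):
    SINGLE = "single"
    DOUBLE = "double"
    TRIPLE = "triple"
    AROMATIC = "aromatic"


_RDKIT_ORDER = {
    Chem.BondType.SINGLE: BondOrder.SINGLE,
    Chem.BondType.DOUBLE: BondOrder.DOUBLE,
    Chem.BondType.TRIPLE: BondOrder.TRIPLE,
    Chem.BondType.AROMATIC: BondOrder.AROMATIC,
}


@dataclass
class AtomNode:
    index: int
    element: str
    h_count: int
    delta: int
    delta_v: float
    aromatic: bool
    in_ring: bool
    ring_class: RingClass = RingClass.NONE
    on_backbone: bool = False


@dataclass
class BondEdge:
    i: int
    j: int
    order: BondOrder
    in_ring: bool = False
    rotatable: bool = False
    on_backbone: bool = False
    virtual: bool = False


@dataclass
class Backbone:
    """Shortest path between the attachment atoms plus fused-ring atoms."""

    path_atoms: list[int]
    atoms: frozenset[int]

    @property
    def n_sp(self) -> int:
        return len(self.path_atoms)

    @property
    def n_bb(self) -> int:
        return len(self.atoms)


@dataclass
class RepeatUnit:
    id: str
    smiles: str
    atoms: list[AtomNode]
    bonds: list[BondEdge]
    attachment_atoms: tuple[int, int]
    closure_bond: BondEdge
    graph: nx.MultiGraph = field(repr=False)
    mol: Chem.Mol = field(repr=False)  # cyclized, heavy atoms only
    real_rings: list[tuple[frozenset[int], frozenset[tuple[int, int]], bool]] = field(
        repr=False, default_factory=list
    )  # (atom set, bond set as sorted pairs, is_aromatic)
    closure_in_mol: bool = False
    _backbone: Backbone | None = field(default=None, repr=False)

    @property
    def n_heavy(self) -> int:
        return len(self.atoms)

    def ring_bond_pairs(self) -> set[tuple[int, int]]:
        """Bonds that belong to at least one genuine (non-closure) ring."""
        pairs: set[tuple[int, int]] = set()
        for _, bond_set, _ in self.real_rings:
            pairs |= bond_set
        return pairs

    def molecular_weight(self) -> float:
        m = 0.0
        for a in self.atoms:
            m += ATOMIC_WEIGHTS[a.element] + a.h_count * ATOMIC_WEIGHTS["H"]
        return m


def valence_delta(atom: AtomNode) -> float:
    """Kier-Hall valence delta of a heavy atom (see :mod:`polytg.elements`)."""
    return kier_hall_valence_delta(atom.element, atom.h_count)


def _bond_pair(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i <= j else (j, i)


def parse_repeat_unit(smiles: str, id: str = "") -> RepeatUnit:
    """Parse a two-wildcard polymer SMILES into an annotated RepeatUnit.

    Raises
    ------
    ParseError
        if the SMILES cannot be parsed.
    StructureError
        if there are not exactly two ``[*]`` attachment points, a wildcard
        is not bonded to exactly one heavy atom, or the heavy-atom graph is
        disconnected.
    UnsupportedElementError
        for elements outside the supported census set.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"{id or smiles!r}: could not parse SMILES {smiles!r}")

    wildcards = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(wildcards) != 2:
        raise StructureError(
            f"{id or smiles!r}: expected exactly 2 [*] attachment points, "
            f"found {len(wildcards)}"
        )

    attach_orig: list[int] = []
    for w in wildcards:
        nbrs = [n for n in mol.GetAtomWithIdx(w).GetNeighbors()]
        heavy = [n.GetIdx() for n in nbrs if n.GetAtomicNum() > 0]
        if len(nbrs) != 1 or len(heavy) != 1:
            raise StructureError(
                f"{id or smiles!r}: each [*] must be bonded to exactly one heavy atom"
            )
        attach_orig.append(heavy[0])

    heavy_orig = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 0]
    if not heavy_orig:
        raise StructureError(f"{id or smiles!r}: no heavy atoms")
    new_index = {orig: k for k, orig in enumerate(heavy_orig)}

    for orig in heavy_orig:
        sym = mol.GetAtomWithIdx(orig).GetSymbol()
        if sym not in SUPPORTED_ELEMENTS:
            raise UnsupportedElementError(
                f"{id or smiles!r}: unsupported element {sym!r}"
            )

    h_counts = {new_index[o]: mol.GetAtomWithIdx(o).GetTotalNumHs() for o in heavy_orig}
    att_i, att_j = (new_index[attach_orig[0]], new_index[attach_orig[1]])

    # Heavy-atom multigraph with the virtual closure edge.
    graph = nx.MultiGraph()
    graph.add_nodes_from(range(len(heavy_orig)))
    bonds: list[BondEdge] = []
    for b in mol.GetBonds():
        bi, bj = b.GetBeginAtom(), b.GetEndAtom()
        if bi.GetAtomicNum() == 0 or bj.GetAtomicNum() == 0:
            continue
        i, j = new_index[bi.GetIdx()], new_index[bj.GetIdx()]
        order = _RDKIT_ORDER[b.GetBondType()]
        graph.add_edge(i, j, key=None)
        bonds.append(BondEdge(i=i, j=j, order=order))
    graph.add_edge(att_i, att_j, key=CLOSURE_KEY)
    closure = BondEdge(i=att_i, j=att_j, order=BondOrder.SINGLE, virtual=True)

    # Connectivity of the heavy-atom graph (closure not needed for this).
    plain = nx.Graph((b.i, b.j) for b in bonds)
    plain.add_nodes_from(range(len(heavy_orig)))
    if not nx.is_connected(plain):
        raise StructureError(
            f"{id or smiles!r}: heavy-atom graph is disconnected after "
            "removing wildcards"
        )

    cyc, lin, closure_in_mol = _build_cyclized_mol(
        mol, wildcards, heavy_orig, att_i, att_j
    )

    # Genuine rings are perceived on the *linear* molecule: the closure bond
    # represents the inter-unit bond and never creates an intra-unit ring
    # (every linear backbone would otherwise become a macrocycle, and chords
    # across real rings would corrupt their SSSR).
    real_rings = _perceive_real_rings(lin)
    ring_atoms: set[int] = set()
    aromatic_ring_atoms: set[int] = set()
    for atom_set, _, is_arom in real_rings:
        ring_atoms |= atom_set
        if is_arom:
            aromatic_ring_atoms |= atom_set

    atoms: list[AtomNode] = []
    for k in range(len(heavy_orig)):
        rd = cyc.GetAtomWithIdx(k)
        elem = rd.GetSymbol()
        h = h_counts[k]
        delta = graph.degree(k)
        atoms.append(
            AtomNode(
                index=k,
                element=elem,
                h_count=h,
                delta=int(delta),
                delta_v=kier_hall_valence_delta(elem, h),
                aromatic=bool(rd.GetIsAromatic()),
                in_ring=k in ring_atoms,
            )
        )

    ring_pairs: set[tuple[int, int]] = set()
    for _, bond_set, _ in real_rings:
        ring_pairs |= bond_set
    for b in bonds:
        b.in_ring = _bond_pair(b.i, b.j) in ring_pairs

    unit = RepeatUnit(
        id=id,
        smiles=smiles,
        atoms=atoms,
        bonds=bonds,
        attachment_atoms=(att_i, att_j),
        closure_bond=closure,
        graph=graph,
        mol=cyc,
        real_rings=real_rings,
        closure_in_mol=closure_in_mol,
    )
    _classify_ring_atoms(unit)
    perceive_backbone(unit)
    return unit


def _build_cyclized_mol(
    mol: Chem.Mol,
    wildcards: list[int],
    heavy_orig: list[int],
    att_i: int,
    att_j: int,
) -> tuple[Chem.Mol, Chem.Mol, bool]:
    """Remove wildcards, returning the cyclized and the linear molecule.

    Hydrogen counts are frozen beforehand so removing the wildcard neighbour
    does not grow implicit hydrogens.  The cyclized molecule carries the
    closure bond where RDKit allows it (parallel edges and self-loops
    cannot be represented; in those cases the closure lives only in the
    networkx multigraph).
    """
    rw = Chem.RWMol(mol)
    for a in rw.GetAtoms():
        if a.GetAtomicNum() > 0:
            a.SetNumExplicitHs(a.GetTotalNumHs())
            a.SetNoImplicit(True)
    for w in sorted(wildcards, reverse=True):
        rw.RemoveAtom(w)
    # After removing the (terminal) wildcards, heavy atoms keep their order,
    # so RDKit indices now coincide with our 0..n-1 heavy indices.
    lin = Chem.Mol(rw.GetMol())
    Chem.SanitizeMol(lin)
    closure_in_mol = False
    if att_i != att_j and rw.GetBondBetweenAtoms(att_i, att_j) is None:
        rw.AddBond(att_i, att_j, Chem.BondType.SINGLE)
        closure_in_mol = True
    cyc = rw.GetMol()
    Chem.SanitizeMol(cyc)
    return cyc, lin, closure_in_mol


def _perceive_real_rings(
    lin: Chem.Mol,
) -> list[tuple[frozenset[int], frozenset[tuple[int, int]], bool]]:
    ri = lin.GetRingInfo()
    rings = []
    for atom_ring, bond_ring in zip(ri.AtomRings(), ri.BondRings()):
        pairs = set()
        for bidx in bond_ring:
            b = lin.GetBondWithIdx(bidx)
            pairs.add(_bond_pair(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        is_arom = all(lin.GetAtomWithIdx(a).GetIsAromatic() for a in atom_ring)
        rings.append((frozenset(atom_ring), frozenset(pairs), is_arom))
    return rings


def _classify_ring_atoms(unit: RepeatUnit) -> None:
    iso_sat = isolated_saturated_rings(unit)
    iso_atoms = set().union(*iso_sat) if iso_sat else set()
    for a in unit.atoms:
        if not a.in_ring:
            a.ring_class = RingClass.NONE
        elif a.aromatic:
            a.ring_class = RingClass.AROMATIC
        elif a.index in iso_atoms:
            a.ring_class = RingClass.SATURATED_ISOLATED
        else:
            a.ring_class = RingClass.OTHER


def isolated_saturated_rings(unit: RepeatUnit) -> list[frozenset[int]]:
    """Saturated carbocycles (cyclohexyl/cyclopentyl-type) not fused to
    any other genuine ring."""
    out = []
    for k, (atom_set, bond_set, is_arom) in enumerate(unit.real_rings):
        if is_arom:
            continue
        if any(unit.atoms[a].element != "C" for a in atom_set):
            continue
        orders = []
        for (i, j) in bond_set:
            orders.extend(
                b.order for b in unit.bonds if _bond_pair(b.i, b.j) == (i, j)
            )
        if any(o is not BondOrder.SINGLE for o in orders):
            continue
        fused = any(
            other_atoms & atom_set
            for m, (other_atoms, _, _) in enumerate(unit.real_rings)
            if m != k
        )
        if not fused:
            out.append(atom_set)
    return out


def perceive_backbone(
    unit: RepeatUnit, fused_ring_policy: str = "all_atoms"
) -> Backbone:
    """Identify the backbone of a repeat unit.

    The backbone path is the shortest path between the two attachment atoms
    in the heavy-atom graph *without* the closure bond (ties broken by the
    lexicographically smallest atom-index sequence).  With the default
    ``fused_ring_policy="all_atoms"``, every atom of a genuine ring sharing
    at least two atoms with that path is also assigned to the backbone, so
    rings traversed by the chain belong to it while pendant rings do not;
    ``"shortest_arc"`` keeps only the path atoms.  Side effects: sets the
    ``on_backbone`` flags on atoms and bonds and caches the result.
    """
    if fused_ring_policy not in ("all_atoms", "shortest_arc"):
        raise ValueError(f"unknown fused_ring_policy {fused_ring_policy!r}")

    att_i, att_j = unit.attachment_atoms
    if att_i == att_j:
        path = [att_i]
    else:
        plain = nx.Graph()
        plain.add_nodes_from(range(unit.n_heavy))
        plain.add_edges_from((b.i, b.j) for b in unit.bonds)
        path = min(
            (tuple(p) for p in nx.all_shortest_paths(plain, att_i, att_j)),
        )
        path = list(path)

    backbone_atoms = set(path)
    if fused_ring_policy == "all_atoms":
        path_set = set(path)
        for atom_set, _, _ in unit.real_rings:
            if len(atom_set & path_set) >= 2:
                backbone_atoms |= atom_set

    bb = Backbone(path_atoms=path, atoms=frozenset(backbone_atoms))
    for a in unit.atoms:
        a.on_backbone = a.index in backbone_atoms
    for b in unit.bonds:
        b.on_backbone = b.i in backbone_atoms and b.j in backbone_atoms
    unit.closure_bond.on_backbone = True
    unit._backbone = bb
    return bb


def get_backbone(unit: RepeatUnit) -> Backbone:
    if unit._backbone is None:
        return perceive_backbone(unit)
    return unit._backbone
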