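"""Topological descriptor engine for polymer repeat units.

Computes the 22-feature vector used for Tg modelling: atom counts and molar
mass, a functional-group census (esters split by backbone membership and
aromatic conjugation, ethers, hydroxyls, ...), the group-contribution term
N_K, the molar-volume proxy Nmv, the rotational-degrees-of-freedom parameter
N_rot, the shortest backbone path N_SP, zeroth- and first-order molecular
connectivity indices (simple and valence), and two backbone steric-hindrance
indices.  All quantities are evaluated on the closure-augmented repeat-unit
graph so that each atom sees its infinite-chain environment and the
inter-unit bond is counted exactly once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Callable, Sequence

from rdkit import Chem

from .errors import ComputationError
from .repeat_unit import (
    Backbone,
    BondOrder,
    CLOSURE_KEY,
    RepeatUnit,
    get_backbone,
    isolated_saturated_rings,
)

#: Canonical feature order for tables and CSV output.
FEATURE_NAMES: list[str] = [
    "N", "N_C", "N_H",
    "N_ester_n", "N_ester_c",
    "N_aromaticring", "N_CH2", "N_ether", "N_backbone_O", "N_O",
    "M", "N_alkyl_ether",
    "N_rot", "N_K", "N_SP", "Nmv",
    "chi0", "chi0v", "chi1", "chi1v",
    "BB_index1", "BB_index2",
]


@dataclass
class FunctionalGroupCensus:
    """Counts of the functional groups entering N_K, Nmv and the ester/ether
    features.  ``n_ester_2c`` holds backbone esters conjugated to aromatic
    rings on *both* sides, which belong to neither N_ester_n nor N_ester_c
    and are reported separately."""

    n_amide: int = 0
    n_cyanide: int = 0
    n_carbonate: int = 0
    n_Cl: int = 0
    n_Br: int = 0
    n_hydroxyl: int = 0
    n_ether: int = 0
    n_CdoubleC: int = 0
    n_sulfone: int = 0
    n_acrylic_ester: int = 0
    n_isolated_saturated_ring: int = 0
    n_ester_total: int = 0
    n_ester_n: int = 0
    n_ester_c: int = 0
    n_ester_2c: int = 0
    n_alkyl_ether: int = 0
    n_aromatic_ring: int = 0
    n_CH2: int = 0
    n_backbone_O: int = 0
    n_O: int = 0


@dataclass
class DescriptorVector:
    id: str
    smiles: str
    N: int
    N_C: int
    N_H: int
    N_ester_n: int
    N_ester_c: int
    N_aromaticring: int
    N_CH2: int
    N_ether: int
    N_backbone_O: int
    N_O: int
    M: float
    N_alkyl_ether: int
    N_rot: float
    N_K: float
    N_SP: int
    Nmv: float
    chi0: float
    chi0v: float
    chi1: float
    chi1v: float
    BB_index1: float
    BB_index2: float
    census: FunctionalGroupCensus = field(repr=False, default=None)

    def to_dict(self) -> dict:
        d = {"id": self.id, "smiles": self.smiles}
        d.update({name: getattr(self, name) for name in FEATURE_NAMES})
        return d


def count_atoms(unit: RepeatUnit) -> tuple[int, int, int, int, float]:
    """(N, N_C, N_H, N_O, M): heavy-atom, carbon, hydrogen and oxygen counts
    and the repeat-unit molar mass in g/mol (wildcards excluded)."""
    n = unit.n_heavy
    n_c = sum(1 for a in unit.atoms if a.element == "C")
    n_h = sum(a.h_count for a in unit.atoms)
    n_o = sum(1 for a in unit.atoms if a.element == "O")
    return n, n_c, n_h, n_o, unit.molecular_weight()


_ESTER = Chem.MolFromSmarts("[CX3](=[OX1])[OX2][#6]")
_AMIDE = Chem.MolFromSmarts("[CX3](=[OX1])[NX3]")
_CARBONATE = Chem.MolFromSmarts("[OX2][CX3](=[OX1])[OX2]")
_NITRILE = Chem.MolFromSmarts("[CX2]#[NX1]")
_SULFONE = Chem.MolFromSmarts("[#16X4](=[OX1])(=[OX1])")
_HYDROXYL = Chem.MolFromSmarts("[OX2H]")


def census_functional_groups(unit: RepeatUnit) -> FunctionalGroupCensus:
    """Pattern-match the functional groups of one repeat unit.

    Substructure matching runs on the cyclized molecule, so groups spanning
    the unit boundary (e.g. the ester completed by the inter-unit bond in a
    polyester) are counted.  Backbone membership of ester atoms decides the
    N_ester_n / N_ester_c split; an ester pendant to the backbone via its
    carbonyl carbon is an acrylic-type ester for the N_K term.
    """
    mol = unit.mol
    bb = get_backbone(unit)
    on_bb = bb.atoms
    c = FunctionalGroupCensus()

    # --- esters -----------------------------------------------------------
    # carbonate carbons are censused separately and must not double-count
    # as two esters
    carbonate_carbons = {m[1] for m in mol.GetSubstructMatches(_CARBONATE)}
    ester_oxygens: set[int] = set()
    seen: set[tuple[int, int]] = set()
    for match in mol.GetSubstructMatches(_ESTER):
        c_carb, o_dbl, o_est = match[0], match[1], match[2]
        if c_carb in carbonate_carbons or (c_carb, o_est) in seen:
            continue
        seen.add((c_carb, o_est))
        ester_oxygens.add(o_est)
        c.n_ester_total += 1
        conj_c = any(
            nbr.GetIsAromatic()
            for nbr in mol.GetAtomWithIdx(c_carb).GetNeighbors()
            if nbr.GetIdx() not in (o_dbl, o_est)
        )
        conj_o = any(
            nbr.GetIsAromatic()
            for nbr in mol.GetAtomWithIdx(o_est).GetNeighbors()
            if nbr.GetIdx() != c_carb
        )
        n_conj = int(conj_c) + int(conj_o)
        if c_carb in on_bb and o_est in on_bb:
            if n_conj == 0:
                c.n_ester_n += 1
            elif n_conj == 1:
                c.n_ester_c += 1
            else:
                c.n_ester_2c += 1
        elif any(
            nbr.GetIdx() in on_bb
            for nbr in mol.GetAtomWithIdx(c_carb).GetNeighbors()
        ):
            c.n_acrylic_ester += 1

    # --- other carbonyl/hetero groups ------------------------------------
    c.n_amide = len(
        {(m[0], m[2]) for m in mol.GetSubstructMatches(_AMIDE)}
    )
    # a carbonate is identified by its (unique) carbonyl carbon
    c.n_carbonate = len(carbonate_carbons)
    for m in mol.GetSubstructMatches(_CARBONATE):
        ester_oxygens.update((m[0], m[3]))
    c.n_cyanide = len(mol.GetSubstructMatches(_NITRILE))
    c.n_sulfone = len({m[0] for m in mol.GetSubstructMatches(_SULFONE)})
    c.n_hydroxyl = len(mol.GetSubstructMatches(_HYDROXYL))
    c.n_Cl = sum(1 for a in unit.atoms if a.element == "Cl")
    c.n_Br = sum(1 for a in unit.atoms if a.element == "Br")
    c.n_O = sum(1 for a in unit.atoms if a.element == "O")
    c.n_backbone_O = sum(
        1 for a in unit.atoms if a.element == "O" and a.index in on_bb
    )

    # --- ethers -----------------------------------------------------------
    # An ether -O- is a divalent oxygen bonded to two carbons; oxygens that
    # are part of an ester or carbonate group are not double-counted.
    for a in unit.atoms:
        if a.element != "O" or a.h_count != 0 or a.index in ester_oxygens:
            continue
        nbrs = mol.GetAtomWithIdx(a.index).GetNeighbors()
        if len(nbrs) != 2 or not all(n.GetSymbol() == "C" for n in nbrs):
            continue
        if any(
            b.GetBondType() != Chem.BondType.SINGLE
            for b in mol.GetAtomWithIdx(a.index).GetBonds()
        ):
            continue
        c.n_ether += 1
        if all(
            n.GetHybridization() == Chem.HybridizationType.SP3
            and not n.GetIsAromatic()
            for n in nbrs
        ):
            c.n_alkyl_ether += 1

    # --- C=C, CH2, rings --------------------------------------------------
    for b in mol.GetBonds():
        if (
            b.GetBondType() == Chem.BondType.DOUBLE
            and b.GetBeginAtom().GetSymbol() == "C"
            and b.GetEndAtom().GetSymbol() == "C"
        ):
            c.n_CdoubleC += 1
    for a in unit.atoms:
        if a.element == "C" and a.h_count == 2:
            rd = mol.GetAtomWithIdx(a.index)
            if all(
                b.GetBondType() == Chem.BondType.SINGLE for b in rd.GetBonds()
            ):
                c.n_CH2 += 1
    c.n_aromatic_ring = sum(1 for _, _, arom in unit.real_rings if arom)
    c.n_isolated_saturated_ring = len(isolated_saturated_rings(unit))
    return c


#: N_K group-contribution coefficients (census field -> coefficient).
N_K_COEFFICIENTS: dict[str, float] = {
    "n_amide": 5.0,
    "n_cyanide": 7.0,
    "n_carbonate": 15.0,
    "n_Cl": 5.0,
    "n_Br": 13.0,
    "n_hydroxyl": 4.0,
    "n_ether": -3.0,
    "n_CdoubleC": -5.0,
    "n_sulfone": 3.0,
    "n_acrylic_ester": -3.0,
    "n_isolated_saturated_ring": -5.0,
}


def compute_n_K(census: FunctionalGroupCensus) -> float:
    """Group-contribution term N_K = 5·N_amide + 7·N_cyanide + 15·N_carbonate
    + 5·N_Cl + 13·N_Br + 4·N_OH − 3·N_ether − 5·N_C=C + 3·N_sulfone
    − 3·N_acrylic-ester − 5·N_isolated-saturated-ring."""
    return sum(
        coeff * getattr(census, name) for name, coeff in N_K_COEFFICIENTS.items()
    )


def compute_nmv(census: FunctionalGroupCensus) -> float:
    """Molar-volume proxy Nmv = 2·N_ester + 3·N_ether (all esters count)."""
    return 2.0 * census.n_ester_total + 3.0 * census.n_ether


def compute_n_rot(unit: RepeatUnit, backbone: Backbone | None = None) -> float:
    """Rotational-degrees-of-freedom parameter.

    Backbone term: acyclic single bonds with both atoms on the backbone,
    including the virtual closure bond.  Side-group term: acyclic single
    bonds off the backbone whose two atoms each have >= 2 heavy neighbours
    (terminal bonds to -CH3/-Cl/-OH rotate nothing of the heavy-atom
    skeleton and contribute 0).  Ring bonds contribute 0.
    """
    bb = backbone if backbone is not None else get_backbone(unit)
    ring_pairs = unit.ring_bond_pairs()
    n_rot = 1.0  # the closure bond: always single, never in a genuine ring
    for b in unit.bonds:
        if b.order is not BondOrder.SINGLE:
            continue
        pair = (b.i, b.j) if b.i <= b.j else (b.j, b.i)
        if pair in ring_pairs:
            continue
        if b.i in bb.atoms and b.j in bb.atoms:
            n_rot += 1.0
        elif unit.atoms[b.i].delta >= 2 and unit.atoms[b.j].delta >= 2:
            n_rot += 1.0
    return n_rot


def compute_connectivity_indices(
    unit: RepeatUnit,
) -> tuple[float, float, float, float]:
    """Molecular connectivity indices (chi0, chi0v, chi1, chi1v).

    chi0  = sum over heavy atoms of delta^(-1/2)
    chi0v = sum over heavy atoms of delta_v^(-1/2)
    chi1  = sum over edges (closure bond once) of (delta_i*delta_j)^(-1/2)
    chi1v = the same with valence deltas.
    """
    for a in unit.atoms:
        if a.delta <= 0 or a.delta_v <= 0:
            raise ComputationError(
                f"atom {a.index} ({a.element}) has non-positive delta "
                f"({a.delta}) or delta_v ({a.delta_v})"
            )
    chi0 = sum(a.delta ** -0.5 for a in unit.atoms)
    chi0v = sum(a.delta_v ** -0.5 for a in unit.atoms)
    chi1 = 0.0
    chi1v = 0.0
    for i, j, _key in unit.graph.edges(keys=True):
        ai, aj = unit.atoms[i], unit.atoms[j]
        chi1 += (ai.delta * aj.delta) ** -0.5
        chi1v += (ai.delta_v * aj.delta_v) ** -0.5
    return chi0, chi0v, chi1, chi1v


BackboneIndexFn = Callable[[RepeatUnit, Sequence[int]], float]


def bb_index1_default(unit: RepeatUnit, backbone_atoms: Sequence[int]) -> float:
    """Backbone steric-hindrance index: mean of delta/delta_v over backbone
    atoms.  Low values flag flexible backbones rich in lone-pair atoms."""
    return sum(
        unit.atoms[i].delta / unit.atoms[i].delta_v for i in backbone_atoms
    ) / len(backbone_atoms)


def bb_index2_default(unit: RepeatUnit, backbone_atoms: Sequence[int]) -> float:
    """Second backbone index: mean of delta^2/delta_v, which separates
    backbone atoms with equal delta/delta_v ratio but different heavy-atom
    coordination (delta)."""
    return sum(
        unit.atoms[i].delta ** 2 / unit.atoms[i].delta_v for i in backbone_atoms
    ) / len(backbone_atoms)


def compute_backbone_indices(
    unit: RepeatUnit,
    backbone: Backbone | None = None,
    index1: BackboneIndexFn = bb_index1_default,
    index2: BackboneIndexFn = bb_index2_default,
) -> tuple[float, float]:
    """Evaluate the two backbone indices; the definitions are pluggable
    strategies so alternative formulations can be swapped in."""
    bb = backbone if backbone is not None else get_backbone(unit)
    atoms = sorted(bb.atoms)
    if not atoms:
        raise ComputationError("empty backbone")
    return index1(unit, atoms), index2(unit, atoms)


def compute_descriptors(
    unit: RepeatUnit,
    index1: BackboneIndexFn = bb_index1_default,
    index2: BackboneIndexFn = bb_index2_default,
) -> DescriptorVector:
    """Assemble the full 22-feature descriptor vector for one repeat unit."""
    backbone = get_backbone(unit)

    def _step(name: str, fn):
        try:
            return fn()
        except ComputationError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise ComputationError(f"computing {name}: {exc}") from exc

    n, n_c, n_h, n_o, m = _step("atom counts", lambda: count_atoms(unit))
    census = _step("functional-group census", lambda: census_functional_groups(unit))
    chi0, chi0v, chi1, chi1v = _step(
        "connectivity indices", lambda: compute_connectivity_indices(unit)
    )
    bb1, bb2 = _step(
        "backbone indices",
        lambda: compute_backbone_indices(unit, backbone, index1, index2),
    )
    return DescriptorVector(
        id=unit.id,
        smiles=unit.smiles,
        N=n,
        N_C=n_c,
        N_H=n_h,
        N_ester_n=census.n_ester_n,
        N_ester_c=census.n_ester_c,
        N_aromaticring=census.n_aromatic_ring,
        N_CH2=census.n_CH2,
        N_ether=census.n_ether,
        N_backbone_O=census.n_backbone_O,
        N_O=n_o,
        M=m,
        N_alkyl_ether=census.n_alkyl_ether,
        N_rot=_step("N_rot", lambda: compute_n_rot(unit, backbone)),
        N_K=compute_n_K(census),
        N_SP=backbone.n_sp,
        Nmv=compute_nmv(census),
        chi0=chi0,
        chi0v=chi0v,
        chi1=chi1,
        chi1v=chi1v,
        BB_index1=bb1,
        BB_index2=bb2,
        census=census,
    )
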