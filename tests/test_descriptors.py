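"""Descriptor engine: counts, census, formulas, connectivity indices."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from polytg.synthetic import grammar_smiles

from polytg.descriptors import (
    FEATURE_NAMES,
    FunctionalGroupCensus,
    N_K_COEFFICIENTS,
    census_functional_groups,
    compute_backbone_indices,
    compute_connectivity_indices,
    compute_descriptors,
    compute_n_K,
    compute_n_rot,
    compute_nmv,
    count_atoms,
)
from polytg.repeat_unit import parse_repeat_unit

from oracles import brute_force_chi


def _unit(smiles):
    return parse_repeat_unit(smiles, smiles)


class TestCounts:
    @pytest.mark.parametrize(
        "smiles, n, n_c, n_h, n_o, m",
        [
            ("[*]CC[*]", 2, 2, 4, 0, 28.054),
            ("[*]CCO[*]", 3, 2, 4, 1, 44.053),
            ("[*]C[*]", 1, 1, 2, 0, 14.027),
        ],
    )
    def test_count_atoms(self, smiles, n, n_c, n_h, n_o, m):
        got = count_atoms(_unit(smiles))
        assert got[:4] == (n, n_c, n_h, n_o)
        assert got[4] == pytest.approx(m, abs=1e-3)


class TestCensus:
    def test_polyethylene_census_empty(self):
        c = census_functional_groups(_unit("[*]CC[*]"))
        for f in dataclasses.fields(c):
            if f.name == "n_CH2":
                assert getattr(c, f.name) == 2
            else:
                assert getattr(c, f.name) == 0, f.name

    def test_pmma_side_ester_is_acrylic_not_backbone(self):
        c = census_functional_groups(_unit("[*]CC([*])(C)C(=O)OC"))
        assert c.n_ester_total == 1
        assert c.n_ester_n == 0 and c.n_ester_c == 0
        assert c.n_acrylic_ester == 1
        assert c.n_CH2 == 1
        assert c.n_O == 2
        assert c.n_ether == 0  # the ester -O- is not an ether

    def test_pet_backbone_esters_one_sided_conjugation(self):
        # both esters conjugate to the ring on exactly one side; the second
        # ester spans the unit boundary and is completed by the closure bond
        c = census_functional_groups(_unit("[*]OCCOC(=O)c1ccc(cc1)C(=O)[*]"))
        assert c.n_ester_total == 2
        assert c.n_ester_c == 2 and c.n_ester_n == 0 and c.n_ester_2c == 0
        assert c.n_backbone_O == 2
        assert c.n_ether == 0

    def test_backbone_nonconjugated_ester(self):
        c = census_functional_groups(_unit("[*]OC(=O)CC[*]"))
        assert c.n_ester_n == 1 and c.n_ester_c == 0

    @pytest.mark.parametrize(
        "smiles, field, count",
        [
            ("[*]CC(Cl)[*]", "n_Cl", 1),
            ("[*]CC(Br)[*]", "n_Br", 1),
            ("[*]CC([*])O", "n_hydroxyl", 1),
            ("[*]CC([*])C#N", "n_cyanide", 1),
            ("[*]CC([*])C(=O)N", "n_amide", 1),
            ("[*]CCOC(=O)OCC[*]", "n_carbonate", 1),
            ("[*]CC=CC[*]", "n_CdoubleC", 1),
            ("[*]CCS(=O)(=O)CC[*]", "n_sulfone", 1),
            ("[*]CC([*])C1CCCCC1", "n_isolated_saturated_ring", 1),
            ("[*]CC([*])c1ccccc1", "n_aromatic_ring", 1),
            ("[*]CCOCC[*]", "n_alkyl_ether", 1),
            ("[*]CC([*])Oc1ccccc1", "n_ether", 1),
        ],
    )
    def test_single_group_counts(self, smiles, field, count):
        assert getattr(census_functional_groups(_unit(smiles)), field) == count

    def test_aryl_ether_not_alkyl(self):
        c = census_functional_groups(_unit("[*]CC([*])Oc1ccccc1"))
        assert c.n_ether == 1 and c.n_alkyl_ether == 0

    def test_carbonate_not_double_counted_as_esters(self):
        c = census_functional_groups(_unit("[*]CCOC(=O)OCC[*]"))
        assert c.n_carbonate == 1
        assert c.n_ester_total == 0


class TestFormulas:
    @pytest.mark.parametrize("field, coeff", sorted(N_K_COEFFICIENTS.items()))
    def test_n_K_responds_with_printed_coefficient(self, field, coeff):
        base = FunctionalGroupCensus()
        bumped = dataclasses.replace(base, **{field: 1})
        assert compute_n_K(bumped) - compute_n_K(base) == coeff

    def test_nmv_linearity(self):
        base = FunctionalGroupCensus()
        plus_ester = dataclasses.replace(base, n_ester_total=1)
        plus_ether = dataclasses.replace(base, n_ether=1)
        assert compute_nmv(plus_ester) - compute_nmv(base) == 2
        assert compute_nmv(plus_ether) - compute_nmv(base) == 3

    @pytest.mark.parametrize(
        "smiles, n_k",
        [
            ("[*]CC[*]", 0),  # empty census
            ("[*]CC(Cl)[*]", 5),  # PVC
            ("[*]CC([*])C(=O)OC", -3),  # acrylic ester
            ("[*]CCO[*]", -3),  # one ether
        ],
    )
    def test_n_K_end_to_end(self, smiles, n_k):
        assert compute_n_K(census_functional_groups(_unit(smiles))) == n_k


class TestNRot:
    @pytest.mark.parametrize(
        "smiles, n_rot",
        [
            ("[*]CC[*]", 2),  # two backbone single bonds per unit
            ("[*]CC([*])c1ccccc1", 3),  # + the CH-phenyl bond
            ("[*]c1ccc(cc1)[*]", 1),  # all-ring backbone: closure only
            ("[*]CC([*])(C)C(=O)OC", 4),
        ],
    )
    def test_examples(self, smiles, n_rot):
        unit = _unit(smiles)
        assert compute_n_rot(unit) == n_rot

    def test_terminal_bonds_contribute_zero(self):
        # propylene vs ethylene: the extra C-CH3 bond is terminal
        assert compute_n_rot(_unit("[*]CC(C)[*]")) == compute_n_rot(
            _unit("[*]CC[*]")
        )


class TestChi:
    def test_polyethylene_hand_values(self):
        chi0, chi0v, chi1, chi1v = compute_connectivity_indices(_unit("[*]CC[*]"))
        assert chi0 == pytest.approx(2 / math.sqrt(2), abs=1e-12)
        assert chi1 == pytest.approx(1.0, abs=1e-12)
        assert chi0v == chi0 and chi1v == chi1

    def test_polymethylene_single_closure_bond(self):
        chi0, _, chi1, _ = compute_connectivity_indices(_unit("[*]C[*]"))
        assert chi0 == pytest.approx(1 / math.sqrt(2), abs=1e-12)
        assert chi1 == pytest.approx(0.5, abs=1e-12)

    def test_polystyrene_hand_values(self):
        chi0, _, chi1, _ = compute_connectivity_indices(
            _unit("[*]CC([*])c1ccccc1")
        )
        assert chi0 == pytest.approx(6 / math.sqrt(2) + 2 / math.sqrt(3), abs=1e-9)
        assert chi1 == pytest.approx(4 / math.sqrt(6) + 1 / 3 + 2, abs=1e-9)

    def test_chi_matches_brute_force_oracle(self, grammar_pool):
        for smi in grammar_pool:
            got = compute_connectivity_indices(_unit(smi))
            expected = brute_force_chi(smi)
            np.testing.assert_allclose(got, expected, atol=1e-9, err_msg=smi)

    def test_saturated_acyclic_hydrocarbons_valence_equals_simple(self):
        for smi in ["[*]CC[*]", "[*]CC(C)[*]", "[*]CC(C)(C)[*]", "[*]CCCC[*]"]:
            chi0, chi0v, chi1, chi1v = compute_connectivity_indices(_unit(smi))
            assert chi0 == pytest.approx(chi0v, abs=1e-12)
            assert chi1 == pytest.approx(chi1v, abs=1e-12)

    def test_chi0_at_least_chi1(self, grammar_pool):
        for smi in grammar_pool:
            chi0, _, chi1, _ = compute_connectivity_indices(_unit(smi))
            assert chi0 >= chi1 > 0


class TestBackboneIndices:
    def test_polyethylene(self):
        bb1, bb2 = compute_backbone_indices(_unit("[*]CC[*]"))
        assert bb1 == pytest.approx(1.0) and bb2 == pytest.approx(2.0)

    def test_peo_default_definition(self):
        bb1, _ = compute_backbone_indices(_unit("[*]CCO[*]"))
        assert bb1 == pytest.approx((1 + 1 + 2 / 6) / 3, abs=1e-12)

    def test_identical_atoms_factorisation(self):
        # backbone of identical atoms: BB2 = delta * BB1 exactly
        unit = _unit("[*]CCCC[*]")
        bb1, bb2 = compute_backbone_indices(unit)
        assert bb2 == pytest.approx(2 * bb1, abs=1e-12)

    def test_pluggable_strategy(self):
        unit = _unit("[*]CCO[*]")
        bb1, bb2 = compute_backbone_indices(
            unit,
            index1=lambda u, atoms: 42.0,
            index2=lambda u, atoms: -1.0,
        )
        assert (bb1, bb2) == (42.0, -1.0)


class TestGrammarProperties:
    @given(smi=st.sampled_from(grammar_smiles()))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_descriptor_identities_hold_for_any_grammar_unit(self, smi):
        vec = compute_descriptors(_unit(smi))
        c = vec.census
        assert vec.Nmv == 2 * c.n_ester_total + 3 * c.n_ether
        assert vec.chi0 >= vec.chi1 > 0
        assert vec.N == vec.N_C + sum(
            1 for a in _unit(smi).atoms if a.element != "C"
        )
        assert vec.N_SP >= 1 and vec.M > 0


class TestAssembly:
    def test_feature_vector_complete_and_deterministic(self, grammar_pool):
        for smi in grammar_pool[:8]:
            d1 = compute_descriptors(_unit(smi)).to_dict()
            d2 = compute_descriptors(_unit(smi)).to_dict()
            assert d1 == d2
            assert set(FEATURE_NAMES) <= set(d1)

    def test_invariant_under_atom_reindexing(self, grammar_pool):
        # randomised SMILES of the same molecule -> identical descriptors
        rng = np.random.default_rng(11)
        for smi in grammar_pool:
            mol = Chem.MolFromSmiles(smi)
            perm = rng.permutation(mol.GetNumAtoms()).tolist()
            alt = Chem.MolToSmiles(
                Chem.RenumberAtoms(mol, perm), canonical=False
            )
            ref = compute_descriptors(_unit(smi)).to_dict()
            got = compute_descriptors(_unit(alt)).to_dict()
            for k in FEATURE_NAMES:
                assert got[k] == pytest.approx(ref[k], abs=1e-9), (smi, alt, k)
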