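"""ETA atomic quantities, derived graphs and composite descriptor invariants.

Hand-derived expected values: alpha(C) = (6-4)/4 / 1 = 0.5;
alpha(Cl) = (17-7)/7 / 2 = 5/7; epsilon = -alpha + 0.3 Zv gives
H 0.3, C 0.7, N 1.1, O 22/15; sigma contributions 0.5 (similar) /
0.75 (dissimilar) with similarity |d(epsilon)| <= 0.3.
"""

import math

import pytest
from rdkit import Chem

from etaqsar import (MoleculeError, atom_beta, atomic_alpha, atomic_epsilon,
                     epsilon_variants, eta_composite, pi_contribution,
                     reference_alkane, saturated_skeleton, sigma_contribution)
from etaqsar.chemio import Atom, canonical_smiles, from_rdkit


def mol(smiles, mid="m"):
    return from_rdkit(Chem.MolFromSmiles(smiles), mid)


def atom_of(m, element):
    return next(a for a in m.atoms if a.element == element)


class TestAtomicValues:
    @pytest.mark.parametrize(
        "smiles,element,alpha,eps",
        [
            ("C", "H", 0.0, 0.3),
            ("C", "C", 0.5, 0.7),
            ("O", "O", 1 / 3, -1 / 3 + 1.8),
            ("N", "N", 0.4, 1.1),
            ("CCl", "Cl", 5 / 7, -5 / 7 + 2.1),
        ],
    )
    def test_alpha_epsilon(self, smiles, element, alpha, eps):
        a = atom_of(mol(smiles), element)
        assert atomic_alpha(a) == pytest.approx(alpha)
        assert atomic_epsilon(a) == pytest.approx(eps)

    def test_period1_heavy_atom_rejected(self):
        he = Atom(index=0, element="He", Z=2, Zv=2, PN=1, is_hydrogen=False)
        with pytest.raises(MoleculeError, match="alpha undefined"):
            atomic_alpha(he)

    @pytest.mark.parametrize(
        "sm_a,el_a,sm_b,el_b,sigma,pi",
        [
            ("C", "C", "C", "C", 0.5, 1.0),    # similar electronegativity
            ("C", "C", "O", "O", 0.75, 1.5),   # dissimilar
            ("N", "N", "O", "O", 0.75, 1.5),   # |1.1 - 1.4667| > 0.3
            ("N", "N", "C", "C", 0.75, 1.5),   # |1.1 - 0.7| > 0.3
        ],
    )
    def test_bond_contributions(self, sm_a, el_a, sm_b, el_b, sigma, pi):
        a, b = atom_of(mol(sm_a), el_a), atom_of(mol(sm_b), el_b)
        assert sigma_contribution(a, b) == sigma
        assert pi_contribution(a, b) == pi


class TestAtomBeta:
    def test_propane_central_carbon(self):
        m = mol("CCC")
        central = next(a for a in m.heavy_atoms() if len(m.heavy_neighbors(a.index)) == 2)
        v = atom_beta(central, m)
        assert v.beta_s == pytest.approx(1.0)  # two C-C sigma bonds
        assert v.beta_ns == 0.0

    def test_acetone_carbonyl_oxygen(self):
        m = mol("CC(=O)C")
        v = atom_beta(atom_of(m, "O"), m)
        assert v.beta_s == pytest.approx(0.75)   # sigma part of C=O
        assert v.beta_ns == pytest.approx(1.5)   # one dissimilar pi bond, no lone-pair delta

    def test_benzene_carbon_aromatic_contribution(self):
        m = mol("c1ccccc1")
        v = atom_beta(m.heavy_atoms()[0], m)
        assert v.beta_s == pytest.approx(1.0)
        assert v.beta_ns == pytest.approx(4.0)  # 2.0 per aromatic ring bond

    def test_phenol_oxygen_gets_lone_pair_increment(self):
        m = mol("Oc1ccccc1")
        v = atom_beta(atom_of(m, "O"), m)
        assert v.beta_ns == pytest.approx(0.5)  # conjugated lone pair only

    def test_hydrogen_suppressed(self):
        m = mol("C")  # methane: no heavy neighbors at all
        v = atom_beta(atom_of(m, "C"), m)
        assert v.beta_s == 0.0 and v.beta_ns == 0.0


class TestDerivedGraphs:
    def test_reference_alkane_of_resorcinol(self):
        ref = reference_alkane(mol("Oc1cccc(O)c1"))
        assert all(a.element in ("C", "H") for a in ref.atoms)
        assert all(b.order == 1 for b in ref.bonds)
        assert ref.n_heavy() == 8
        assert ref.n_atoms() == 24  # 8 C + 16 H

    def test_alkane_is_fixed_point(self):
        m = mol("CCC(C)CC")
        assert canonical_smiles(reference_alkane(m)) == canonical_smiles(m)
        assert canonical_smiles(saturated_skeleton(m)) == canonical_smiles(m)

    def test_benzene_reference_is_cyclohexane(self):
        assert canonical_smiles(reference_alkane(mol("c1ccccc1"))) == "C1CCCCC1"

    def test_limonene_skeleton_is_p_menthane(self):
        sat = saturated_skeleton(mol("CC1=CCC(CC1)C(=C)C"))
        assert canonical_smiles(sat) == canonical_smiles(mol("CC1CCC(C(C)C)CC1"))
        assert sat.n_atoms() == 30  # C10H20

    def test_ethanol_skeleton_unchanged(self):
        m = mol("CCO")
        assert canonical_smiles(saturated_skeleton(m)) == canonical_smiles(m)

    def test_camphene_reference_equals_skeleton(self, named_compounds):
        camphene = named_compounds["1"]
        assert canonical_smiles(reference_alkane(camphene)) == canonical_smiles(
            saturated_skeleton(camphene)
        )

    def test_carbonyl_kept_in_skeleton(self):
        sat = saturated_skeleton(mol("CC(=O)C"))
        assert any(b.order == 2 for b in sat.heavy_bonds())  # C=O survives


class TestEpsilonVariants:
    def test_alkane_variants_coincide(self):
        e1, e2, e3, e4, e5 = epsilon_variants(mol("CCC(C)CC"))
        assert e3 == pytest.approx(e2)
        assert e4 == pytest.approx(e2)
        assert e5 == pytest.approx(e2)

    def test_camphene_eps3_equals_eps4(self, named_compounds):
        _, _, e3, e4, _ = epsilon_variants(named_compounds["1"])
        assert e3 == pytest.approx(e4)

    def test_resorcinol_eps5_above_eps2(self, named_compounds):
        _, e2, _, _, e5 = epsilon_variants(named_compounds["49"])
        assert e5 > e2  # dropping low-epsilon donor hydrogens raises the mean


HYDROCARBONS = ["1", "50", "54", "59"]
HETERO = ["3", "4", "8", "10", "14", "15", "23", "26", "35", "44", "49"]


class TestComposites:
    def test_depsilon_c_zero_iff_no_heteroatoms(self, named_compounds):
        for num in HYDROCARBONS:
            assert eta_composite(named_compounds[num])["ETA_dEpsilon_C"] == pytest.approx(0.0)
        for num in HETERO:
            assert eta_composite(named_compounds[num])["ETA_dEpsilon_C"] < 0

    def test_depsilon_d_donor_content(self, named_compounds):
        for num in HYDROCARBONS:
            assert eta_composite(named_compounds[num])["ETA_dEpsilon_D"] == pytest.approx(0.0)
        assert eta_composite(named_compounds["49"])["ETA_dEpsilon_D"] > 0

    def test_dalpha_b_zero_for_hydrocarbons(self, named_compounds):
        for num in HYDROCARBONS:
            assert eta_composite(named_compounds[num])["ETA_dAlpha_B"] == pytest.approx(0.0)
        assert eta_composite(named_compounds["49"])["ETA_dAlpha_B"] > 0

    def test_functionality_index_ordering(self, named_compounds):
        benzoate = eta_composite(named_compounds["10"])["ETA_EtaP_F"]
        cineole = eta_composite(named_compounds["4"])["ETA_EtaP_F"]
        assert benzoate > cineole
        for num in named_compounds:
            assert eta_composite(named_compounds[num])["ETA_EtaP_F"] >= 0

    def test_betap_s_relation(self, named_compounds):
        d = eta_composite(named_compounds["50"])
        assert d["ETA_BetaP_s"] == pytest.approx(d["ETA_Beta_s"] / d["Nv"])
        assert d["ETA_BetaP_s"] < eta_composite(named_compounds["44"])["ETA_BetaP_s"]

    def test_single_heavy_atom_eta_zero(self):
        d = eta_composite(mol("C"))
        assert d["ETA_Eta"] == 0.0 and d["ETA_Eta_F"] == 0.0

    @pytest.mark.parametrize("perm_seed", [0, 1, 2])
    def test_atom_order_invariance(self, named_compounds, perm_seed):
        import numpy as np
        from rdkit import Chem as _C

        base = named_compounds["26"]
        rd = _C.MolFromSmiles("COc1cc(CC=C)ccc1OCC(=O)O")
        order = list(np.random.default_rng(perm_seed).permutation(rd.GetNumAtoms()))
        permuted = from_rdkit(_C.RenumberAtoms(rd, [int(i) for i in order]), "perm")
        ref, new = eta_composite(base), eta_composite(permuted)
        for k in ref:
            assert new[k] == pytest.approx(ref[k], abs=1e-10), k
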