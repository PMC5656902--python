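import numpy as np
import pytest

from cpaselect import (Molecule3D, find_catalyst_anchors, read_ensemble_csv,
                       read_structure, write_structure)
from cpaselect.errors import AnchorError, EnsembleError, StructureParseError

WATER_XYZ = """3
water
O   0.0000   0.0000   0.1173
H   0.0000   0.7572  -0.4692
H   0.0000  -0.7572  -0.4692
"""


def _embedded_smiles(smiles):
    from rdkit import Chem
    from rdkit.Chem import AllChem

    from cpaselect.chem_io import _rdkit_to_molecule

    m = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = 7
    AllChem.EmbedMolecule(m, params)
    return _rdkit_to_molecule(m)


class TestReadStructure:
    def test_xyz_water_infers_two_bonds(self, tmp_path):
        p = tmp_path / "water.xyz"
        p.write_text(WATER_XYZ)
        mol = read_structure(p)
        assert mol.n_atoms == 3
        assert len(mol.bonds) == 2
        assert mol.symbols == ["O", "H", "H"]

    def test_xyz_bad_element_token(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("1\n\nXq 0.0 0.0 0.0\n")
        with pytest.raises(StructureParseError, match="Xq"):
            read_structure(p)

    def test_xyz_nonnumeric_coordinate_names_line(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("1\n\nC 0.0 zero 0.0\n")
        with pytest.raises(StructureParseError, match="line 3"):
            read_structure(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(StructureParseError, match="no such file"):
            read_structure(tmp_path / "absent.sdf")

    def test_empty_molecule_rejected(self, tmp_path):
        p = tmp_path / "empty.xyz"
        p.write_text("0\nempty\n")
        with pytest.raises(StructureParseError):
            read_structure(p)


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["sdf", "xyz"])
    def test_diphenyl_phosphate_round_trip(self, tmp_path, fmt):
        mol = _embedded_smiles("O=P(O)(Oc1ccccc1)Oc1ccccc1")
        p = tmp_path / f"dpp.{fmt}"
        write_structure(mol, p)
        back = read_structure(p)
        assert back.symbols == mol.symbols
        np.testing.assert_allclose(back.coords, mol.coords, atol=1e-4)
        if fmt == "sdf":  # XYZ re-infers bonds; SDF must carry them verbatim
            assert {(i, j) for i, j, _ in back.bonds} == \
                   {(i, j) for i, j, _ in mol.bonds}


class TestCatalystAnchors:
    def test_parent_scaffold_has_hydrogen_roots(self, parent_catalyst):
        _, anchors = parent_catalyst
        assert anchors.substituent_root_indices == ("H", "H")
        assert anchors.acid_form == "acid"

    def test_phenyl_roots_are_aromatic_carbons(self, phenyl_catalyst):
        mol, anchors = phenyl_catalyst
        for root in anchors.substituent_root_indices:
            assert mol.symbols[root] == "C"
            # the ipso carbon of a phenyl ring has three carbon neighbours
            assert sum(mol.symbols[j] == "C" for j in mol.adjacency()[root]) == 3

    def test_diphenyl_phosphate_is_rejected(self):
        mol = _embedded_smiles("O=P(O)(Oc1ccccc1)Oc1ccccc1")
        with pytest.raises(AnchorError):
            find_catalyst_anchors(mol)

    def test_no_phosphorus_rejected(self, tmp_path):
        p = tmp_path / "water.xyz"
        p.write_text(WATER_XYZ)
        with pytest.raises(AnchorError, match="not a monophosphoric acid"):
            find_catalyst_anchors(read_structure(p))

    def test_permutation_invariance(self, phenyl_catalyst, rng):
        mol, anchors = phenyl_catalyst
        perm = rng.permutation(mol.n_atoms)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(mol.n_atoms)
        permuted = Molecule3D(
            [mol.symbols[i] for i in perm],
            mol.coords[perm],
            [(int(inv[i]), int(inv[j]), o) for i, j, o in mol.bonds],
        )
        a2 = find_catalyst_anchors(permuted)
        assert perm[a2.p_index] == anchors.p_index
        assert {int(perm[i]) for i in a2.acid_o_indices} == set(anchors.acid_o_indices)
        assert {int(perm[i]) for i in a2.c3_indices} == set(anchors.c3_indices)
        mapped_roots = {r if r == "H" else int(perm[r])
                        for r in a2.substituent_root_indices}
        assert mapped_roots == set(anchors.substituent_root_indices)


class TestEnsembleCsv:
    def test_relative_energies_kcal(self, tmp_path):
        p = tmp_path / "ens.csv"
        p.write_text("label,pathway,config,energy\n"
                     "TS1,II_Z,S,0.0\nTS2,I_Z,R,0.7\n")
        ens = read_ensemble_csv(p)
        assert sorted(r.rel_energy for r in ens.records) == [0.0, 0.7]

    def test_single_hartree_record_is_zero(self, tmp_path):
        p = tmp_path / "one.csv"
        p.write_text("label,pathway,config,energy\nTS1,I_E,R,-1000.0\n")
        ens = read_ensemble_csv(p, energy_unit="hartree")
        assert ens.records[0].rel_energy == 0.0

    def test_hartree_gap_conversion(self, tmp_path):
        # 0.001115 hartree * 627.5094740631 = 0.699673 kcal/mol
        p = tmp_path / "h.csv"
        p.write_text("label,pathway,config,energy\n"
                     "A,II_Z,S,-1000.000000\nB,I_Z,R,-999.998885\n")
        ens = read_ensemble_csv(p, energy_unit="hartree")
        gap = max(r.rel_energy for r in ens.records)
        assert gap == pytest.approx(0.001115 * 627.5094740631, abs=1e-9)

    def test_unknown_pathway_token(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("label,pathway,config,energy\nA,III_E,R,0.0\n")
        with pytest.raises(ValueError, match="III_E"):
            read_ensemble_csv(p)

    def test_non_numeric_energy(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("label,pathway,config,energy\nA,I_E,R,low\n")
        with pytest.raises(EnsembleError, match="non-numeric"):
            read_ensemble_csv(p)

    def test_unknown_config(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("label,pathway,config,energy\nA,I_E,Q,0.0\n")
        with pytest.raises(EnsembleError, match="configuration"):
            read_ensemble_csv(p)
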