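import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cpaselect import (Molecule3D, PathwayLabel, ReactionSpec,
                       classify_ts_geometry, infer_pathway)
from cpaselect.catalyst_catalog import load_catalog
from cpaselect.chem_io import AtomMap
from cpaselect.errors import GeometryError
from cpaselect.fixtures import (make_ts_fixture,
                                reflect_substrate_through_front_plane)


class TestPathwayLabel:
    def test_parse_and_str_round_trip(self):
        for token in ["I_E", "I_Z", "II_E", "II_Z"]:
            assert str(PathwayLabel.parse(token)) == token

    def test_unknown_token(self):
        with pytest.raises(ValueError, match="II_X"):
            PathwayLabel.parse("II_X")

    def test_ordering_is_orientation_then_config(self):
        order = sorted(map(PathwayLabel.parse, ["II_Z", "I_Z", "II_E", "I_E"]))
        assert [str(p) for p in order] == ["I_E", "I_Z", "II_E", "II_Z"]


class TestReactionSpec:
    def test_cyclic_imine_must_be_z(self):
        with pytest.raises(ValueError, match="locked Z"):
            ReactionSpec(imine_cyclic=True, n_substituent_size="large",
                         accessible_configs={"E"})

    def test_displaced_bulk_required(self):
        with pytest.raises(ValueError, match="displaced_bulk"):
            ReactionSpec(imine_cyclic=False, n_substituent_size="small",
                         nucleophile_kind="displaced")

    def test_empty_configs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ReactionSpec(imine_cyclic=False, n_substituent_size="large",
                         accessible_configs=set())


class TestInferPathway:
    @pytest.mark.parametrize("spec,expected", [
        (ReactionSpec(True, "large", {"Z"}, "symmetrical"), "I_Z"),
        (ReactionSpec(False, "large", {"E"}, "symmetrical"), "I_E"),
        (ReactionSpec(False, "small", {"E"}, "displaced", "small"), "II_E"),
    ])
    def test_archetypes(self, spec, expected):
        assert str(infer_pathway(spec)) == expected

    def test_declared_pathway_overrides(self):
        spec = ReactionSpec(False, "large", {"E"}, "symmetrical",
                            declared_pathway=PathwayLabel.parse("II_E"))
        assert str(infer_pathway(spec)) == "II_E"

    def test_reproduces_printed_mechanism_columns(self):
        """Tables of acyclic screens: every unambiguous row's transcribed
        features infer the printed pathway."""
        _, rows = load_catalog()
        checked = 0
        for row in rows:
            if row.source_table not in (1, 5) or row.ambiguous_mechanism:
                continue
            assert str(infer_pathway(row.reaction)) == row.mechanism_label, \
                row.reaction_name
            checked += 1
        assert checked == 14  # 9 unambiguous rows in one screen, 5 in the other


class TestClassifyTsGeometry:
    @pytest.mark.parametrize("orientation", ["I", "II"])
    @pytest.mark.parametrize("config", ["E", "Z"])
    def test_fixture_round_trip(self, orientation, config):
        mol, amap = make_ts_fixture(orientation, config)
        label = classify_ts_geometry(mol, amap)
        assert (label.orientation, label.config) == (orientation, config)

    @pytest.mark.parametrize("orientation", ["I", "II"])
    @pytest.mark.parametrize("config", ["E", "Z"])
    def test_substrate_mirror_flips_orientation_only(self, orientation, config):
        mol, amap = make_ts_fixture(orientation, config)
        mirrored = reflect_substrate_through_front_plane(mol, amap)
        label = classify_ts_geometry(mirrored, amap)
        assert label.orientation != orientation
        assert label.config == config

    def test_exact_90_degree_dihedral_is_E(self):
        mol, amap = make_ts_fixture("I", "E", dihedral=90.0)
        assert classify_ts_geometry(mol, amap).config == "E"

    def test_rigid_motion_invariance(self, rng):
        mol, amap = make_ts_fixture("II", "Z")
        R = Rotation.random(random_state=3).as_matrix()
        moved = Molecule3D(list(mol.symbols),
                           mol.coords @ R.T + rng.normal(size=3),
                           list(mol.bonds))
        assert str(classify_ts_geometry(moved, amap)) == "II_Z"

    def test_permutation_invariance(self, rng):
        mol, amap = make_ts_fixture("I", "Z")
        perm = rng.permutation(mol.n_atoms)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(mol.n_atoms)
        permuted = Molecule3D([mol.symbols[i] for i in perm], mol.coords[perm],
                              [(int(inv[i]), int(inv[j]), o)
                               for i, j, o in mol.bonds])
        a = amap.anchors
        remapped = AtomMap(
            imine_c=int(inv[amap.imine_c]), imine_n=int(inv[amap.imine_n]),
            n_sub_anchor=int(inv[amap.n_sub_anchor]),
            c_sub_anchor=int(inv[amap.c_sub_anchor]),
            anchors=type(a)(
                p_index=int(inv[a.p_index]),
                acid_o_indices=tuple(int(inv[i]) for i in a.acid_o_indices),
                ether_o_indices=tuple(int(inv[i]) for i in a.ether_o_indices),
                c3_indices=tuple(int(inv[i]) for i in a.c3_indices),
                substituent_root_indices=a.substituent_root_indices,
                acid_form=a.acid_form))
        assert str(classify_ts_geometry(permuted, remapped)) == "I_Z"

    def test_collinear_anchors_rejected(self):
        mol, amap = make_ts_fixture("I", "E")
        coords = mol.coords.copy()
        # put the N-substituent anchor on the C=N axis
        axis = coords[amap.imine_n] - coords[amap.imine_c]
        coords[amap.n_sub_anchor] = coords[amap.imine_n] + axis
        degenerate = Molecule3D(list(mol.symbols), coords, list(mol.bonds))
        with pytest.raises(GeometryError, match="collinear"):
            classify_ts_geometry(degenerate, amap)
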