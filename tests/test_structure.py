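"""Structure parsing, typing and annotated output."""

import numpy as np
import pytest

from surfpatch.structure import (
    ParseError, ChainError, TypingError, ResidueScore,
    parse_pdb, select_chains, assign_typing, write_annotated_pdb,
)
from conftest import ALA_PDB, single_atom_pdb


HET_HEM = (
    "HETATM   90 FE   HEM A 900       0.000   1.000   2.000"
    "  1.00  0.00          FE\n"
)
WATER = (
    "HETATM   91  O   HOH A 901       5.000   5.000   5.000"
    "  1.00  0.00           O\n"
)


class TestParse:
    def test_basic_atoms_and_single_chain(self):
        s = parse_pdb(ALA_PDB)
        assert s.n_atoms == 5
        assert s.chains == {"A"}
        assert len(s.ligand_atoms) == 0

    def test_cofactor_hetatm_routed_to_ligands(self):
        s = parse_pdb(ALA_PDB + HET_HEM)
        assert s.n_atoms == 5
        assert len(s.ligand_atoms) == 1
        assert s.ligand_atoms.res_name[0] == "HEM"
        assert s.ligand_atoms.hetero[0]

    def test_waters_and_foreign_hetatm_dropped(self):
        other = HET_HEM.replace("HEM", "XYZ")
        s = parse_pdb(ALA_PDB + WATER + other)
        assert s.n_atoms == 5
        assert len(s.ligand_atoms) == 0

    def test_altloc_keeps_highest_occupancy(self):
        lines = ALA_PDB.splitlines()
        # two conformers of CB: A at 0.6, B at 0.4
        cb_a = lines[4][:16] + "A" + lines[4][17:54] + "  0.60" + lines[4][60:]
        cb_b = (lines[4][:16] + "B" + lines[4][17:30]
                + f"{99.0:8.3f}{99.0:8.3f}{99.0:8.3f}" + "  0.40"
                + lines[4][60:])
        text = "\n".join(lines[:4] + [cb_a, cb_b]) + "\n"
        s = parse_pdb(text)
        assert s.n_atoms == 5  # <= raw record count
        cb = s.atoms[s.atoms.atom_name == "CB"]
        assert np.allclose(cb.coord[0], [10.497, 6.178, -4.128], atol=1e-3)

    def test_no_atom_records_is_parse_error(self):
        with pytest.raises(ParseError):
            parse_pdb("HEADER  NOTHING\n")

    def test_malformed_coordinate_names_line(self):
        bad = ALA_PDB.replace("11.639", "xx.xxx")
        with pytest.raises(ParseError, match="line 2"):
            parse_pdb(bad)

    def test_mse_kept_as_polymer_methionine(self):
        mse = (
            "HETATM    9  SD  MSE A   2       1.000   1.000   1.000"
            "  1.00  0.00           S\n"
        )
        s = parse_pdb(ALA_PDB + mse)
        assert s.n_atoms == 6
        assert "MET" in set(s.atoms.res_name)


class TestSelectChains:
    def _two_chain(self):
        b = ALA_PDB.replace(" A ", " B ").replace("A   1", "B   1")
        return parse_pdb(ALA_PDB + b)

    def test_single_chain_selection(self):
        s = self._two_chain()
        a = select_chains(s, {"A"})
        assert a.chains == {"A"}
        assert a.n_atoms == 5

    def test_select_all_is_identity(self):
        s = self._two_chain()
        out = select_chains(s, s.chains)
        assert out.n_atoms == s.n_atoms

    def test_unknown_chain_error_lists_available(self):
        s = self._two_chain()
        with pytest.raises(ChainError, match="chain Z not found"):
            select_chains(s, {"Z"})


class TestTyping:
    def test_radius_and_class_tables(self, ala_structure):
        s = ala_structure
        by_name = {n: i for i, n in enumerate(s.atoms.atom_name)}
        assert s.atoms.vdw_radius[by_name["CB"]] == pytest.approx(1.70)
        assert s.atoms.pharmacophore[by_name["CB"]] == "hydrophobic"
        assert s.atoms.pharmacophore[by_name["N"]] == "donor"
        assert s.atoms.pharmacophore[by_name["O"]] == "acceptor"
        assert s.atoms.vdw_radius[by_name["O"]] == pytest.approx(1.52)

    @pytest.mark.parametrize(
        "res,atom,element,expected",
        [
            ("ARG", "NH1", "N", "positive"),
            ("LYS", "NZ", "N", "positive"),
            ("ASP", "OD1", "O", "negative"),
            ("ASP", "OD2", "O", "negative"),
            ("PHE", "CZ", "C", "aromatic"),
            ("SER", "OG", "O", "donor"),
            ("ASN", "OD1", "O", "acceptor"),
            ("GLY", "O", "O", "acceptor"),
        ],
    )
    def test_class_lookup(self, res, atom, element, expected):
        from surfpatch.structure import _pharmacophore_class

        assert _pharmacophore_class(res, atom, element) == expected

    def test_every_atom_gets_one_class(self, toy_pocket):
        assert len(toy_pocket.atoms.pharmacophore) == len(toy_pocket.atoms)
        assert all(p != "" for p in toy_pocket.atoms.pharmacophore)

    def test_unknown_element_raises(self):
        bad = ALA_PDB + single_atom_pdb(element="Q", name="QQ", serial=9,
                                        res_id=2)
        with pytest.raises(TypingError):
            assign_typing(parse_pdb(bad))


class TestAnnotatedOutput:
    def test_score_encoded_as_b_factor(self, ala_structure):
        out = write_annotated_pdb(ala_structure,
                                  [ResidueScore("A", 1, "", 0.5)])
        atom_lines = [l for l in out.splitlines() if l.startswith("ATOM")]
        assert all(l[60:66].strip() == "50.00" for l in atom_lines)

    def test_zero_and_unscored_residues(self):
        b = ALA_PDB.replace("A   1", "A   2").replace("ATOM      1",
                                                      "ATOM     11")
        s = assign_typing(parse_pdb(ALA_PDB + b))
        out = write_annotated_pdb(s, [ResidueScore("A", 1, "", 0.0)])
        atom_lines = [l for l in out.splitlines() if l.startswith("ATOM")]
        assert all(l[60:66].strip() == "0.00" for l in atom_lines)

    def test_score_out_of_range_rejected(self, ala_structure):
        with pytest.raises(ValueError):
            ResidueScore("A", 1, "", 1.5)

    def test_roundtrip_preserves_identity_and_coords(self, toy_pocket):
        scores = [ResidueScore("A", 1, "", 0.25)]
        text = write_annotated_pdb(toy_pocket, scores)
        s1 = parse_pdb(text)
        text2 = write_annotated_pdb(assign_typing(s1), scores)
        s2 = parse_pdb(text2)
        assert np.allclose(s1.atoms.coord, s2.atoms.coord, atol=1.5e-3)
        assert list(s1.atoms.atom_name) == list(s2.atoms.atom_name)
        assert len(s1.ligand_atoms) == len(toy_pocket.ligand_atoms)
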