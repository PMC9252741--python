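"""Vertex features and pharmacophore distance signatures."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from surfpatch.structure import parse_pdb, assign_typing, ProteinStructure
from surfpatch.surface import compute_ses_mesh
from surfpatch.features import (
    shape_index, chemical_features, graph_signature, compute_vertex_features,
    SIGNATURE_PAIRS, SIGNATURE_CLASSES,
)
from conftest import single_atom_pdb


class TestShapeIndex:
    def test_sphere_is_umbilic(self, test_meshes):
        si = shape_index(test_meshes["sphere5"])
        assert np.abs(np.abs(si) - 1.0).max() < 0.1

    def test_cylinder_side(self, test_meshes):
        mesh = test_meshes["cylinder"]
        side = np.abs(mesh.vertices[:, 2]) < 4.0
        si = shape_index(mesh)
        assert np.abs(np.abs(si[side]) - 0.5).max() < 0.1

    def test_saddle_origin(self, test_meshes):
        mesh = test_meshes["saddle"]
        near = np.linalg.norm(mesh.vertices[:, :2], axis=1) < 0.5
        si = shape_index(mesh)
        assert np.abs(si[near]).max() < 0.1

    def test_range_bounds(self, test_meshes):
        for mesh in test_meshes.values():
            si = shape_index(mesh)
            assert (si >= -1).all() and (si <= 1).all()


def _typed(text):
    return assign_typing(parse_pdb(text))


class TestChemicalFeatures:
    def test_hydropathy_of_ile_scaled_to_one(self):
        pdb = single_atom_pdb().replace("ALA", "ILE")
        s = _typed(pdb)
        mesh = compute_ses_mesh(s)
        chem = chemical_features(mesh, s)
        assert np.allclose(chem["hydropathy"], 1.0)

    def test_electrostatic_zero_between_opposite_charges(self):
        # LYS NZ (+1) and two ASP carboxylate oxygens (-0.5 each),
        # arranged symmetrically about the origin
        pdb = (
            single_atom_pdb(element="N", name="NZ", x=-6.0, serial=1,
                            res_id=1).replace("ALA", "LYS")
            + single_atom_pdb(element="O", name="OD1", x=6.0, serial=2,
                              res_id=2).replace("ALA", "ASP")
            + single_atom_pdb(element="O", name="OD2", x=6.0, serial=3,
                              res_id=2).replace("ALA", "ASP")
        )
        s = _typed(pdb)
        mesh = compute_ses_mesh(s)
        chem = chemical_features(mesh, s)
        mid = np.abs(mesh.vertices[:, 0]) < 0.3
        if mid.any():
            assert np.abs(chem["electrostatic"][mid]).max() < 0.05

    def test_hbond_zero_far_from_donors(self):
        # lone hydrophobic atom: no donors/acceptors within reach
        s = _typed(single_atom_pdb(name="CB"))
        mesh = compute_ses_mesh(s)
        chem = chemical_features(mesh, s)
        assert np.allclose(chem["hbond"], 0.0)

    def test_no_nan_or_inf_anywhere(self, toy_pocket):
        mesh = compute_ses_mesh(toy_pocket, grid=1.2)
        sig = graph_signature(toy_pocket)
        vf = compute_vertex_features(mesh, toy_pocket, signatures=sig)
        assert np.isfinite(vf.matrix).all()


def _toy_structure_from_atoms(rng, n=30):
    """Random cloud of typed atoms spanning several residues."""
    palette = [
        ("LYS", "NZ", "N"), ("ASP", "OD1", "O"), ("ALA", "CB", "C"),
        ("PHE", "CZ", "C"), ("SER", "OG", "O"), ("GLY", "O", "O"),
        ("ALA", "N", "N"),
    ]
    lines = []
    for i in range(n):
        res, name, element = palette[i % len(palette)]
        x, y, z = rng.uniform(-12, 12, 3)
        lines.append(
            single_atom_pdb(element=element, name=name, x=x, y=y, z=z,
                            serial=i + 1, res_id=i + 1).replace("ALA", res)
        )
    return _typed("".join(lines))


def _brute_force_signature(s, bins, neighborhood=30.0):
    """O(n^2) reference enumeration."""
    heavy = s.heavy()
    coords = heavy.coord.astype(float)
    pharm = list(heavy.pharmacophore)
    keys = s.residue_keys()
    res_index = s.atom_residue_index()
    pair_idx = {p: i for i, p in enumerate(SIGNATURE_PAIRS)}
    out = np.zeros((len(keys), len(SIGNATURE_PAIRS), len(bins)))
    for r in range(len(keys)):
        atoms_r = np.where(res_index == r)[0]
        ca = [a for a in atoms_r if heavy.atom_name[a] == "CA"]
        center = coords[ca[0]] if ca else coords[atoms_r].mean(axis=0)
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                ci, cj = pharm[i], pharm[j]
                if ci not in SIGNATURE_CLASSES or cj not in SIGNATURE_CLASSES:
                    continue
                di = np.linalg.norm(coords[i] - center)
                dj = np.linalg.norm(coords[j] - center)
                if di > neighborhood and dj > neighborhood:
                    continue
                d = np.linalg.norm(coords[i] - coords[j])
                lo, hi = sorted([ci, cj], key=SIGNATURE_CLASSES.index)
                p = pair_idx[(lo, hi)]
                for b, edge in enumerate(bins):
                    if d <= edge:
                        out[r, p, b] += 1
    return out


class TestGraphSignature:
    def test_single_pair_cumulative_row(self):
        pdb = (
            single_atom_pdb(element="N", name="N", serial=1, res_id=1)
            + single_atom_pdb(element="O", name="O", x=5.0, serial=2,
                              res_id=1)
        )
        s = _typed(pdb)
        sig = graph_signature(s, bins=(2, 4, 6, 8))
        p = SIGNATURE_PAIRS.index(("donor", "acceptor"))
        assert sig.matrix[0, p].tolist() == [0, 0, 1, 1]

    def test_absent_class_pair_row_is_zero(self):
        s = _typed(single_atom_pdb())
        sig = graph_signature(s)
        p = SIGNATURE_PAIRS.index(("positive", "negative"))
        assert (sig.matrix[:, p, :] == 0).all()

    def test_matches_brute_force_enumeration(self, rng):
        s = _toy_structure_from_atoms(rng, n=30)
        bins = (4.0, 8.0, 12.0, 20.0, 30.0)
        got = graph_signature(s, bins=bins).matrix
        ref = _brute_force_signature(s, bins)
        assert np.array_equal(got, ref)

    def test_rows_non_decreasing(self, toy_dimer):
        sig = graph_signature(toy_dimer.a)
        assert (np.diff(sig.matrix, axis=2) >= 0).all()

    def test_exact_rigid_invariance(self, rng):
        s = _toy_structure_from_atoms(rng, n=20)
        ref = graph_signature(s).matrix
        rot = Rotation.random(random_state=11).as_matrix()
        s2 = ProteinStructure(atoms=s.atoms.copy(),
                              ligand_atoms=s.ligand_atoms)
        s2.atoms.coord = (
            s.atoms.coord.astype(float) @ rot.T + [3.0, -1.0, 2.0]
        ).astype(np.float32)
        moved = graph_signature(s2).matrix
        # distances shift by < 1e-3 under float32 storage; counts can only
        # change for pairs exactly at a bin edge, which the toy avoids
        assert np.array_equal(ref, moved)


class TestVertexFeatures:
    def test_matrix_layout_and_signature_inheritance(self, toy_dimer):
        s = toy_dimer.a
        mesh = compute_ses_mesh(s, grid=1.2)
        sig = graph_signature(s)
        vf = compute_vertex_features(mesh, s, signatures=sig)
        n_sig = sig.flat().shape[1]
        assert vf.matrix.shape == (mesh.n_vertices, 5 + n_sig)
        v = 0
        r = mesh.vertex_residue[v]
        assert np.array_equal(vf.signature[v], sig.flat()[r])
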