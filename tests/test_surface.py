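"""Surface mesh, SASA and buried-surface interface labelling."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from surfpatch.structure import parse_pdb, assign_typing, ProteinStructure
from surfpatch.surface import compute_ses_mesh, compute_sasa, delta_sasa
from surfpatch.fixtures import make_toy_dimer
from conftest import single_atom_pdb


def _structure(*pdb_lines):
    return assign_typing(parse_pdb("".join(pdb_lines)))


@pytest.fixture(scope="module")
def carbon():
    return _structure(single_atom_pdb())


R_C = 1.70 + 1.4  # carbon vdW + probe


class TestMesh:
    def test_single_atom_is_a_sphere(self, carbon):
        mesh = compute_ses_mesh(carbon, grid=0.8)
        d = np.linalg.norm(mesh.vertices, axis=1)
        assert d.max() - d.min() < 2 * 0.8
        assert abs(d.mean() - R_C) < 0.5

    def test_normals_outward_and_unit(self, carbon):
        mesh = compute_ses_mesh(carbon)
        assert np.allclose(np.linalg.norm(mesh.normals, axis=1), 1.0,
                           atol=1e-6)
        assert (np.einsum("ij,ij->i", mesh.normals, mesh.vertices) > 0).all()

    def test_distant_atoms_give_two_components(self):
        s = _structure(
            single_atom_pdb(),
            single_atom_pdb(x=100.0, serial=2, res_id=2),
        )
        mesh = compute_ses_mesh(s)
        import scipy.sparse as sp
        from surfpatch.patches import edge_graph

        n, _ = sp.csgraph.connected_components(edge_graph(mesh))
        assert n == 2

    def test_vertex_count_grows_with_resolution(self, carbon):
        coarse = compute_ses_mesh(carbon, grid=1.0)
        fine = compute_ses_mesh(carbon, grid=0.5)
        assert fine.n_vertices > coarse.n_vertices

    def test_every_vertex_referenced_and_no_degenerate_faces(self, carbon):
        mesh = compute_ses_mesh(carbon)
        assert set(np.unique(mesh.triangles)) == set(range(mesh.n_vertices))
        assert (mesh.triangle_areas() > 0).all()

    def test_vertex_residue_map(self):
        s = _structure(
            single_atom_pdb(),
            single_atom_pdb(x=100.0, serial=2, res_id=2),
        )
        mesh = compute_ses_mesh(s)
        near_first = np.linalg.norm(mesh.vertices, axis=1) < 50
        assert (mesh.vertex_residue[near_first] == 0).all()
        assert (mesh.vertex_residue[~near_first] == 1).all()

    def test_mesh_area_close_to_sasa_for_convex_body(self, carbon):
        mesh = compute_ses_mesh(carbon, grid=0.5)
        sasa = compute_sasa(carbon).total
        assert abs(mesh.area - sasa) / sasa < 0.15


class TestSasa:
    def test_isolated_atom_closed_form(self, carbon):
        got = compute_sasa(carbon).total
        exact = 4 * np.pi * R_C ** 2
        assert abs(got - exact) / exact < 0.01

    def test_two_distant_atoms_additive(self):
        s = _structure(
            single_atom_pdb(),
            single_atom_pdb(x=100.0, serial=2, res_id=2),
        )
        assert compute_sasa(s).total == pytest.approx(
            2 * 4 * np.pi * R_C ** 2, rel=1e-6
        )

    @pytest.mark.parametrize("d", [2.0, 4.0, 5.5])
    def test_two_sphere_cap_occlusion_oracle(self, d):
        # closed form: each sphere loses a cap of height h = R - d/2
        s = _structure(
            single_atom_pdb(),
            single_atom_pdb(x=d, serial=2, res_id=2),
        )
        h = R_C - d / 2
        exact = 2 * (4 * np.pi * R_C ** 2 - 2 * np.pi * R_C * h)
        got = compute_sasa(s).total
        assert abs(got - exact) / exact < 0.02

    def test_rigid_motion_invariance(self, rng):
        lines = [
            single_atom_pdb(x=x, y=y, z=z, serial=i + 1, res_id=i + 1)
            for i, (x, y, z) in enumerate(rng.normal(0, 3, (15, 3)))
        ]
        s = _structure(*lines)
        ref = compute_sasa(s).atom_sasa
        rot = Rotation.random(random_state=3).as_matrix()
        s2 = ProteinStructure(atoms=s.atoms.copy(),
                              ligand_atoms=s.ligand_atoms)
        s2.atoms.coord = (s.atoms.coord @ rot.T + [7.0, -2.0, 4.0]).astype(
            np.float32
        )
        moved = compute_sasa(s2).atom_sasa
        # float32 coordinate storage limits agreement; the sample frame
        # itself co-rotates exactly
        assert np.abs(moved - ref).max() / ref.max() < 1e-5

    def test_residue_sum_matches_total(self, toy_dimer):
        t = compute_sasa(toy_dimer.a)
        assert t.table["sasa"].sum() == pytest.approx(t.atom_sasa.sum(),
                                                      abs=1e-6)

    def test_too_few_points_rejected(self, carbon):
        with pytest.raises(ValueError):
            compute_sasa(carbon, n_points=8)


class TestDeltaSasa:
    def test_separated_protomers_zero_everywhere(self):
        dim = make_toy_dimer(contact_width=0, seed=1)
        labels = delta_sasa(dim.a, dim.b)
        assert labels.table["delta_sasa"].abs().max() == 0.0
        assert not labels.table["flag"].any()

    def test_burial_is_nonnegative(self, toy_dimer):
        labels = delta_sasa(toy_dimer.a, toy_dimer.b)
        assert (labels.table["delta_sasa"] >= -1e-6).all()

    def test_symmetric_dimer_flags_chain_symmetric(self):
        # full-width contact: the 180-degree rotation maps residue i of A
        # onto residue i of B, so flags must agree under the chain swap
        dim = make_toy_dimer(n_res=16, contact_width=16, seed=2)
        labels = delta_sasa(dim.a, dim.b)
        a_flags = {k[1] for k in labels.flagged() if k[0] == "A"}
        b_flags = {k[1] for k in labels.flagged() if k[0] == "B"}
        assert a_flags == b_flags

    def test_definitional_oracle_high_density(self, toy_dimer):
        from surfpatch.structure import merge
        from surfpatch.surface import principal_frame

        a, b = toy_dimer.a, toy_dimer.b
        labels = delta_sasa(a, b, n_points=960)
        frame = principal_frame(merge(a, b).heavy().coord)
        dense = {}
        bound = compute_sasa(merge(a, b), n_points=4000,
                             frame=frame).residue_sasa()
        for part in (a, b):
            unbound = compute_sasa(part, n_points=4000,
                                   frame=frame).residue_sasa()
            for k, v in unbound.items():
                dense[k] = v - bound[k]
        for row in labels.table.itertuples():
            key = (row.chain_id, row.res_id, row.ins_code)
            assert abs(row.delta_sasa - dense[key]) < 0.5

    def test_chain_collision_rejected(self, toy_dimer):
        with pytest.raises(KeyError):
            delta_sasa(toy_dimer.a, toy_dimer.a)

    def test_vertex_flag_projection(self, toy_dimer):
        labels = delta_sasa(toy_dimer.a, toy_dimer.b)
        mesh = compute_ses_mesh(toy_dimer.a, grid=1.2)
        vf = labels.vertex_flags(mesh)
        flagged_res = {
            k for k in labels.flagged() if k[0] == "A"
        }
        for vid in np.where(vf)[0]:
            assert mesh.residue_keys[mesh.vertex_residue[vid]] in flagged_res
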