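"""Model-level operations: sampling, labelling, pockets, prediction, I/O."""

import numpy as np
import pytest

from surfpatch.structure import parse_pdb, assign_typing
from surfpatch.surface import compute_ses_mesh
from surfpatch.patches import extract_patches
from surfpatch.model import (
    ModelConfig, balanced_sample, featurize_structure, SiteModel,
    SiteResults, LigandModel, LigandResults, detect_pockets,
    label_ligand_patches,
)
from surfpatch.fixtures import make_toy_pocket, make_toy_dimer
from conftest import single_atom_pdb


class TestBalancedSample:
    def test_equal_class_counts(self, rng):
        labels = np.zeros(110, dtype=bool)
        labels[:10] = True
        idx = balanced_sample(labels, seed=3)
        assert len(idx) == 20
        assert labels[idx].sum() == 10

    def test_all_kept_when_already_balanced(self):
        labels = np.array([True] * 10 + [False] * 10)
        idx = balanced_sample(labels, seed=0)
        assert len(idx) == 20
        assert sorted(idx) == list(range(20))

    def test_deterministic_for_fixed_seed(self):
        labels = np.zeros(200, dtype=bool)
        labels[:20] = True
        a = balanced_sample(labels, seed=42)
        b = balanced_sample(labels, seed=42)
        assert np.array_equal(a, b)
        c = balanced_sample(labels, seed=43)
        assert not np.array_equal(a, c)

    def test_missing_class_raises_with_name(self):
        with pytest.raises(ValueError, match="prot7"):
            balanced_sample(np.zeros(5, dtype=bool), seed=0, name="prot7")


class TestLigandLabelling:
    def _mesh_with_centers(self):
        s = assign_typing(parse_pdb(single_atom_pdb()))
        mesh = compute_ses_mesh(s)
        patches = extract_patches(mesh, r_max=0.0,
                                  centers=np.arange(mesh.n_vertices))
        return s, mesh, patches

    def test_three_angstrom_rule(self, toy_pocket):
        from scipy.spatial import cKDTree

        mesh = compute_ses_mesh(toy_pocket, grid=1.2)
        patches = extract_patches(mesh, r_max=0.0,
                                  centers=np.arange(mesh.n_vertices))
        labels = label_ligand_patches(patches, toy_pocket.ligand_atoms, mesh)
        d, _ = cKDTree(toy_pocket.ligand_atoms.coord).query(mesh.vertices)
        for lab, dist in zip(labels, d):
            if dist < 3.0:
                assert lab == "HEM"
            else:
                assert lab is None
        assert any(lab == "HEM" for lab in labels)

    def test_no_ligand_atoms_all_none(self):
        s, mesh, patches = self._mesh_with_centers()
        labels = label_ligand_patches(patches, s.ligand_atoms, mesh)
        assert all(lab is None for lab in labels)


class TestPocketDetection:
    def test_synthetic_pocket_found_at_cavity(self, toy_pocket):
        mesh = compute_ses_mesh(toy_pocket, grid=1.2)
        pockets = detect_pockets(toy_pocket, mesh)
        assert len(pockets) >= 1
        # the top pocket's vertices surround the planted ligand
        from scipy.spatial import cKDTree

        d, _ = cKDTree(toy_pocket.ligand_atoms.coord).query(
            mesh.vertices[pockets[0].vertices]
        )
        assert d.min() < 4.0

    def test_isolated_atom_has_no_pockets(self):
        s = assign_typing(parse_pdb(single_atom_pdb()))
        mesh = compute_ses_mesh(s)
        assert detect_pockets(s, mesh) == []

    def test_sorted_by_size_stable(self, toy_pocket):
        mesh = compute_ses_mesh(toy_pocket, grid=1.2)
        pockets = detect_pockets(toy_pocket, mesh)
        sizes = [p.size for p in pockets]
        assert sizes == sorted(sizes, reverse=True)
        again = detect_pockets(toy_pocket, mesh)
        assert [list(p.vertices) for p in pockets] == \
               [list(p.vertices) for p in again]


@pytest.fixture(scope="module")
def tiny_fit():
    dim = make_toy_dimer(seed=4)
    cfg = ModelConfig(epochs=5)
    model = SiteModel.from_dimers([dim], cfg, grid=1.4)
    return model, model.fit(seed=17)


@pytest.fixture(scope="module")
def pocket_setup():
    items = [(make_toy_pocket(c, seed=s), c)
             for c in ("HEM", "ADP") for s in (0, 1)]
    return LigandModel.from_structures(
        items, classes=("HEM", "ADP"),
        config=ModelConfig(epochs=3), grid=1.4,
    )


class TestSitePrediction:
    def test_scores_in_unit_interval_every_residue_scored(self, tiny_fit):
        model, res = tiny_fit
        scores, vertex_scores, fp = res.predict_structure(
            model.proteins[0].structure, grid=1.4
        )
        assert ((vertex_scores >= 0) & (vertex_scores <= 1)).all()
        scored = {(s.chain_id, s.residue_number) for s in scores}
        surface_res = {
            fp.mesh.residue_keys[r][:2]
            for r in np.unique(fp.mesh.vertex_residue)
        }
        assert scored == surface_res

    def test_zero_weight_model_scores_half(self, tiny_fit):
        model, res = tiny_fit
        import copy

        dead = copy.deepcopy(res)
        for k in dead.head:
            dead.head[k] = np.zeros_like(dead.head[k])
        sc = dead.predict_vertices(model.proteins[0])
        assert np.allclose(sc, 0.5)

    def test_fixed_seed_reproducible_loss_trace(self):
        dim = make_toy_dimer(seed=4)
        cfg = ModelConfig(epochs=4)
        model = SiteModel.from_dimers([dim], cfg, grid=1.4)
        t1 = model.fit(seed=17).loss_trace
        t2 = model.fit(seed=17).loss_trace
        assert np.array_equal(t1, t2)

    def test_save_load_roundtrip_identical_predictions(self, tiny_fit,
                                                       tmp_path):
        model, res = tiny_fit
        path = tmp_path / "m.npz"
        res.save(str(path))
        back = SiteResults.load(str(path))
        a = res.predict_vertices(model.proteins[0])
        b = back.predict_vertices(model.proteins[0])
        assert np.array_equal(a, b)

    def test_loss_decreases_after_warmup(self, tiny_fit):
        # full-batch Adam oscillates on tiny problems, so assert the
        # smoothed trend rather than pointwise monotonicity
        dim = make_toy_dimer(seed=4)
        model = SiteModel.from_dimers([dim], ModelConfig(epochs=60),
                                      grid=1.4)
        trace = model.fit(seed=17).loss_trace
        assert trace[-10:].min() < trace[10]
        assert trace[-10:].mean() < trace[:10].mean()


class TestLigandPrediction:
    def test_prediction_is_simplex(self, pocket_setup):
        model = pocket_setup
        res = model.fit(seed=17, draws_per_pocket=1)
        fp, verts = model.pockets[0]
        pred = res.classify_pocket(fp, verts, samples=20, seed=0)
        assert pred.scores.sum() == pytest.approx(1.0, abs=1e-6)
        assert (pred.scores >= 0).all()
        assert pred.sample_count == 20

    def test_untrained_symmetric_head_is_uniform(self, pocket_setup):
        model = pocket_setup
        res = model.fit(seed=17, draws_per_pocket=1)
        # zero the classifier output layer: softmax must be exactly uniform
        res.head["W3"] = np.zeros_like(res.head["W3"])
        res.head["b3"] = np.zeros_like(res.head["b3"])
        fp, verts = model.pockets[0]
        pred = res.classify_pocket(fp, verts, samples=10, seed=0)
        assert np.allclose(pred.scores, 0.5, atol=1e-12)

    def test_default_sample_count_is_100(self, pocket_setup):
        import inspect

        sig = inspect.signature(LigandResults.classify_pocket)
        assert sig.parameters["samples"].default == 100

    def test_save_load_roundtrip(self, pocket_setup, tmp_path):
        model = pocket_setup
        res = model.fit(seed=17, draws_per_pocket=1)
        path = tmp_path / "lig.npz"
        res.save(str(path))
        back = LigandResults.load(str(path))
        fp, verts = model.pockets[1]
        a = res.classify_pocket(fp, verts, samples=5, seed=3).scores
        b = back.classify_pocket(fp, verts, samples=5, seed=3).scores
        assert np.array_equal(a, b)
        assert back.classes == ("HEM", "ADP")
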