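"""Trainable surface models: interaction-site scoring and pocket classification.

The module follows a fit/results pattern: :class:`SiteModel` and
:class:`LigandModel` are built from featurized structures, their ``fit()``
returns :class:`SiteResults` / :class:`LigandResults` objects that carry the
trained parameters, the loss trace and prediction methods.

Both models share the same trunk — a Gaussian-kernel embedding of overlapping
geodesic surface patches (radius 12 Angstrom by default) with rotation
max-pooling — followed by a small ReLU head: a per-patch sigmoid score for the
interaction-site task, a softmax over cofactor classes (pooled over sampled
pocket vertices) for the ligand task.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .structure import ProteinStructure, ResidueScore, COFACTOR_CODES
from .surface import SurfaceMesh, compute_ses_mesh, delta_sasa, fibonacci_sphere
from .features import graph_signature, compute_vertex_features
from .patches import Patch, edge_graph, extract_patches, DEFAULT_PATCH_RADIUS
from .nn import (
    KernelEmbedder, Adam, PatchBatch, pack_patches, leaky_relu,
    leaky_relu_grad, sigmoid, softmax,
)

__all__ = [
    "ModelConfig",
    "FeaturizedProtein",
    "featurize_structure",
    "balanced_sample",
    "SiteModel",
    "SiteResults",
    "LigandModel",
    "LigandResults",
    "PocketPrediction",
    "Pocket",
    "detect_pockets",
    "label_ligand_patches",
]


@dataclass
class ModelConfig:
    """Hyperparameters of the patch network.

    Defaults are desk-scale: 12 kernels on a 3-ring x 4-spoke polar grid over
    a 12 Angstrom geodesic patch, a 16-wide embedding, 8 rotation offsets and
    a single 16-unit hidden layer (two trainable layers in total).
    """

    n_kernels: int = 12
    embed_dim: int = 16
    hidden_dim: int = 16
    rotations: int = 8
    layers: int = 2
    patch_radius: float = DEFAULT_PATCH_RADIUS
    max_patch_vertices: int = 32
    centers_per_class: int = 32
    learning_rate: float = 0.02
    epochs: int = 100
    seed: int = 17

    def __post_init__(self):
        for name in ("n_kernels", "embed_dim", "hidden_dim", "rotations",
                     "layers", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class FeaturizedProtein:
    """A structure with its surface mesh, per-vertex features and edge graph."""

    structure: ProteinStructure
    mesh: SurfaceMesh
    matrix: np.ndarray          # (n_vertices, n_features), unscaled
    graph: object               # sparse edge graph for geodesics

    @property
    def n_vertices(self) -> int:
        return self.mesh.n_vertices


def featurize_structure(
    s: ProteinStructure, grid: float = 0.8, probe: float = 1.4
) -> FeaturizedProtein:
    """Mesh a structure and compute the full per-vertex feature matrix."""
    mesh = compute_ses_mesh(s, probe=probe, grid=grid)
    sig = graph_signature(s)
    vf = compute_vertex_features(mesh, s, signatures=sig)
    return FeaturizedProtein(
        structure=s, mesh=mesh, matrix=vf.matrix, graph=edge_graph(mesh)
    )


def patches_for(
    fp: FeaturizedProtein, centers, radius: float = DEFAULT_PATCH_RADIUS,
    attach_features: bool = False,
) -> list:
    """Geodesic patches at the given centers.

    Feature rows are normally gathered later (at batch packing) from
    ``fp.matrix``; ``attach_features=True`` copies them onto each patch.
    """
    return extract_patches(
        fp.mesh, features=fp.matrix if attach_features else None,
        r_max=radius, centers=centers, graph=fp.graph,
    )


def balanced_sample(labels: np.ndarray, seed: int, name: str = "") -> np.ndarray:
    """All positive indices plus an equal number of sampled negatives.

    Negatives are drawn uniformly without replacement; for a fixed seed the
    selection is deterministic.  Raises if either class is absent.
    """
    labels = np.asarray(labels, dtype=bool)
    pos = np.where(labels)[0]
    neg = np.where(~labels)[0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError(
            f"balanced sampling requires both classes; protein {name!r} has "
            f"{len(pos)} positives and {len(neg)} negatives"
        )
    rng = np.random.default_rng(seed)
    if len(neg) > len(pos):
        neg = rng.choice(neg, size=len(pos), replace=False)
    elif len(pos) > len(neg):
        pos = rng.choice(pos, size=len(neg), replace=False)
    return np.concatenate([np.sort(pos), np.sort(neg)])


def _feature_scale(matrices):
    """Per-column max-abs scale and the mask of informative columns.

    Columns that are zero over the whole training corpus carry no signal and
    are dropped from the model input (the mask is stored with the fitted
    parameters and applied identically at prediction time).
    """
    scale = np.zeros(matrices[0].shape[1])
    for m in matrices:
        scale = np.maximum(scale, np.abs(m).max(axis=0))
    mask = scale > 1e-12
    scale = scale.copy()
    scale[~mask] = 1.0
    return scale, mask


# --------------------------------------------------------------------------
# Site model
# --------------------------------------------------------------------------


class SiteModel:
    """Binary interaction-site model over surface patches.

    ``proteins`` is a list of :class:`FeaturizedProtein`; ``labels`` the
    matching per-vertex interface flags (from the buried-surface-area rule).
    """

    def __init__(self, proteins, labels, config: ModelConfig | None = None):
        if len(proteins) != len(labels):
            raise ValueError("proteins and labels must align")
        self.proteins = list(proteins)
        self.labels = [np.asarray(l, dtype=bool) for l in labels]
        self.config = config or ModelConfig()

    @classmethod
    def from_dimers(cls, dimers, config: ModelConfig | None = None,
                    grid: float = 0.8, both_protomers: bool = False):
        """Featurize the protomers of each dimer; labels from dSASA.

        By default only chain-A protomers are kept (one protein per complex);
        ``both_protomers=True`` doubles the corpus.
        """
        proteins, labels = [], []
        for d in dimers:
            iface = delta_sasa(d.a, d.b)
            parts = (d.a, d.b) if both_protomers else (d.a,)
            for part in parts:
                fp = featurize_structure(part, grid=grid)
                proteins.append(fp)
                labels.append(iface.vertex_flags(fp.mesh))
        return cls(proteins, labels, config=config)

    def fit(self, seed: int | None = None) -> "SiteResults":
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        scale, fmask = _feature_scale([fp.matrix for fp in self.proteins])

        all_patches, y = [], []
        for i, (fp, lab) in enumerate(zip(self.proteins, self.labels)):
            idx = balanced_sample(lab, seed=seed + 1000 * i, name=str(i))
            # cap the per-protein training centers, keeping classes balanced
            cap = cfg.centers_per_class
            pos, neg = idx[lab[idx]], idx[~lab[idx]]
            if len(pos) > cap:
                sub = np.random.default_rng(seed + 1000 * i + 1)
                pos = np.sort(sub.choice(pos, size=cap, replace=False))
                neg = np.sort(sub.choice(neg, size=cap, replace=False))
                idx = np.concatenate([pos, neg])
            all_patches.append(
                pack_patches(
                    patches_for(fp, idx, radius=cfg.patch_radius),
                    max_vertices=cfg.max_patch_vertices,
                    feature_matrix=fp.matrix,
                )
            )
            y.append(lab[idx])
        y = np.concatenate(y).astype(float)
        batch = _concat_batches(all_patches)
        batch.features = batch.features[:, :, fmask] / scale[fmask]

        emb = KernelEmbedder(
            n_features=batch.features.shape[2], n_kernels=cfg.n_kernels,
            embed_dim=cfg.embed_dim, rotations=cfg.rotations,
            patch_radius=cfg.patch_radius, rng=rng,
        )
        head = {
            "W2": rng.normal(0, np.sqrt(2.0 / cfg.embed_dim),
                             (cfg.embed_dim, cfg.hidden_dim)),
            "b2": np.zeros(cfg.hidden_dim),
            "w3": np.zeros(cfg.hidden_dim),
            "b3": np.zeros(1),
        }
        opt_e = Adam(emb.params, lr=cfg.learning_rate)
        opt_h = Adam(head, lr=cfg.learning_rate)
        trace = []
        B = batch.size
        for epoch in range(cfg.epochs):
            h, cache = emb.forward(batch, want_cache=True)
            zu = h @ head["W2"] + head["b2"]
            u = leaky_relu(zu)
            logit = u @ head["w3"] + head["b3"][0]
            p = sigmoid(logit)
            eps = 1e-12
            loss = -np.mean(
                y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    "training diverged (loss is not finite); "
                    "lower the learning rate"
                )
            trace.append(float(loss))
            dlogit = (p - y) / B
            gh = {
                "w3": u.T @ dlogit,
                "b3": np.array([dlogit.sum()]),
            }
            du = dlogit[:, None] * head["w3"][None, :]
            du *= leaky_relu_grad(zu)
            gh["W2"] = h.T @ du
            gh["b2"] = du.sum(axis=0)
            dh = du @ head["W2"].T
            ge = emb.backward(dh, cache)
            opt_e.step(emb.params, ge)
            opt_h.step(head, gh)
        return SiteResults(
            config=cfg, embedder=emb, head=head, feature_scale=scale,
            feature_mask=fmask, loss_trace=np.array(trace), seed=seed,
        )


@dataclass
class SiteResults:
    """Fitted interaction-site model."""

    config: ModelConfig
    embedder: KernelEmbedder
    head: dict
    feature_scale: np.ndarray
    loss_trace: np.ndarray
    seed: int
    feature_mask: np.ndarray = None

    def __post_init__(self):
        if self.feature_mask is None:
            self.feature_mask = np.ones(len(self.feature_scale), dtype=bool)

    def predict_vertices(self, fp: FeaturizedProtein,
                         centers=None) -> np.ndarray:
        """Per-center interface scores in [0, 1] (default: every vertex)."""
        if centers is None:
            centers = np.arange(fp.n_vertices)
        cfg = self.config
        scores = np.empty(len(centers))
        # chunk to bound memory on dense meshes
        for lo in range(0, len(centers), 2048):
            sel = centers[lo:lo + 2048]
            pt = patches_for(fp, sel, radius=cfg.patch_radius)
            batch = pack_patches(pt, max_vertices=cfg.max_patch_vertices,
                                 feature_matrix=fp.matrix)
            batch.features = (
                batch.features[:, :, self.feature_mask]
                / self.feature_scale[self.feature_mask]
            )
            h = self.embedder.forward(batch)
            u = leaky_relu(h @ self.head["W2"] + self.head["b2"])
            scores[lo:lo + 2048] = sigmoid(
                u @ self.head["w3"] + self.head["b3"][0]
            )
        return scores

    def predict_structure(self, s: ProteinStructure, grid: float = 0.8):
        """Residue-level scores (max over the residue's surface vertices)."""
        fp = featurize_structure(s, grid=grid)
        vertex_scores = self.predict_vertices(fp)
        res_scores = []
        for ri, key in enumerate(fp.mesh.residue_keys):
            mask = fp.mesh.vertex_residue == ri
            if mask.any():
                res_scores.append(
                    ResidueScore(key[0], key[1], key[2],
                                 float(vertex_scores[mask].max()))
                )
        return res_scores, vertex_scores, fp

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Interaction-site patch model",
            "=" * 44,
            f"kernels            {cfg.n_kernels}",
            f"embedding dim      {cfg.embed_dim}",
            f"hidden dim         {cfg.hidden_dim}",
            f"rotations          {cfg.rotations}",
            f"patch radius       {cfg.patch_radius:.1f} A",
            f"seed               {self.seed}",
            f"epochs             {len(self.loss_trace)}",
            f"initial loss       {self.loss_trace[0]:.4f}",
            f"final loss         {self.loss_trace[-1]:.4f}",
        ]
        return "\n".join(lines)

    def save(self, path: str) -> None:
        _save_results(path, kind="site", config=self.config,
                      embedder=self.embedder, head=self.head,
                      feature_scale=self.feature_scale,
                      feature_mask=self.feature_mask,
                      loss_trace=self.loss_trace, seed=self.seed)

    @classmethod
    def load(cls, path: str) -> "SiteResults":
        payload = _load_results(path, expected_kind="site")
        return cls(**payload)


# --------------------------------------------------------------------------
# Ligand model
# --------------------------------------------------------------------------


@dataclass
class PocketPrediction:
    """Averaged class scores for one pocket (non-negative, sum to one)."""

    classes: tuple
    scores: np.ndarray
    sample_count: int

    @property
    def top(self) -> str:
        return self.classes[int(np.argmax(self.scores))]

    def as_dict(self) -> dict:
        return {c: float(s) for c, s in zip(self.classes, self.scores)}


class LigandModel:
    """Multi-class pocket classifier over sampled surface patches.

    ``pockets`` is a list of (FeaturizedProtein, pocket-vertex-id-array);
    ``labels`` the matching cofactor class names.  ``classes`` fixes the
    output order (default: the seven recognised cofactors).
    """

    def __init__(self, pockets, labels, classes=COFACTOR_CODES,
                 config: ModelConfig | None = None,
                 vertices_per_sample: int = 32):
        self.pockets = list(pockets)
        self.labels = list(labels)
        self.classes = tuple(classes)
        unknown = set(self.labels) - set(self.classes)
        if unknown:
            raise ValueError(f"labels outside class set: {sorted(unknown)}")
        self.config = config or ModelConfig()
        self.vertices_per_sample = vertices_per_sample

    @classmethod
    def from_structures(cls, structures_with_labels, classes=None,
                        config: ModelConfig | None = None,
                        grid: float = 0.8, cutoff: float = 3.0):
        """Featurize pocket structures; pocket vertices from the < 3 A rule."""
        pockets, labels = [], []
        for s, lab in structures_with_labels:
            fp = featurize_structure(s, grid=grid)
            if len(s.ligand_atoms) == 0:
                raise ValueError("pocket structure has no ligand atoms")
            d, _ = cKDTree(s.ligand_atoms.coord).query(fp.mesh.vertices)
            verts = np.where(d < cutoff)[0]
            if len(verts) == 0:
                raise ValueError("no surface vertex within the label cutoff")
            pockets.append((fp, verts))
            labels.append(lab)
        if classes is None:
            classes = tuple(sorted(set(labels)))
        return cls(pockets, labels, classes=classes, config=config)

    def fit(self, seed: int | None = None,
            draws_per_pocket: int = 2) -> "LigandResults":
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        scale, fmask = _feature_scale([fp.matrix for fp, _ in self.pockets])
        C = len(self.classes)
        cls_index = {c: i for i, c in enumerate(self.classes)}
        y = np.array([cls_index[l] for l in self.labels])

        # precompute patches for every pocket vertex, per pocket
        batches = []
        for fp, verts in self.pockets:
            pt = patches_for(fp, verts, radius=cfg.patch_radius)
            b = pack_patches(pt, max_vertices=cfg.max_patch_vertices,
                             feature_matrix=fp.matrix)
            b.features = b.features[:, :, fmask] / scale[fmask]
            batches.append(b)

        emb = KernelEmbedder(
            n_features=batches[0].features.shape[2], n_kernels=cfg.n_kernels,
            embed_dim=cfg.embed_dim, rotations=cfg.rotations,
            patch_radius=cfg.patch_radius, rng=rng,
        )
        head = {
            "W2": rng.normal(0, np.sqrt(2.0 / cfg.embed_dim),
                             (cfg.embed_dim, cfg.hidden_dim)),
            "b2": np.zeros(cfg.hidden_dim),
            "W3": np.zeros((cfg.hidden_dim, C)),
            "b3": np.zeros(C),
        }
        opt_e = Adam(emb.params, lr=cfg.learning_rate)
        opt_h = Adam(head, lr=cfg.learning_rate)
        trace = []
        m = self.vertices_per_sample
        full = _concat_batches(batches)
        offsets = np.cumsum([0] + [b.size for b in batches[:-1]])
        for epoch in range(cfg.epochs):
            # draw vertex samples for this epoch
            sub_parts, targets = [], []
            for pi, b in enumerate(batches):
                n = b.size
                for _ in range(draws_per_pocket):
                    take = rng.choice(n, size=m, replace=n < m)
                    sub_parts.append(take + offsets[pi])
                    targets.append(y[pi])
            idx = np.concatenate(sub_parts)
            gathered = PatchBatch(
                rho=full.rho[idx], theta=full.theta[idx],
                mask=full.mask[idx], features=full.features[idx],
            )
            S = len(targets)
            t = np.array(targets)
            h, cache = emb.forward(gathered, want_cache=True)
            hbar = h.reshape(S, m, -1).mean(axis=1)
            zu = hbar @ head["W2"] + head["b2"]
            u = leaky_relu(zu)
            logits = u @ head["W3"] + head["b3"]
            p = softmax(logits, axis=1)
            loss = -np.mean(np.log(p[np.arange(S), t] + 1e-12))
            if not np.isfinite(loss):
                raise RuntimeError(
                    "training diverged (loss is not finite); "
                    "lower the learning rate"
                )
            trace.append(float(loss))
            dlogits = p.copy()
            dlogits[np.arange(S), t] -= 1.0
            dlogits /= S
            gh = {
                "W3": u.T @ dlogits,
                "b3": dlogits.sum(axis=0),
            }
            du = dlogits @ head["W3"].T
            du *= leaky_relu_grad(zu)
            gh["W2"] = hbar.T @ du
            gh["b2"] = du.sum(axis=0)
            dhbar = du @ head["W2"].T
            dh = np.repeat(dhbar / m, m, axis=0)
            ge = emb.backward(dh, cache)
            opt_e.step(emb.params, ge)
            opt_h.step(head, gh)
        return LigandResults(
            config=cfg, embedder=emb, head=head, feature_scale=scale,
            feature_mask=fmask, classes=self.classes,
            loss_trace=np.array(trace), seed=seed, vertices_per_sample=m,
        )


def _concat_batches(batches) -> PatchBatch:
    V = max(b.rho.shape[1] for b in batches)
    D = batches[0].features.shape[2]

    def pad(a, V, extra=()):
        out = np.zeros((a.shape[0], V) + tuple(extra))
        out[:, :a.shape[1]] = a
        return out

    return PatchBatch(
        rho=np.vstack([pad(b.rho, V) for b in batches]),
        theta=np.vstack([pad(b.theta, V) for b in batches]),
        mask=np.vstack([pad(b.mask, V) for b in batches]),
        features=np.concatenate(
            [pad(b.features, V, (D,)) for b in batches], axis=0
        ),
    )


@dataclass
class LigandResults:
    """Fitted pocket classifier."""

    config: ModelConfig
    embedder: KernelEmbedder
    head: dict
    feature_scale: np.ndarray
    classes: tuple
    loss_trace: np.ndarray
    seed: int
    vertices_per_sample: int = 32
    feature_mask: np.ndarray = None

    def __post_init__(self):
        if self.feature_mask is None:
            self.feature_mask = np.ones(len(self.feature_scale), dtype=bool)

    def _forward_sample(self, batch: PatchBatch) -> np.ndarray:
        h = self.embedder.forward(batch)
        hbar = h.mean(axis=0, keepdims=True)
        u = leaky_relu(hbar @ self.head["W2"] + self.head["b2"])
        return softmax(u @ self.head["W3"] + self.head["b3"], axis=1)[0]

    def classify_pocket(
        self, fp: FeaturizedProtein, pocket_vertices, samples: int = 100,
        seed: int = 0,
    ) -> PocketPrediction:
        """Average class probabilities over repeated vertex subsamples.

        Each of ``samples`` draws takes ``vertices_per_sample`` pocket
        vertices (with replacement when the pocket is smaller), embeds their
        patches, mean-pools and classifies; the final score is the mean of
        the per-draw probability vectors.
        """
        verts = np.asarray(pocket_vertices, dtype=int)
        if len(verts) == 0:
            raise ValueError("pocket has no vertices")
        cfg = self.config
        pt = patches_for(fp, verts, radius=cfg.patch_radius)
        batch = pack_patches(pt, max_vertices=cfg.max_patch_vertices,
                             feature_matrix=fp.matrix)
        batch.features = (
            batch.features[:, :, self.feature_mask]
            / self.feature_scale[self.feature_mask]
        )
        rng = np.random.default_rng(seed)
        m = self.vertices_per_sample
        acc = np.zeros(len(self.classes))
        for _ in range(samples):
            take = rng.choice(batch.size, size=m, replace=batch.size < m)
            sub = PatchBatch(
                rho=batch.rho[take], theta=batch.theta[take],
                mask=batch.mask[take], features=batch.features[take],
            )
            acc += self._forward_sample(sub)
        return PocketPrediction(
            classes=self.classes, scores=acc / samples, sample_count=samples
        )

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Pocket ligand-class patch model",
            "=" * 44,
            f"classes            {', '.join(self.classes)}",
            f"kernels            {cfg.n_kernels}",
            f"embedding dim      {cfg.embed_dim}",
            f"rotations          {cfg.rotations}",
            f"patch radius       {cfg.patch_radius:.1f} A",
            f"vertices/sample    {self.vertices_per_sample}",
            f"seed               {self.seed}",
            f"epochs             {len(self.loss_trace)}",
            f"initial loss       {self.loss_trace[0]:.4f}",
            f"final loss         {self.loss_trace[-1]:.4f}",
        ]
        return "\n".join(lines)

    def save(self, path: str) -> None:
        _save_results(path, kind="ligand", config=self.config,
                      embedder=self.embedder, head=self.head,
                      feature_scale=self.feature_scale,
                      feature_mask=self.feature_mask,
                      loss_trace=self.loss_trace, seed=self.seed,
                      classes=self.classes,
                      vertices_per_sample=self.vertices_per_sample)

    @classmethod
    def load(cls, path: str) -> "LigandResults":
        payload = _load_results(path, expected_kind="ligand")
        return cls(**payload)


# --------------------------------------------------------------------------
# Serialization (versioned npz container with a JSON header)
# --------------------------------------------------------------------------

_FORMAT_VERSION = 1


def _save_results(path, kind, config, embedder, head, feature_scale,
                  loss_trace, seed, feature_mask=None, classes=None,
                  vertices_per_sample=None):
    meta = {
        "format_version": _FORMAT_VERSION,
        "kind": kind,
        "config": asdict(config),
        "seed": seed,
        "embedder": {
            "K": embedder.K, "D": embedder.D, "E": embedder.E,
            "R": embedder.R,
        },
    }
    if classes is not None:
        meta["classes"] = list(classes)
    if vertices_per_sample is not None:
        meta["vertices_per_sample"] = vertices_per_sample
    arrays = {f"emb_{k}": v for k, v in embedder.params.items()}
    arrays.update({f"head_{k}": v for k, v in head.items()})
    arrays["feature_scale"] = feature_scale
    arrays["feature_mask"] = (
        feature_mask if feature_mask is not None
        else np.ones(len(feature_scale), dtype=bool)
    )
    arrays["loss_trace"] = loss_trace
    np.savez(path, meta=np.bytes_(json.dumps(meta).encode()), **arrays)


def _load_results(path, expected_kind):
    data = np.load(path, allow_pickle=False)
    meta = json.loads(bytes(data["meta"]).decode())
    if meta.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model container version: {meta}")
    if meta["kind"] != expected_kind:
        raise ValueError(
            f"model container holds a {meta['kind']!r} model, "
            f"expected {expected_kind!r}"
        )
    cfg = ModelConfig(**meta["config"])
    emb = KernelEmbedder(
        n_features=meta["embedder"]["D"], n_kernels=meta["embedder"]["K"],
        embed_dim=meta["embedder"]["E"], rotations=meta["embedder"]["R"],
        patch_radius=cfg.patch_radius,
    )
    for k in emb.params:
        emb.params[k] = data[f"emb_{k}"]
    head = {
        k[len("head_"):]: data[k] for k in data.files if k.startswith("head_")
    }
    payload = dict(
        config=cfg, embedder=emb, head=head,
        feature_scale=data["feature_scale"],
        feature_mask=data["feature_mask"], loss_trace=data["loss_trace"],
        seed=meta["seed"],
    )
    if expected_kind == "ligand":
        payload["classes"] = tuple(meta["classes"])
        payload["vertices_per_sample"] = meta["vertices_per_sample"]
    return payload


# --------------------------------------------------------------------------
# Pocket detection and ligand labelling
# --------------------------------------------------------------------------


@dataclass
class Pocket:
    """A candidate pocket: buried solvent probes and nearby surface vertices."""

    vertices: np.ndarray   # surface vertex ids
    probes: np.ndarray     # (n, 3) buried probe positions
    size: int              # probe-cluster size (ranking key)


def detect_pockets(
    s: ProteinStructure,
    mesh: SurfaceMesh,
    spacing: float = 1.0,
    probe: float = 1.4,
    n_rays: int = 30,
    ray_length: float = 8.0,
    burial_threshold: float = 0.5,
    min_probes: int = 4,
    vertex_cutoff: float = 3.0,
) -> list:
    """Geometric pocket candidates by the buried-probe heuristic.

    Solvent grid probes just outside the protein are scored by burial — the
    fraction of ``n_rays`` Fibonacci ray directions that hit the protein
    within ``ray_length`` Angstrom.  Probes with burial >= the threshold are
    clustered by grid connectivity; each cluster is mapped to the surface
    vertices within ``vertex_cutoff`` of its probes.  Pockets are returned
    sorted by cluster size (stable order).
    """
    heavy = s.heavy()
    coords = heavy.coord
    radii = heavy.vdw_radius
    tree = cKDTree(coords)

    lo = coords.min(axis=0) - 4.0
    hi = coords.max(axis=0) + 4.0
    axes = [np.arange(lo[d], hi[d] + spacing, spacing) for d in range(3)]
    shape = tuple(len(a) for a in axes)
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    # signed clearance: distance to nearest atom surface
    k = min(20, len(coords))
    d, j = tree.query(pts, k=k)
    if k == 1:
        d, j = d[:, None], j[:, None]
    clearance = (d - radii[j]).min(axis=1)
    shell = (clearance > probe) & (clearance < 4.0)
    shell_idx = np.where(shell)[0]
    if len(shell_idx) == 0:
        return []
    probes = pts[shell_idx]

    dirs = fibonacci_sphere(n_rays)
    steps = np.arange(1.0, ray_length + 0.5, 1.0)
    # sample points along every ray of every probe
    sample = (
        probes[:, None, None, :]
        + dirs[None, :, None, :] * steps[None, None, :, None]
    )
    flat = sample.reshape(-1, 3)
    ds, js = tree.query(flat, k=1)
    inside = (ds - radii[js]) < 0.0
    inside = inside.reshape(len(probes), n_rays, len(steps))
    hit = inside.any(axis=2)
    burial = hit.mean(axis=1)

    buried_mask = np.zeros(shape, dtype=bool).ravel()
    buried_mask[shell_idx[burial >= burial_threshold]] = True
    buried_mask = buried_mask.reshape(shape)
    lab, n_lab = ndimage.label(buried_mask, structure=np.ones((3, 3, 3)))
    if n_lab == 0:
        return []

    labels_flat = lab.ravel()
    vtree = cKDTree(mesh.vertices)
    pockets = []
    for li in range(1, n_lab + 1):
        sel = np.where(labels_flat == li)[0]
        if len(sel) < min_probes:
            continue
        cluster = pts[sel]
        near = vtree.query_ball_point(cluster, vertex_cutoff)
        verts = np.unique(np.concatenate([np.array(v, dtype=int)
                                          for v in near])) if any(
            len(v) for v in near) else np.array([], dtype=int)
        if len(verts) == 0:
            continue
        pockets.append(Pocket(vertices=verts, probes=cluster, size=len(sel)))
    pockets.sort(key=lambda p: -p.size)
    return pockets


def label_ligand_patches(
    patches, ligand_atoms, mesh: SurfaceMesh, cutoff: float = 3.0
) -> list:
    """Class of the nearest cofactor atom per patch center, within the cutoff.

    A patch whose center vertex lies less than ``cutoff`` (default 3.0
    Angstrom) from any ligand atom is labelled with that ligand's component
    code; otherwise ``None``.
    """
    if len(ligand_atoms) == 0:
        return [None] * len(patches)
    tree = cKDTree(ligand_atoms.coord)
    centers = np.array([mesh.vertices[p.center] for p in patches])
    d, j = tree.query(centers)
    out = []
    for dist, atom_idx in zip(d, j):
        out.append(
            str(ligand_atoms.res_name[atom_idx]) if dist < cutoff else None
        )
    return out
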