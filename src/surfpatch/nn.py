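"""Minimal neural-network machinery for the patch models.

The learnable operator is a soft polar-grid convolution: each of K Gaussian
kernels, parameterised by a radial center/width and an angular center/width,
produces a normalised weighting of the patch's vertices; kernel-weighted
feature sums are mapped linearly to an embedding and passed through a leaky
ReLU (slope 0.1 on the negative side, so desk-scale full-batch training can
never strand the whole layer in a dead zero-gradient state).
Because the angular origin of a patch is arbitrary, the embedding is computed
for R equally spaced angular offsets and max-pooled elementwise, which makes
it invariant to shifting every theta by a whole offset step.

Everything is plain numpy with hand-derived gradients (the models are small);
gradient correctness is established by finite-difference tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PatchBatch", "KernelEmbedder", "Adam", "relu", "leaky_relu",
           "leaky_relu_grad", "sigmoid", "softmax", "pack_patches"]


def relu(x):
    return np.maximum(x, 0.0)


LEAK = 0.1


def leaky_relu(x):
    return np.where(x > 0, x, LEAK * x)


def leaky_relu_grad(x):
    return np.where(x > 0, 1.0, LEAK)


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x, axis=-1):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _wrap_angle(x):
    """Wrap to (-pi, pi]."""
    return np.mod(x + np.pi, 2.0 * np.pi) - np.pi


@dataclass
class PatchBatch:
    """Padded batch of patches: rho/theta/mask (B, V), features (B, V, D)."""

    rho: np.ndarray
    theta: np.ndarray
    mask: np.ndarray
    features: np.ndarray

    @property
    def size(self) -> int:
        return self.rho.shape[0]


def pack_patches(patches, feature_scale=None, max_vertices: int = 64,
                 feature_matrix=None) -> PatchBatch:
    """Pad a list of :class:`~surfpatch.patches.Patch` into a batch.

    Patches larger than ``max_vertices`` are thinned deterministically by
    taking evenly spaced members in rho order (the center is always kept);
    feature rows are divided by ``feature_scale`` when given.  Feature rows
    come from each patch's own ``features`` or, more economically, are
    gathered from a shared per-vertex ``feature_matrix`` after thinning.
    """
    B = len(patches)
    V = min(max(len(p) for p in patches), max_vertices)
    if feature_matrix is not None:
        D = feature_matrix.shape[1]
    else:
        D = patches[0].features.shape[1]
    rho = np.zeros((B, V))
    theta = np.zeros((B, V))
    mask = np.zeros((B, V))
    feats = np.zeros((B, V, D))
    for b, p in enumerate(patches):
        idx = np.arange(len(p))
        if len(p) > V:
            order = np.argsort(p.rho, kind="stable")
            take = order[np.unique(np.linspace(0, len(p) - 1, V).astype(int))]
            idx = np.sort(take)
            if 0 not in idx:  # members[0] is the center
                idx[0] = 0
        n = len(idx)
        rho[b, :n] = p.rho[idx]
        theta[b, :n] = p.theta[idx]
        mask[b, :n] = 1.0
        if feature_matrix is not None:
            feats[b, :n] = feature_matrix[p.members[idx]]
        else:
            feats[b, :n] = p.features[idx]
    if feature_scale is not None:
        feats = feats / feature_scale
    return PatchBatch(rho=rho, theta=theta, mask=mask, features=feats)


class KernelEmbedder:
    """Gaussian-kernel patch embedding with rotation max-pooling.

    Parameters (all learnable): ``mu_rho``, ``mu_theta`` (kernel centers),
    ``log_sigma_rho``, ``log_sigma_theta`` (log widths), ``W`` ((K*D, E))
    and ``b`` ((E,)).
    """

    PARAM_NAMES = ("mu_rho", "mu_theta", "log_sigma_rho", "log_sigma_theta",
                   "W", "b")

    def __init__(self, n_features: int, n_kernels: int = 12,
                 embed_dim: int = 16, rotations: int = 8,
                 patch_radius: float = 12.0, rng=None):
        self.K = n_kernels
        self.D = n_features
        self.E = embed_dim
        self.R = rotations
        if rng is None:
            rng = np.random.default_rng(0)
        n_ang = min(4, n_kernels)
        n_rad = max(n_kernels // n_ang, 1)
        mu_rho, mu_th = [], []
        for i in range(n_kernels):
            ring, spoke = divmod(i, n_ang)
            mu_rho.append((ring % n_rad + 0.5) * patch_radius / n_rad)
            mu_th.append(2.0 * np.pi * spoke / n_ang)
        self.params = {
            "mu_rho": np.array(mu_rho),
            "mu_theta": np.array(mu_th),
            "log_sigma_rho": np.full(n_kernels,
                                     np.log(patch_radius / n_rad / 2.0)),
            "log_sigma_theta": np.full(n_kernels, np.log(np.pi / n_ang)),
            "W": rng.normal(0.0, np.sqrt(2.0 / (n_kernels * n_features)),
                            (n_kernels * n_features, embed_dim)),
            "b": np.zeros(embed_dim),
        }

    # -- forward -----------------------------------------------------------
    def _weights(self, batch: PatchBatch, offset: float):
        p = self.params
        sr2 = np.exp(2.0 * p["log_sigma_rho"])
        st2 = np.exp(2.0 * p["log_sigma_theta"])
        drho = batch.rho[..., None] - p["mu_rho"]
        dth = _wrap_angle(batch.theta[..., None] + offset - p["mu_theta"])
        a = -(drho ** 2) / (2.0 * sr2) - (dth ** 2) / (2.0 * st2)
        w = np.exp(a) * batch.mask[..., None]
        s = w.sum(axis=1)  # (B, K)
        bad = s < 1e-12
        if bad.any():
            # uniform fallback over real members
            nmem = batch.mask.sum(axis=1)[:, None, None]
            w = np.where(
                bad[:, None, :], batch.mask[..., None] / nmem, w
            )
            s = np.where(bad, 1.0, s)
        wn = w / s[:, None, :]
        return w, s, wn, drho, dth, sr2, st2

    def forward(self, batch: PatchBatch, want_cache: bool = False):
        """Embedding (B, E); optionally a cache for :meth:`backward`."""
        p = self.params
        B = batch.size
        z_all = np.empty((self.R, B, self.E))
        wn_all = [] if want_cache else None
        s_all = [] if want_cache else None
        for r in range(self.R):
            off = 2.0 * np.pi * r / self.R
            w, s, wn, *_ = self._weights(batch, off)
            G = np.matmul(wn.transpose(0, 2, 1), batch.features)  # (B, K, D)
            z_all[r] = G.reshape(B, -1) @ p["W"] + p["b"]
            if want_cache:
                wn_all.append(wn)
                s_all.append(s)
        h_all = leaky_relu(z_all)
        amax = h_all.argmax(axis=0)  # (B, E)
        h = np.take_along_axis(h_all, amax[None], axis=0)[0]
        if not want_cache:
            return h
        cache = {"batch": batch, "z_all": z_all, "amax": amax,
                 "wn_all": wn_all, "s_all": s_all}
        return h, cache

    # -- backward ----------------------------------------------------------
    def backward(self, dh: np.ndarray, cache) -> dict:
        """Gradients of a scalar loss w.r.t. all parameters, given dL/dh."""
        p = self.params
        batch = cache["batch"]
        B = batch.size
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        for r in range(self.R):
            sel = cache["amax"] == r  # (B, E)
            if not sel.any():
                continue
            z = cache["z_all"][r]
            dz = dh * sel * leaky_relu_grad(z)
            wn = cache["wn_all"][r]
            s = cache["s_all"][r]
            G = np.matmul(wn.transpose(0, 2, 1), batch.features)
            grads["W"] += G.reshape(B, -1).T @ dz
            grads["b"] += dz.sum(axis=0)
            dG = (dz @ p["W"].T).reshape(B, self.K, self.D)
            dwn = np.matmul(batch.features, dG.transpose(0, 2, 1))  # (B,V,K)
            # through the per-kernel normalisation wn = w / s
            inner = np.einsum("bvk,bvk->bk", dwn, wn)
            dw = (dwn - inner[:, None, :]) / s[:, None, :]
            w = wn * s[:, None, :]
            da = dw * w
            off = 2.0 * np.pi * r / self.R
            _, _, _, drho, dth, sr2, st2 = self._weights(batch, off)
            grads["mu_rho"] += np.einsum("bvk,bvk->k", da, drho / sr2)
            grads["log_sigma_rho"] += np.einsum(
                "bvk,bvk->k", da, drho ** 2 / sr2
            )
            grads["mu_theta"] += np.einsum("bvk,bvk->k", da, dth / st2)
            grads["log_sigma_theta"] += np.einsum(
                "bvk,bvk->k", da, dth ** 2 / st2
            )
        return grads


class Adam:
    """Adam optimizer over a dict-of-arrays parameter set."""

    def __init__(self, params: dict, lr: float = 0.01, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
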