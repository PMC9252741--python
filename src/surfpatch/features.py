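"""Per-vertex surface features and per-residue pharmacophore distance signatures.

Geometric features (shape index, curvedness) come from principal curvatures
estimated by quadric fitting over each vertex's 2-ring.  Chemical features are
simple surface proxies: Kyte-Doolittle hydropathy of the underlying residue, a
Coulomb potential with distance-dependent dielectric from template charges on
ionisable groups, and a directional hydrogen-bond propensity.

The distance signature of a residue is a cumulative histogram of pharmacophore
class *pairs* over increasing distance thresholds: for each unordered pair of
the six non-neutral classes, the number of heavy-atom pairs (one atom inside a
neighbourhood sphere around the residue, the partner anywhere) whose distance
is below each bin edge.  Surface vertices inherit their residue's signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
from scipy.spatial import cKDTree

from .structure import ProteinStructure, SIGNATURE_CLASSES
from .surface import SurfaceMesh

__all__ = [
    "VertexFeatures",
    "GraphSignature",
    "shape_index",
    "chemical_features",
    "graph_signature",
    "compute_vertex_features",
    "KYTE_DOOLITTLE",
    "SIGNATURE_PAIRS",
    "DEFAULT_BINS",
]

KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

#: The 21 unordered pairs of signature classes, canonical order.
SIGNATURE_PAIRS = tuple(combinations_with_replacement(SIGNATURE_CLASSES, 2))

#: Default distance-bin edges for signatures: 2, 4, ..., 30 Angstrom.
DEFAULT_BINS = tuple(float(x) for x in range(2, 31, 2))

# Formal-charge templates on ionisable side-chain groups, spread over the
# terminal atoms of each group.
_CHARGE_TEMPLATES = {
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5, ("ARG", "NH2"): 0.5,
}


@dataclass
class VertexFeatures:
    """Per-vertex feature arrays; ``matrix`` stacks them with the signature."""

    shape_index: np.ndarray
    curvedness: np.ndarray
    hydropathy: np.ndarray
    electrostatic: np.ndarray
    hbond: np.ndarray
    signature: np.ndarray = None  # (n_vertices, n_signature_cols), optional

    base_names = ("shape_index", "curvedness", "hydropathy", "electrostatic", "hbond")

    @property
    def matrix(self) -> np.ndarray:
        cols = [getattr(self, n) for n in self.base_names]
        m = np.column_stack(cols)
        if self.signature is not None:
            m = np.hstack([m, self.signature])
        return m

    def to_tsv(self, path: str, mesh: SurfaceMesh) -> None:
        import pandas as pd

        df = pd.DataFrame(mesh.vertices, columns=["x", "y", "z"])
        df.insert(0, "vertex", np.arange(len(df)))
        for n in self.base_names:
            df[n] = getattr(self, n)
        if self.signature is not None:
            sig = pd.DataFrame(
                self.signature,
                columns=[f"sig_{j}" for j in range(self.signature.shape[1])],
            )
            df = pd.concat([df, sig], axis=1)
        df.to_csv(path, sep="\t", index=False)


@dataclass
class GraphSignature:
    """Per-residue cumulative pharmacophore-pair distance distributions.

    ``matrix`` has shape (n_residues, 21, n_bins); entry [r, p, b] counts
    heavy-atom pairs of class pair ``SIGNATURE_PAIRS[p]`` at distance <= bin
    edge ``bins[b]``, with at least one atom inside the residue's
    neighbourhood sphere.
    """

    residue_keys: list
    matrix: np.ndarray
    bins: tuple = DEFAULT_BINS
    pairs: tuple = SIGNATURE_PAIRS

    def flat(self) -> np.ndarray:
        """(n_residues, 21 * n_bins) view for feature concatenation."""
        return self.matrix.reshape(len(self.residue_keys), -1)


# --------------------------------------------------------------------------
# Geometry
# --------------------------------------------------------------------------


def _vertex_adjacency(mesh: SurfaceMesh) -> list:
    adj = [set() for _ in range(mesh.n_vertices)]
    for a, b, c in mesh.triangles:
        adj[a].update((b, c))
        adj[b].update((a, c))
        adj[c].update((a, b))
    return [sorted(s) for s in adj]


def principal_curvatures(mesh: SurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex (k1, k2), k1 >= k2, by local quadric least squares.

    The 2-ring of each vertex is expressed in a frame with the vertex normal
    as z; a full quadric h(u, v) is fitted and the curvatures are the
    eigenvalues of its Hessian at the origin.  Vertices with too few
    neighbours get zero curvature.
    """
    adj = _vertex_adjacency(mesh)
    V, N = mesh.vertices, mesh.normals
    k1 = np.zeros(mesh.n_vertices)
    k2 = np.zeros(mesh.n_vertices)
    for i in range(mesh.n_vertices):
        ring = set(adj[i])
        for j in list(ring):
            ring.update(adj[j])
        ring.discard(i)
        nb = np.fromiter(ring, dtype=int)
        if len(nb) < 5:
            continue
        n = N[i]
        # tangent basis
        t1 = np.cross(n, [1.0, 0.0, 0.0])
        if np.linalg.norm(t1) < 1e-6:
            t1 = np.cross(n, [0.0, 1.0, 0.0])
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(n, t1)
        rel = V[nb] - V[i]
        u = rel @ t1
        v = rel @ t2
        h = rel @ n
        A = np.column_stack(
            [0.5 * u * u, u * v, 0.5 * v * v, u, v]
        )
        coef, *_ = np.linalg.lstsq(A, h, rcond=None)
        a, b, c = coef[0], coef[1], coef[2]
        # eigenvalues of [[a, b], [b, c]]
        mean = 0.5 * (a + c)
        det = np.sqrt(max((0.5 * (a - c)) ** 2 + b * b, 0.0))
        k1[i], k2[i] = mean + det, mean - det
    return k1, k2


def shape_index(mesh: SurfaceMesh) -> np.ndarray:
    """Shape index in [-1, 1]: +/-1 umbilic, +/-0.5 cylindrical, 0 saddle."""
    k1, k2 = principal_curvatures(mesh)
    si = np.zeros(mesh.n_vertices)
    diff = k1 - k2
    umbilic = diff < 1e-9
    si[~umbilic] = (2.0 / np.pi) * np.arctan(
        (k1[~umbilic] + k2[~umbilic]) / diff[~umbilic]
    )
    si[umbilic] = np.sign(k1[umbilic] + k2[umbilic])
    return np.clip(si, -1.0, 1.0)


def curvedness(mesh: SurfaceMesh) -> np.ndarray:
    k1, k2 = principal_curvatures(mesh)
    return np.sqrt(0.5 * (k1 * k1 + k2 * k2))


# --------------------------------------------------------------------------
# Chemistry
# --------------------------------------------------------------------------


def chemical_features(
    mesh: SurfaceMesh,
    s: ProteinStructure,
    hbond_cutoff: float = 3.5,
    elec_scale: float = 20.0,
) -> dict:
    """Hydropathy, electrostatic and H-bond features per mesh vertex.

    hydropathy: Kyte-Doolittle value of the vertex's residue scaled by 1/4.5.
    electrostatic: Coulomb potential from template charges with a
    distance-dependent dielectric (eps = 4d), tanh-squashed to [-1, 1].
    hbond: sum over donor (+) and acceptor (-) atoms within ``hbond_cutoff``
    of cos(angle) between the group axis and the direction to the vertex,
    clipped to [-1, 1].
    """
    if not s.is_typed:
        raise ValueError("structure must be typed")
    heavy = s.heavy()
    names = s.residue_names()

    kd = np.array(
        [KYTE_DOOLITTLE.get(nm, 0.0) / 4.5 for nm in names]
    )
    hydropathy = kd[mesh.vertex_residue]

    # electrostatics
    charges, charge_pos = [], []
    for i in range(len(heavy)):
        q = _CHARGE_TEMPLATES.get(
            (str(heavy.res_name[i]), str(heavy.atom_name[i]))
        )
        if q:
            charges.append(q)
            charge_pos.append(heavy.coord[i])
    elec = np.zeros(mesh.n_vertices)
    if charges:
        q = np.array(charges)
        cp = np.array(charge_pos)
        d = np.linalg.norm(
            mesh.vertices[:, None, :] - cp[None, :, :], axis=2
        )
        d = np.maximum(d, 1.0)
        elec = np.tanh(elec_scale * (q[None, :] / (4.0 * d * d)).sum(axis=1))

    # hydrogen-bond propensity
    pharm = heavy.pharmacophore
    da_idx = np.where((pharm == "donor") | (pharm == "acceptor"))[0]
    hbond = np.zeros(mesh.n_vertices)
    if len(da_idx):
        coords = heavy.coord
        tree = cKDTree(coords)
        # group axis: from the nearest bonded heavy atom toward the d/a atom
        axes = np.zeros((len(da_idx), 3))
        for k, ai in enumerate(da_idx):
            nb = tree.query_ball_point(coords[ai], 1.9)
            nb = [j for j in nb if j != ai]
            if nb:
                anchor = coords[nb].mean(axis=0)
                ax = coords[ai] - anchor
                nrm = np.linalg.norm(ax)
                if nrm > 1e-9:
                    axes[k] = ax / nrm
        vtree = cKDTree(mesh.vertices)
        for k, ai in enumerate(da_idx):
            sign = 1.0 if pharm[ai] == "donor" else -1.0
            near = vtree.query_ball_point(coords[ai], hbond_cutoff)
            if not near:
                continue
            rel = mesh.vertices[near] - coords[ai]
            nrm = np.linalg.norm(rel, axis=1)
            ok = nrm > 1e-9
            cosang = np.zeros(len(near))
            cosang[ok] = (rel[ok] @ axes[k]) / nrm[ok]
            hbond[near] += sign * np.maximum(cosang, 0.0)
    hbond = np.clip(hbond, -1.0, 1.0)

    return {"hydropathy": hydropathy, "electrostatic": elec, "hbond": hbond}


# --------------------------------------------------------------------------
# Distance signatures
# --------------------------------------------------------------------------


def graph_signature(
    s: ProteinStructure,
    bins: tuple = DEFAULT_BINS,
    neighborhood: float = 30.0,
) -> GraphSignature:
    """Cumulative pharmacophore-pair distance signatures per residue.

    For each residue, heavy atoms within ``neighborhood`` of its C-alpha (or
    heavy-atom centroid when C-alpha is absent) are paired with every heavy
    atom of the structure; each unordered pair with both atoms in a
    non-neutral class is counted once per distance bin it fits under.
    """
    if not s.is_typed:
        raise ValueError("structure must be typed")
    heavy = s.heavy()
    coords = heavy.coord
    pharm = heavy.pharmacophore
    class_idx = {c: i for i, c in enumerate(SIGNATURE_CLASSES)}
    pair_idx = {p: i for i, p in enumerate(SIGNATURE_PAIRS)}
    # atoms that participate in signatures
    sig_mask = np.isin(pharm, SIGNATURE_CLASSES)
    sig_atoms = np.where(sig_mask)[0]
    sig_class = np.array([class_idx[c] for c in pharm[sig_atoms]])

    keys = s.residue_keys()
    res_index = s.atom_residue_index()[s.atoms.element != "H"]
    bins_arr = np.asarray(bins, dtype=float)
    n_bins = len(bins_arr)
    out = np.zeros((len(keys), len(SIGNATURE_PAIRS), n_bins))
    tree = cKDTree(coords[sig_atoms])

    for r in range(len(keys)):
        atoms_r = np.where(res_index == r)[0]
        ca = atoms_r[heavy.atom_name[atoms_r] == "CA"]
        center = coords[ca[0]] if len(ca) else coords[atoms_r].mean(axis=0)
        in_sphere = np.array(
            tree.query_ball_point(center, neighborhood), dtype=int
        )
        if len(in_sphere) == 0:
            continue
        # pairs (i in sphere, j anywhere), unordered, counted once
        sphere_set = np.zeros(len(sig_atoms), dtype=bool)
        sphere_set[in_sphere] = True
        d = np.linalg.norm(
            coords[sig_atoms[in_sphere]][:, None, :]
            - coords[sig_atoms][None, :, :],
            axis=2,
        )
        ci = sig_class[in_sphere]
        cj = sig_class
        for a_local in range(len(in_sphere)):
            i_global = in_sphere[a_local]
            # avoid double counting pairs with both endpoints in the sphere
            dup = sphere_set & (np.arange(len(sig_atoms)) < i_global)
            valid = ~dup
            valid[i_global] = False
            dij = d[a_local][valid]
            within = dij <= bins_arr[-1]
            dij = dij[within]
            cjv = cj[valid][within]
            if not len(dij):
                continue
            bin_pos = np.searchsorted(bins_arr, dij, side="left")
            for cjx, bp in zip(cjv, bin_pos):
                lo, hi = min(ci[a_local], cjx), max(ci[a_local], cjx)
                p = pair_idx[(SIGNATURE_CLASSES[lo], SIGNATURE_CLASSES[hi])]
                out[r, p, bp:] += 1.0
    return GraphSignature(residue_keys=keys, matrix=out, bins=tuple(bins_arr))


# --------------------------------------------------------------------------
# Assembly
# --------------------------------------------------------------------------


def compute_vertex_features(
    mesh: SurfaceMesh,
    s: ProteinStructure,
    signatures: GraphSignature | None = None,
) -> VertexFeatures:
    """Full per-vertex feature set; signatures are inherited from residues.

    Signature columns here are raw counts; normalisation (per-column max over
    a training set) is applied at model level.
    """
    chem = chemical_features(mesh, s)
    k1, k2 = principal_curvatures(mesh)
    diff = k1 - k2
    si = np.zeros(mesh.n_vertices)
    umb = diff < 1e-9
    si[~umb] = (2.0 / np.pi) * np.arctan((k1[~umb] + k2[~umb]) / diff[~umb])
    si[umb] = np.sign(k1[umb] + k2[umb])
    cv = np.sqrt(0.5 * (k1 * k1 + k2 * k2))
    sig = None
    if signatures is not None:
        sig = signatures.flat()[mesh.vertex_residue]
    return VertexFeatures(
        shape_index=np.clip(si, -1, 1),
        curvedness=cv,
        hydropathy=chem["hydropathy"],
        electrostatic=chem["electrostatic"],
        hbond=chem["hbond"],
        signature=sig,
    )
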