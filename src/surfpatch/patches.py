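"""Geodesic surface patches with radial/angular coordinates.

The surface is decomposed into overlapping patches: all vertices within a
geodesic radius (default 12 Angstrom) of a center vertex.  Geodesic distance
is the shortest path on the mesh edge graph (Dijkstra with Euclidean edge
weights) — an upper bound on the true polyhedral geodesic, adequate at patch
scale.  Each member also gets an angular coordinate: its projection onto the
center's tangent plane, measured counterclockwise (about the outward normal)
from the projection of the center's first incident edge.  The angular origin
is arbitrary per patch; rotation invariance is recovered downstream by
max-pooling over rotated kernel offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .surface import SurfaceMesh

__all__ = [
    "Patch",
    "edge_graph",
    "geodesic_distances",
    "angular_coordinates",
    "extract_patches",
    "DEFAULT_PATCH_RADIUS",
]

DEFAULT_PATCH_RADIUS = 12.0


@dataclass
class Patch:
    """A geodesic neighbourhood around a center vertex.

    ``members`` lists vertex ids (center first); ``rho`` the geodesic
    distances (rho[0] == 0) and ``theta`` the angular coordinates in
    [0, 2 pi) (theta[0] == 0 by convention).  ``features`` optionally holds
    the members' feature rows.
    """

    center: int
    members: np.ndarray
    rho: np.ndarray
    theta: np.ndarray
    features: np.ndarray = None

    def __len__(self) -> int:
        return len(self.members)


def edge_graph(mesh: SurfaceMesh):
    """Sparse symmetric vertex graph weighted by Euclidean edge length."""
    t = mesh.triangles
    i = np.concatenate([t[:, 0], t[:, 1], t[:, 2]])
    j = np.concatenate([t[:, 1], t[:, 2], t[:, 0]])
    w = np.linalg.norm(mesh.vertices[i] - mesh.vertices[j], axis=1)
    n = mesh.n_vertices
    g = coo_matrix((np.r_[w, w], (np.r_[i, j], np.r_[j, i])), shape=(n, n))
    # duplicate entries: keep the minimum edge weight
    g.sum_duplicates()
    # duplicates summed; rebuild with explicit min via csr max trick is
    # unnecessary because duplicate edges have identical weights
    cnt = coo_matrix(
        (np.ones(2 * len(w)), (np.r_[i, j], np.r_[j, i])), shape=(n, n)
    )
    cnt.sum_duplicates()
    g = g.tocsr()
    cnt = cnt.tocsr()
    g.data = g.data / cnt.data
    return g


def geodesic_distances(
    mesh: SurfaceMesh, centers, r_max: float = np.inf, graph=None
) -> np.ndarray:
    """Truncated single- or multi-source Dijkstra distances.

    Returns an array of shape (n_centers, n_vertices) (or (n_vertices,) for a
    scalar center); unreached vertices hold ``inf``.
    """
    if graph is None:
        graph = edge_graph(mesh)
    scalar = np.isscalar(centers)
    idx = [centers] if scalar else list(centers)
    d = dijkstra(graph, directed=False, indices=idx, limit=r_max)
    return d[0] if scalar else d


def _neighbors(mesh: SurfaceMesh, center: int) -> np.ndarray:
    nb_mask = (mesh.triangles == center).any(axis=1)
    nb = np.unique(mesh.triangles[nb_mask])
    return nb[nb != center]


def angular_coordinates(
    mesh: SurfaceMesh, center: int, members: np.ndarray, neighbors=None
) -> np.ndarray:
    """Tangent-plane angles of ``members`` about ``center``, in [0, 2 pi).

    The reference direction (theta = 0) is the tangent-plane projection of the
    center's first incident edge (lowest-index neighbour).
    """
    n = mesh.normals[center]
    if np.linalg.norm(n) < 1e-9:
        raise ValueError(f"degenerate normal at vertex {center}")
    nb = _neighbors(mesh, center) if neighbors is None else neighbors
    if len(nb) < 2:
        raise ValueError(f"vertex {center} has fewer than 2 neighbours")
    ref = mesh.vertices[nb[0]] - mesh.vertices[center]
    ref = ref - (ref @ n) * n
    nrm = np.linalg.norm(ref)
    if nrm < 1e-9:  # reference edge parallel to the normal; use the next one
        ref = mesh.vertices[nb[1]] - mesh.vertices[center]
        ref = ref - (ref @ n) * n
        nrm = np.linalg.norm(ref)
    ref /= nrm
    perp = np.cross(n, ref)

    rel = mesh.vertices[members] - mesh.vertices[center]
    x = rel @ ref
    y = rel @ perp
    theta = np.mod(np.arctan2(y, x), 2.0 * np.pi)
    theta[members == center] = 0.0
    return theta


def extract_patches(
    mesh: SurfaceMesh,
    features: np.ndarray | None = None,
    r_max: float = DEFAULT_PATCH_RADIUS,
    centers=None,
    graph=None,
) -> list:
    """One overlapping geodesic patch per requested center (default: all).

    ``features`` is an (n_vertices, d) matrix whose member rows are attached
    to each patch.
    """
    if centers is None:
        centers = np.arange(mesh.n_vertices)
    centers = np.asarray(centers, dtype=int)
    if graph is None:
        graph = edge_graph(mesh)
    d = geodesic_distances(mesh, centers, r_max=r_max, graph=graph)
    # csr indices are ascending, so indices[indptr[c]] is the lowest-index
    # neighbour of c — the per-patch angular reference
    csr = graph.tocsr()
    patches = []
    for row, c in zip(d, centers):
        members = np.where(np.isfinite(row))[0]
        # center first, then ascending vertex id
        members = np.r_[c, members[members != c]]
        rho = row[members]
        nb = csr.indices[csr.indptr[c]:csr.indptr[c + 1]]
        if len(members) > 1 and len(nb) >= 2:
            theta = angular_coordinates(mesh, c, members, neighbors=nb)
        else:
            theta = np.zeros(len(members))
        feat = features[members] if features is not None else None
        patches.append(
            Patch(center=int(c), members=members, rho=rho, theta=theta,
                  features=feat)
        )
    return patches
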