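"""Molecular surface meshes, solvent accessibility and interface definition.

The molecular surface is a smooth isosurface of a summed per-atom exponential
density, extracted by marching cubes; the iso-level is chosen so an isolated
atom yields a sphere of radius ``r_vdw + probe``.  This is an explicit
approximation to the solvent-excluded surface: atom spheres blend smoothly
instead of meeting in sharp reentrant arcs.

Solvent-accessible surface area (SASA) uses the Shrake-Rupley construction
with a deterministic Fibonacci point set.  Sphere points are laid out in a
structure-intrinsic frame (principal axes of the heavy-atom cloud), which
makes the computed areas exactly invariant under rigid motion of the input.

The interface of a complex is defined through the change in accessibility:
``dSASA = SASA_A + SASA_B - SASA_AB`` per residue, with a residue flagged as
interface when it loses more than a threshold area and was solvent-exposed in
its unbound protomer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .structure import ProteinStructure, ChainError, merge

__all__ = [
    "SurfaceMesh",
    "SasaTable",
    "InterfaceLabels",
    "compute_ses_mesh",
    "compute_sasa",
    "delta_sasa",
    "MAX_RESIDUE_SASA",
]

# Theoretical maximum per-residue SASA (Gly-X-Gly extended tripeptides),
# Tien et al. 2013 values, Angstrom^2.
MAX_RESIDUE_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
_DEFAULT_MAX_SASA = 200.0  # fallback for nonstandard residues


@dataclass
class SurfaceMesh:
    """Triangulated molecular surface with per-vertex provenance.

    ``vertex_atom`` maps each vertex to the index of its nearest heavy atom in
    the structure's polymer atom array; ``vertex_residue`` maps to the index of
    that atom's residue in ``residue_keys``.
    """

    vertices: np.ndarray          # (N, 3) Angstrom
    triangles: np.ndarray         # (M, 3) int
    normals: np.ndarray           # (N, 3) outward unit
    vertex_atom: np.ndarray       # (N,) int, heavy-atom index
    vertex_residue: np.ndarray    # (N,) int, residue index
    residue_keys: list = field(default_factory=list)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        cr = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        return 0.5 * np.linalg.norm(cr, axis=1)

    @property
    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def export(self, path: str) -> None:
        """Write the mesh to OFF/PLY/etc. (format from the file extension)."""
        import trimesh

        trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        ).export(path)


@dataclass
class SasaTable:
    """Per-residue solvent-accessible surface areas."""

    table: pd.DataFrame           # columns: chain_id, res_id, ins_code, sasa
    atom_sasa: np.ndarray         # per heavy atom, Angstrom^2
    probe_radius: float
    sample_count: int

    @property
    def total(self) -> float:
        return float(self.table["sasa"].sum())

    def residue_sasa(self) -> dict:
        return {
            (r.chain_id, r.res_id, r.ins_code): r.sasa
            for r in self.table.itertuples()
        }

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class InterfaceLabels:
    """Per-residue dSASA and interface flags for one protomer pair."""

    table: pd.DataFrame  # chain_id, res_id, ins_code, res_name, sasa_unbound,
                         # delta_sasa, rel_sasa, flag

    def flagged(self) -> set:
        sub = self.table[self.table["flag"]]
        return {
            (r.chain_id, r.res_id, r.ins_code) for r in sub.itertuples()
        }

    def vertex_flags(self, mesh: SurfaceMesh) -> np.ndarray:
        """Project residue flags onto mesh vertices via ``vertex_residue``."""
        flagged = self.flagged()
        res_flag = np.array(
            [k in flagged for k in mesh.residue_keys], dtype=bool
        )
        return res_flag[mesh.vertex_residue]

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Mesh construction
# --------------------------------------------------------------------------


def compute_ses_mesh(
    s: ProteinStructure,
    probe: float = 1.4,
    grid: float = 0.8,
    blend: float = 0.5,
) -> SurfaceMesh:
    """Triangulate the (approximate) solvent-excluded surface of a structure.

    The scalar field is ``sum_i exp((R_i - d_i) / blend)`` with
    ``R_i = r_vdw,i + probe``; the iso-level 1 surface of a single atom is the
    sphere of radius ``R_i`` exactly, and overlapping atoms blend smoothly on
    the length scale ``blend`` (Angstrom).

    Parameters
    ----------
    probe : solvent probe radius added to every atom radius.
    grid : marching-cubes voxel edge length; halving it roughly quadruples the
        vertex count.
    blend : smoothing length of the density; small values approach the union
        of spheres.
    """
    if not s.is_typed:
        raise ValueError("structure must be typed (run assign_typing first)")
    heavy = s.heavy()
    if len(heavy) == 0:
        raise ValueError("no heavy atoms")
    coords = heavy.coord
    radii = heavy.vdw_radius + probe
    cutoff = 7.0 * blend  # density contribution below exp(-7) ~ 1e-3

    margin = float(radii.max() + cutoff + 2 * grid)
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    shape = np.maximum(np.ceil((hi - lo) / grid).astype(int) + 1, 8)
    field_ = np.zeros(shape, dtype=np.float64)

    # accumulate each atom's density on its local sub-grid
    for c, R in zip(coords, radii):
        reach = R + cutoff
        i0 = np.maximum(np.floor((c - reach - lo) / grid).astype(int), 0)
        i1 = np.minimum(np.ceil((c + reach - lo) / grid).astype(int) + 1, shape)
        ax = [lo[d] + grid * np.arange(i0[d], i1[d]) for d in range(3)]
        dx = ax[0][:, None, None] - c[0]
        dy = ax[1][None, :, None] - c[1]
        dz = ax[2][None, None, :] - c[2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        field_[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] += np.exp(
            np.minimum((R - d) / blend, 30.0)
        )

    verts, faces, normals, _ = marching_cubes(
        field_, level=1.0, spacing=(grid, grid, grid)
    )
    verts = verts + lo

    # drop degenerate (zero-area) triangles, if any
    cr = np.cross(
        verts[faces[:, 1]] - verts[faces[:, 0]],
        verts[faces[:, 2]] - verts[faces[:, 0]],
    )
    faces = faces[np.linalg.norm(cr, axis=1) > 1e-12]
    used = np.unique(faces)
    remap = -np.ones(len(verts), dtype=int)
    remap[used] = np.arange(len(used))
    verts, normals, faces = verts[used], normals[used], remap[faces]

    # orient outward: the density decreases away from the atoms
    tree = cKDTree(coords)
    _, nearest = tree.query(verts)
    outward = verts - coords[nearest]
    if np.einsum("ij,ij->", normals, outward) < 0:
        normals = -normals
    normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)

    res_index = s.atom_residue_index()[s.atoms.element != "H"]
    return SurfaceMesh(
        vertices=verts,
        triangles=faces,
        normals=normals,
        vertex_atom=nearest,
        vertex_residue=res_index[nearest],
        residue_keys=s.residue_keys(),
    )


# --------------------------------------------------------------------------
# SASA
# --------------------------------------------------------------------------


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden-angle spiral)."""
    i = np.arange(n, dtype=np.float64)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def principal_frame(coords: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame aligned with the point cloud's principal axes.

    Deterministic sign convention (third-moment positive) makes the frame
    co-rotate with the structure, so quantities sampled in this frame are
    invariant under rigid motion.
    """
    if len(coords) < 3:
        return np.eye(3)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    v = v[:, ::-1]  # descending eigenvalue order
    for k in range(2):
        proj = centered @ v[:, k]
        m3 = (proj ** 3).sum()
        if m3 < 0 or (m3 == 0 and proj[np.argmax(np.abs(proj))] < 0):
            v[:, k] = -v[:, k]
    v[:, 2] = np.cross(v[:, 0], v[:, 1])
    return v


def compute_sasa(
    s: ProteinStructure,
    probe: float = 1.4,
    n_points: int = 960,
    frame: np.ndarray | None = None,
) -> SasaTable:
    """Shrake-Rupley SASA over heavy atoms.

    Each atom's expanded sphere (radius ``r_vdw + probe``) is sampled at
    ``n_points`` Fibonacci points; a point is exposed iff it lies outside every
    other atom's expanded sphere.  Atom SASA is the exposed fraction of
    ``4 pi (r + probe)^2``; residue SASA sums its atoms.

    ``frame`` fixes the orientation of the sample point set; by default the
    structure's own principal frame is used (rigid-motion invariant).  Passing
    a shared frame lets bound/unbound computations use identical samples.
    """
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    if not s.is_typed:
        raise ValueError("structure must be typed (run assign_typing first)")
    heavy = s.heavy()
    if len(heavy) == 0:
        raise ValueError("no heavy atoms")
    coords = heavy.coord.astype(np.float64)
    radii = heavy.vdw_radius + probe
    if frame is None:
        frame = principal_frame(coords)
    pts = fibonacci_sphere(n_points) @ frame.T

    tree = cKDTree(coords)
    rmax = radii.max()
    atom_sasa = np.empty(len(coords))
    for i in range(len(coords)):
        sphere = coords[i] + radii[i] * pts
        nb = tree.query_ball_point(coords[i], radii[i] + rmax)
        nb = [j for j in nb if j != i]
        exposed = np.ones(n_points, dtype=bool)
        if nb:
            nbc = coords[nb]
            nbr = radii[nb]
            d2 = ((sphere[:, None, :] - nbc[None, :, :]) ** 2).sum(axis=2)
            exposed = (d2 > (nbr ** 2)[None, :]).all(axis=1)
        atom_sasa[i] = 4.0 * np.pi * radii[i] ** 2 * exposed.mean()

    res_index = s.atom_residue_index()[s.atoms.element != "H"]
    keys = s.residue_keys()
    per_res = np.zeros(len(keys))
    np.add.at(per_res, res_index, atom_sasa)
    table = pd.DataFrame(
        {
            "chain_id": [k[0] for k in keys],
            "res_id": [k[1] for k in keys],
            "ins_code": [k[2] for k in keys],
            "sasa": per_res,
        }
    )
    return SasaTable(
        table=table, atom_sasa=atom_sasa, probe_radius=probe,
        sample_count=n_points,
    )


def delta_sasa(
    a: ProteinStructure,
    b: ProteinStructure,
    probe: float = 1.4,
    n_points: int = 4000,
    threshold: float = 1.0,
    surface_fraction: float = 0.05,
) -> InterfaceLabels:
    """Label interface residues of a protomer pair by buried surface area.

    Computes SASA of each protomer alone and of the merged complex (all three
    with the complex's sample-point frame, so burial is exactly monotone), then
    per residue ``dSASA = SASA_unbound - SASA_bound``.  A residue is flagged as
    interface iff ``dSASA > threshold`` (default 1.0 A^2) and its unbound
    relative SASA exceeds ``surface_fraction`` (default 5%) of the residue-type
    maximum.
    """
    complex_ = merge(a, b)  # raises ChainError on collision
    frame = principal_frame(complex_.heavy().coord)
    sasa_a = compute_sasa(a, probe, n_points, frame=frame)
    sasa_b = compute_sasa(b, probe, n_points, frame=frame)
    sasa_ab = compute_sasa(complex_, probe, n_points, frame=frame)

    bound = sasa_ab.residue_sasa()
    rows = []
    for part, tab in ((a, sasa_a), (b, sasa_b)):
        names = dict(zip(part.residue_keys(), part.residue_names()))
        for r in tab.table.itertuples():
            key = (r.chain_id, r.res_id, r.ins_code)
            unbound = r.sasa
            d = unbound - bound.get(key, 0.0)
            max_sasa = MAX_RESIDUE_SASA.get(names[key], _DEFAULT_MAX_SASA)
            rel = unbound / max_sasa
            rows.append(
                {
                    "chain_id": key[0],
                    "res_id": key[1],
                    "ins_code": key[2],
                    "res_name": names[key],
                    "sasa_unbound": unbound,
                    "delta_sasa": d,
                    "rel_sasa": rel,
                    "flag": bool(d > threshold and rel > surface_fraction),
                }
            )
    return InterfaceLabels(table=pd.DataFrame(rows))
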