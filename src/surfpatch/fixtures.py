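"""Deterministic synthetic structures for building and testing every stage.

No external structure download is ever needed: this module generates

* toy dimers — two idealised poly-alanine helices placed at van der Waals
  contact, with a planted interface truth (residues within 5 Angstrom
  inter-chain heavy-atom distance).  The planted 5 A contact rule is
  deliberately different from the buried-surface-area rule used for labelling,
  so agreement between the two is a genuine cross-check.
* toy pockets — a concave shell of residue stubs around a placed cofactor
  ligand, with a class-specific pharmacophore composition of the lining so a
  small classifier has learnable chemical signal.
* analytic test meshes — sphere, cylinder, saddle and strip with known
  curvature and geodesic ground truth.

All fixtures are bit-reproducible from their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import biotite.structure as struc

from .structure import ProteinStructure, assign_typing, COFACTOR_CODES
from .surface import SurfaceMesh

__all__ = [
    "ToyDimer",
    "make_toy_dimer",
    "make_toy_pocket",
    "make_test_meshes",
    "dimer_corpus",
    "pocket_corpus",
    "build_helix",
]

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
         "CA-CB": 1.521}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7,
          "CA-C-O": 120.8, "N-CA-CB": 110.4}
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0  # ideal alpha helix


def _place(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF atom placement: bond from c, angle at c, dihedral about b-c."""
    ang = np.deg2rad(angle_deg)
    chi = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-bond * np.cos(ang), bond * np.sin(ang) * np.cos(chi),
         bond * np.sin(ang) * np.sin(chi)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_helix(n_res: int) -> np.ndarray:
    """Ideal poly-alanine alpha helix (phi=-57, psi=-47), axis along z.

    Returns coordinates of shape (n_res, 5, 3) for atoms (N, CA, C, O, CB),
    centered at the origin.
    """
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    coords = np.zeros((n_res, 5, 3))
    # seed residue
    coords[0, 0] = [0.0, 0.0, 0.0]                       # N
    coords[0, 1] = [_BOND["N-CA"], 0.0, 0.0]             # CA
    ang = np.deg2rad(180.0 - _ANGLE["N-CA-C"])
    coords[0, 2] = coords[0, 1] + _BOND["CA-C"] * np.array(
        [np.cos(ang), np.sin(ang), 0.0]
    )                                                    # C
    for i in range(n_res):
        N, CA, C = coords[i, 0], coords[i, 1], coords[i, 2]
        if i + 1 < n_res:
            Nn = _place(N, CA, C, _BOND["C-N"], _ANGLE["CA-C-N"], _PSI)
            coords[i + 1, 0] = Nn
            coords[i + 1, 1] = _place(
                CA, C, Nn, _BOND["N-CA"], _ANGLE["C-N-CA"], _OMEGA
            )
            coords[i + 1, 2] = _place(
                C, Nn, coords[i + 1, 1], _BOND["CA-C"], _ANGLE["N-CA-C"], _PHI
            )
            # carbonyl O opposite the next N
            coords[i, 3] = _place(
                N, CA, C, _BOND["C-O"], _ANGLE["CA-C-O"], _PSI + 180.0
            )
        else:
            coords[i, 3] = _place(
                N, CA, C, _BOND["C-O"], _ANGLE["CA-C-O"], _PSI + 180.0
            )
        coords[i, 4] = _place(
            C, N, CA, _BOND["CA-CB"], _ANGLE["N-CA-CB"], -122.6
        )
    # align principal CA axis with z, center at origin
    ca = coords[:, 1, :]
    center = ca.mean(axis=0)
    flat = coords.reshape(-1, 3) - center
    ca0 = ca - center
    _, _, vt = np.linalg.svd(ca0)
    axis = vt[0]
    if axis[2] < 0 or (axis[2] == 0 and ca0[-1] @ axis < 0):
        axis = -axis
    # rotation taking `axis` to z
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    if s < 1e-12:
        rot = np.eye(3)
    else:
        c = axis @ z
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)
    return (flat @ rot.T).reshape(n_res, 5, 3)


_BB_NAMES = ("N", "CA", "C", "O", "CB")
_BB_ELEMENTS = ("N", "C", "C", "O", "C")


def _make_atom_array(
    names, elements, coords, chain_id, res_ids, res_names, hetero=False
) -> struc.AtomArray:
    n = len(names)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = np.full(n, chain_id, dtype="U4")
    arr.res_id = np.asarray(res_ids, dtype=int)
    arr.ins_code = np.full(n, "", dtype="U1")
    arr.res_name = np.asarray(res_names, dtype="U5")
    arr.atom_name = np.asarray(names, dtype="U6")
    arr.element = np.asarray(elements, dtype="U2")
    arr.hetero = np.full(n, hetero, dtype=bool)
    arr.set_annotation("b_factor", np.zeros(n))
    arr.set_annotation("occupancy", np.ones(n))
    arr.set_annotation("atom_id", np.arange(1, n + 1))
    return arr


def _helix_structure(coords, chain_id, residue_names=None) -> ProteinStructure:
    n_res = coords.shape[0]
    if residue_names is None:
        residue_names = ["ALA"] * n_res
    names, elements, res_ids, res_names, xyz = [], [], [], [], []
    for i in range(n_res):
        for k in range(5):
            names.append(_BB_NAMES[k])
            elements.append(_BB_ELEMENTS[k])
            res_ids.append(i + 1)
            res_names.append(residue_names[i])
            xyz.append(coords[i, k])
    arr = _make_atom_array(names, elements, xyz, chain_id, res_ids, res_names)
    return ProteinStructure(atoms=arr)


@dataclass
class ToyDimer:
    """A synthetic two-helix complex with planted contact truth."""

    a: ProteinStructure
    b: ProteinStructure
    interface: set  # of (chain_id, res_id, ins_code)
    seed: int


def make_toy_dimer(
    n_res: int = 16,
    contact_width: int = 10,
    seed: int = 0,
    contact_gap: float = 3.6,
    jitter: float = 0.05,
) -> ToyDimer:
    """Two ideal helices at van der Waals contact, with planted interface.

    Chain B is chain A rotated 180 degrees about the inter-chain axis and
    offset so the closest inter-chain heavy-atom distance equals
    ``contact_gap``; ``contact_width`` controls the axial overlap (number of
    residues in register).  ``contact_width = 0`` separates the chains by
    50 Angstrom.  Truth: residues with any inter-chain heavy-atom distance
    below 5 Angstrom.

    Residue identities mimic the chemistry of real interfaces: residues whose
    side chain faces the partner are hydrophobic (LEU), the solvent-facing
    rest polar (LYS).  The backbone geometry is the ideal helix either way;
    only names (hence hydropathy and typing) differ, giving the site model a
    learnable chemical asymmetry like the hydrophobic patches that mark real
    protein-protein interfaces.
    """
    if n_res < 6:
        raise ValueError("n_res must be >= 6")
    rng = np.random.default_rng(seed)
    base = build_helix(n_res).reshape(-1, 3)
    base = base + rng.normal(0.0, jitter, base.shape)

    rot180 = np.diag([-1.0, -1.0, 1.0])
    other = base @ rot180.T
    if contact_width <= 0:
        other = other + np.array([50.0, 0.0, 0.0])
    else:
        shift_z = (n_res - min(contact_width, n_res)) * 1.5
        other = other + np.array([0.0, 0.0, shift_z])
        # binary search the x-offset giving the requested closest approach
        lo, hi = 0.0, 30.0
        for _ in range(48):
            mid = 0.5 * (lo + hi)
            dmin = np.min(
                np.linalg.norm(
                    base[:, None, :]
                    - (other + np.array([mid, 0.0, 0.0]))[None, :, :],
                    axis=2,
                )
            )
            if dmin < contact_gap:
                lo = mid
            else:
                hi = mid
        other = other + np.array([0.5 * (lo + hi), 0.0, 0.0])

    # random global pose (same transform for both chains: contact preserved)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    shift = rng.uniform(-5.0, 5.0, 3)
    base = base @ rot.T + shift
    other = other @ rot.T + shift

    n_at = n_res * 5
    base_r = base.reshape(n_res, 5, 3)
    other_r = other.reshape(n_res, 5, 3)

    def face_names(own, partner):
        # hydrophobic identity only where the side chain faces the partner
        # AND the residue is near the contact band — mimicking the compact
        # hydrophobic patches that mark real interfaces
        toward = partner.reshape(-1, 3).mean(0) - own.reshape(-1, 3).mean(0)
        toward /= np.linalg.norm(toward)
        cb_dir = own[:, 4] - own[:, 1]  # CA -> CB
        facing = (cb_dir @ toward) > 0
        dmin = np.array([
            np.linalg.norm(
                own[i].reshape(-1, 1, 3) - partner.reshape(1, -1, 3), axis=2
            ).min()
            for i in range(own.shape[0])
        ])
        return [
            "LEU" if (f and d < 6.5) else "LYS"
            for f, d in zip(facing, dmin)
        ]

    a = assign_typing(
        _helix_structure(base_r, "A", face_names(base_r, other_r))
    )
    b = assign_typing(
        _helix_structure(other_r, "B", face_names(other_r, base_r))
    )

    d = np.linalg.norm(base[:, None, :] - other[None, :, :], axis=2)
    truth = set()
    res_of = np.repeat(np.arange(1, n_res + 1), 5)
    close = np.argwhere(d < 5.0)
    for ia, ib in close:
        truth.add(("A", int(res_of[ia]), ""))
        truth.add(("B", int(res_of[ib]), ""))
    assert n_at == len(base)
    return ToyDimer(a=a, b=b, interface=truth, seed=seed)


# --------------------------------------------------------------------------
# Pockets
# --------------------------------------------------------------------------

# side-chain tip atoms per residue type: (atom_name, element, depth rank)
_SIDECHAINS = {
    "ALA": [("CB", "C")],
    "VAL": [("CB", "C")],
    "LEU": [("CB", "C"), ("CD1", "C")],
    "ILE": [("CB", "C"), ("CD1", "C")],
    "PHE": [("CB", "C"), ("CG", "C"), ("CZ", "C")],
    "TYR": [("CB", "C"), ("CG", "C"), ("OH", "O")],
    "TRP": [("CB", "C"), ("CG", "C"), ("CZ2", "C")],
    "MET": [("CB", "C"), ("SD", "S")],
    "SER": [("CB", "C"), ("OG", "O")],
    "THR": [("CB", "C"), ("OG1", "O")],
    "ASN": [("CB", "C"), ("OD1", "O"), ("ND2", "N")],
    "GLN": [("CB", "C"), ("OE1", "O"), ("NE2", "N")],
    "LYS": [("CB", "C"), ("NZ", "N")],
    "ARG": [("CB", "C"), ("NH1", "N"), ("NH2", "N")],
    "ASP": [("CB", "C"), ("OD1", "O"), ("OD2", "O")],
    "GLU": [("CB", "C"), ("OE1", "O"), ("OE2", "O")],
    "GLY": [],
}

# pocket-lining residue palettes: distinct pharmacophore composition per class
_POCKET_PALETTES = {
    "HEM": ["PHE", "LEU", "PHE", "ILE", "TRP", "LEU"],
    "ADP": ["LYS", "ARG", "GLY", "SER", "LYS", "THR"],
    "COA": ["ARG", "SER", "LEU", "THR", "LYS", "ALA"],
    "FAD": ["TYR", "GLY", "SER", "THR", "ASN", "GLY"],
    "NAD": ["ASN", "GLN", "GLY", "VAL", "SER", "ASP"],
    "NAP": ["LYS", "THR", "SER", "TYR", "ARG", "GLY"],
    "SAM": ["ASP", "MET", "GLU", "ASN", "ASP", "LEU"],
}


def _ring(n, radius, z=0.0, phase=0.0):
    ang = phase + 2.0 * np.pi * np.arange(n) / n
    return np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), np.full(n, z)]
    )


def _ligand_template(code: str):
    """Idealised cofactor template: (atom_names, elements, coords).

    Atom counts and element composition roughly follow the real compounds;
    geometry is schematic (rings and chains), adequate for distance-based
    labelling and surface placement.
    """
    if code == "HEM":
        coords = np.vstack(
            [np.zeros((1, 3)), _ring(4, 2.0), _ring(12, 3.3, phase=0.3)]
        )
        names = ["FE", "NA", "NB", "NC", "ND"] + [f"C{i}" for i in range(1, 13)]
        elements = ["FE"] + ["N"] * 4 + ["C"] * 12
    elif code == "ADP":
        ring = _ring(9, 1.9)  # adenine (schematic fused ring)
        sugar = _ring(5, 1.2, z=0.0) + np.array([3.4, 0.0, 0.3])
        tail = np.array(
            [[5.2, 0.4, 0.6], [6.3, -0.4, 0.9], [6.0, 1.5, 0.2],
             [7.5, 0.3, 1.4], [8.3, -0.7, 1.8], [8.1, 1.4, 1.2]]
        ) * 0.85
        coords = np.vstack([ring, sugar, tail])
        names = (["N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"]
                 + ["C1'", "C2'", "C3'", "C4'", "O4'"]
                 + ["PA", "O1A", "O2A", "PB", "O1B", "O2B"])
        elements = (["N", "C", "N", "C", "C", "C", "N", "C", "N"]
                    + ["C"] * 4 + ["O"] + ["P", "O", "O", "P", "O", "O"])
    elif code == "SAM":
        ring = _ring(9, 1.9)
        chain = np.array(
            [[3.2, 0.0, 0.4], [4.4, 0.5, 0.8], [5.5, -0.3, 1.0],
             [6.6, 0.4, 1.3], [7.4, -0.5, 1.6], [7.2, 1.5, 1.1]]
        ) * 0.8
        coords = np.vstack([ring, chain])
        names = (["N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"]
                 + ["SD", "CG", "CB", "CA", "N", "O"])
        elements = (["N", "C", "N", "C", "C", "C", "N", "C", "N"]
                    + ["S", "C", "C", "C", "N", "O"])
    elif code == "FAD":
        iso = np.vstack([_ring(6, 1.6, z=0.4), _ring(6, 1.6, z=-0.4,
                                                     phase=0.5)])
        tail = np.column_stack(
            [np.linspace(2.2, 6.5, 6), np.linspace(0, 1.2, 6),
             np.linspace(0.5, -0.5, 6)]
        )
        coords = np.vstack([iso, tail])
        names = ([f"C{i}" for i in range(1, 9)] + ["N1", "N3", "N5", "N10"]
                 + ["O2", "O4", "C1'", "C2'", "PA", "PB"])
        elements = ["C"] * 8 + ["N"] * 4 + ["O", "O", "C", "C", "P", "P"]
    elif code in ("NAD", "NAP"):
        nic = _ring(6, 1.5)
        ade = _ring(9, 1.8) + np.array([5.2, 0.6, 0.6])
        bridge = np.array(
            [[1.8, -0.8, 0.2], [2.8, 0.0, 0.4], [3.8, -0.6, 0.5],
             [2.3, 1.2, 0.1]]
        )
        coords = np.vstack([nic, bridge, ade])
        names = (["C2N", "C3N", "C4N", "C5N", "C6N", "N1N"]
                 + ["O7N", "PA", "PB", "O3"]
                 + ["N1A", "C2A", "N3A", "C4A", "C5A", "C6A", "N7A", "C8A",
                    "N9A"])
        elements = (["C"] * 5 + ["N"] + ["O", "P", "P", "O"]
                    + ["N", "C", "N", "C", "C", "C", "N", "C", "N"])
        if code == "NAP":
            coords = np.vstack([coords, [[4.6, -1.6, 0.9], [5.4, -2.2, 1.2]]])
            names = names + ["P2'", "O2X"]
            elements = elements + ["P", "O"]
    elif code == "COA":
        ade = _ring(9, 1.8)
        chain = np.column_stack(
            [np.linspace(2.4, 8.0, 8), np.sin(np.linspace(0, 3, 8)),
             np.linspace(0.2, 1.0, 8)]
        )
        coords = np.vstack([ade, chain])
        names = (["N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"]
                 + ["PA", "PB", "C1P", "C2P", "N4P", "O5P", "C6P", "S1P"])
        elements = (["N", "C", "N", "C", "C", "C", "N", "C", "N"]
                    + ["P", "P", "C", "C", "N", "O", "C", "S"])
    else:
        raise ValueError(
            f"unknown ligand class {code!r}; expected one of {COFACTOR_CODES}"
        )
    coords = coords - coords.mean(axis=0)
    # normalise extent so the template fills the pocket cavity
    scale = 3.2 / max(np.linalg.norm(coords, axis=1).max(), 1e-9)
    coords = coords * scale
    return names, elements, coords


def make_toy_pocket(
    ligand_class: str,
    seed: int = 0,
    shell_radius: float = 9.0,
    n_shell: int = 48,
    opening: float = 0.45,
    jitter: float = 0.05,
):
    """A concave residue-stub shell around a placed cofactor ligand.

    The shell is a sphere of single-residue stubs with an opening toward +z;
    side chains point inward so the pocket lining has the class-specific
    pharmacophore composition of ``_POCKET_PALETTES[ligand_class]``.  The
    ligand template sits in the cavity, guaranteed within 3 Angstrom of the
    lining surface.  Same seed, different class: identical backbone geometry,
    different lining chemistry.
    """
    if ligand_class not in COFACTOR_CODES:
        raise ValueError(
            f"unknown ligand class {ligand_class!r}; "
            f"expected one of {COFACTOR_CODES}"
        )
    i = np.arange(n_shell, dtype=float)
    z = 1.0 - (2 * i + 1.0) / n_shell
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    pts = np.column_stack(
        [np.sqrt(1 - z * z) * np.cos(phi), np.sqrt(1 - z * z) * np.sin(phi), z]
    )
    pts = pts[pts[:, 2] < opening]  # opening toward +z
    palette = _POCKET_PALETTES[ligand_class]

    names, elements, res_ids, res_names, xyz = [], [], [], [], []
    for k, u in enumerate(pts):
        # per-stub noise stream, backbone drawn before side chain, so the
        # backbone geometry is identical across ligand classes at equal seed
        stub_rng = np.random.default_rng([seed, k])
        res = palette[k % len(palette)]
        p = shell_radius * u
        inward = -u
        # tangent frame
        t1 = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(t1) < 1e-6:
            t1 = np.array([1.0, 0.0, 0.0])
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(u, t1)
        stub = [
            ("N", "N", p + 1.46 * t1),
            ("CA", "C", p),
            ("C", "C", p - 1.25 * t1 + 0.8 * t2),
            ("O", "O", p - 1.25 * t1 + 0.8 * t2 + 1.23 * u),
        ]
        side = _SIDECHAINS[res]
        for j, (an, el) in enumerate(side):
            off = 1.5 + 1.3 * j
            lateral = 0.5 * ((j % 2) * 2 - 1) * t1 if j > 0 else 0.0 * t1
            stub.append((an, el, p + off * inward + lateral))
        for an, el, c in stub:
            names.append(an)
            elements.append(el)
            res_ids.append(k + 1)
            res_names.append(res)
            xyz.append(c + stub_rng.normal(0.0, jitter, 3))
    xyz = np.array(xyz)

    lnames, lelements, lcoords = _ligand_template(ligand_class)
    lcoords = lcoords + np.array([0.0, 0.0, -1.0])  # sit toward pocket floor

    # one common random pose from a class-independent stream
    rng = np.random.default_rng([seed, 999983])
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, zz = q
    rot = np.array(
        [
            [1 - 2 * (y * y + zz * zz), 2 * (x * y - w * zz),
             2 * (x * zz + w * y)],
            [2 * (x * y + w * zz), 1 - 2 * (x * x + zz * zz),
             2 * (y * zz - w * x)],
            [2 * (x * zz - w * y), 2 * (y * zz + w * x),
             1 - 2 * (x * x + y * y)],
        ]
    )
    shift = rng.uniform(-3.0, 3.0, 3)
    xyz = xyz @ rot.T + shift
    lcoords = lcoords @ rot.T + shift

    protein = _make_atom_array(names, elements, xyz, "A", res_ids, res_names)
    lig = _make_atom_array(
        lnames, lelements, lcoords, "A",
        [900] * len(lnames), [ligand_class] * len(lnames), hetero=True,
    )
    return assign_typing(ProteinStructure(atoms=protein, ligand_atoms=lig))


# --------------------------------------------------------------------------
# Analytic meshes
# --------------------------------------------------------------------------


def _as_surface_mesh(vertices, faces, normals) -> SurfaceMesh:
    n = len(vertices)
    return SurfaceMesh(
        vertices=np.asarray(vertices, dtype=float),
        triangles=np.asarray(faces, dtype=int),
        normals=np.asarray(normals, dtype=float),
        vertex_atom=np.zeros(n, dtype=int),
        vertex_residue=np.zeros(n, dtype=int),
        residue_keys=[("A", 1, "")],
    )


def make_test_meshes() -> dict:
    """Analytic meshes with known ground truth.

    sphere: unit icosphere (|SI| = 1, geodesic antipode = pi).
    sphere5: radius-5 icosphere for curvature at protein-like scale.
    cylinder: radius 2, height 12, capped; side vertices have |SI| = 0.5.
    saddle: z = (x^2 - y^2)/2 height field; SI = 0 near the origin.
    strip: two-row triangulated band along x with unit spacing.
    """
    import trimesh

    out = {}
    for key, radius in (("sphere", 1.0), ("sphere5", 5.0)):
        m = trimesh.creation.icosphere(subdivisions=3, radius=radius)
        v = np.asarray(m.vertices)
        normals = v / np.linalg.norm(v, axis=1, keepdims=True)
        out[key] = _as_surface_mesh(v, np.asarray(m.faces), normals)

    n_t, n_z = 48, 13
    ang = 2.0 * np.pi * np.arange(n_t) / n_t
    zs = np.linspace(-6.0, 6.0, n_z)
    cv = np.array(
        [[2.0 * np.cos(a), 2.0 * np.sin(a), zv] for zv in zs for a in ang]
    )
    cf = []
    for iz in range(n_z - 1):
        for it in range(n_t):
            a = iz * n_t + it
            b = iz * n_t + (it + 1) % n_t
            cf.append([a, b, a + n_t])
            cf.append([b, b + n_t, a + n_t])
    cn = cv.copy()
    cn[:, 2] = 0.0
    cn /= np.linalg.norm(cn, axis=1, keepdims=True)
    out["cylinder"] = _as_surface_mesh(cv, np.array(cf), cn)

    n = 21
    x = np.linspace(-2.0, 2.0, n)
    xx, yy = np.meshgrid(x, x, indexing="ij")
    zz = 0.5 * (xx ** 2 - yy ** 2)
    verts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n])
            faces.append([a + 1, a + n + 1, a + n])
    # analytic normal of the height field, oriented +z
    gx, gy = xx.ravel(), -yy.ravel()
    normals = np.column_stack([-gx, -gy, np.ones(n * n)])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    out["saddle"] = _as_surface_mesh(verts, np.array(faces), normals)

    m = 30
    verts = np.array(
        [[i, 0.0, 0.0] for i in range(m)] + [[i, 1.0, 0.0] for i in range(m)]
    )
    faces = []
    for i in range(m - 1):
        faces.append([i, i + 1, m + i])
        faces.append([i + 1, m + i + 1, m + i])
    normals = np.tile([0.0, 0.0, 1.0], (2 * m, 1))
    out["strip"] = _as_surface_mesh(verts, np.array(faces), normals)
    return out


# --------------------------------------------------------------------------
# Corpora
# --------------------------------------------------------------------------


# (n_res, contact_width) pairs where the axial phase of the two helices puts
# the 5 A contact band and the buried-surface band in register
_DIMER_GEOMETRIES = ((16, 10), (16, 11), (17, 8), (17, 11), (18, 9))


def dimer_corpus(n: int = 25, base_seed: int = 0) -> list:
    """Deterministic list of toy dimers with varied size and contact width."""
    out = []
    for i in range(n):
        n_res, width = _DIMER_GEOMETRIES[i % len(_DIMER_GEOMETRIES)]
        out.append(
            make_toy_dimer(
                n_res=n_res, contact_width=width, seed=base_seed * 1000 + i
            )
        )
    return out


def pocket_corpus(classes, n_per_class: int, base_seed: int = 0) -> list:
    """Deterministic list of (structure, class) pocket fixtures."""
    out = []
    for ci, cls in enumerate(classes):
        for i in range(n_per_class):
            out.append(
                (make_toy_pocket(cls, seed=base_seed * 1000 + ci * 97 + i),
                 cls)
            )
    return out
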