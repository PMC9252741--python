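"""Protein structure parsing, chemical typing, and annotated PDB output.

Structures are held as :class:`biotite.structure.AtomArray` objects wrapped in a
:class:`ProteinStructure`, which separates polymer atoms from recognised cofactor
ligands (ADP, CoA, FAD, heme, NAD, NADP, SAM).  Chemical typing attaches a van der
Waals radius and a coarse pharmacophore class (hydrophobic, aromatic, H-bond
donor/acceptor, positive, negative, neutral) to every atom; all downstream surface
and feature computations read those annotations.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomRecord",
    "ProteinStructure",
    "ResidueScore",
    "ParseError",
    "ChainError",
    "TypingError",
    "parse_pdb",
    "select_chains",
    "assign_typing",
    "write_annotated_pdb",
    "COFACTOR_CODES",
    "PHARMACOPHORE_CLASSES",
    "SIGNATURE_CLASSES",
]

#: Chemical component codes of the seven recognised cofactors.
COFACTOR_CODES = ("ADP", "COA", "FAD", "HEM", "NAD", "NAP", "SAM")

#: All pharmacophore classes, in canonical order.
PHARMACOPHORE_CLASSES = (
    "hydrophobic",
    "aromatic",
    "donor",
    "acceptor",
    "positive",
    "negative",
    "neutral",
)

#: The six classes that enter distance signatures (neutral excluded).
SIGNATURE_CLASSES = PHARMACOPHORE_CLASSES[:6]

_WATER_CODES = frozenset({"HOH", "WAT", "DOD", "H2O", "TIP", "SOL"})

# van der Waals radii in Angstrom, by element symbol
_VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
    "SE": 1.90,
    "FE": 1.52,
    "MG": 1.73,
    "ZN": 1.39,
    "MN": 1.61,
    "CU": 1.40,
    "CA": 2.31,
    "NA": 2.27,
    "K": 2.75,
    "CL": 1.75,
    "F": 1.47,
    "BR": 1.85,
    "I": 1.98,
}


class ParseError(ValueError):
    """Raised when PDB content cannot be interpreted."""


class ChainError(KeyError):
    """Raised when a requested chain is absent."""


class TypingError(ValueError):
    """Raised when an atom cannot be assigned a radius or pharmacophore."""


@dataclass(frozen=True)
class AtomRecord:
    """A single typed atom (convenience view; bulk storage is array-based)."""

    serial: int
    name: str
    element: str
    chain_id: str
    residue_name: str
    residue_number: int
    insertion: str
    coords: np.ndarray
    vdw_radius: float
    pharmacophore: str
    is_hetero: bool


@dataclass(frozen=True)
class ResidueScore:
    """Prediction score in [0, 1] attached to one residue."""

    chain_id: str
    residue_number: int
    insertion: str
    score: float

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(
                f"score {self.score} outside [0, 1] for residue "
                f"{self.chain_id}{self.residue_number}{self.insertion}"
            )


@dataclass
class ProteinStructure:
    """Polymer atoms plus any recognised cofactor ligand atoms.

    ``atoms`` and ``ligand_atoms`` are biotite ``AtomArray`` objects.  After
    :func:`assign_typing` both carry ``vdw_radius`` (float, Angstrom) and
    ``pharmacophore`` (string class) annotations.
    """

    atoms: struc.AtomArray
    ligand_atoms: struc.AtomArray = field(default=None)

    def __post_init__(self):
        if self.ligand_atoms is None:
            self.ligand_atoms = self.atoms[:0]

    # -- basic views -------------------------------------------------------
    @property
    def chains(self) -> set:
        return set(np.unique(self.atoms.chain_id))

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def is_typed(self) -> bool:
        return "vdw_radius" in self.atoms.get_annotation_categories()

    def heavy(self) -> struc.AtomArray:
        """Polymer atoms excluding hydrogens."""
        return self.atoms[self.atoms.element != "H"]

    def residue_keys(self) -> list:
        """Ordered unique (chain_id, res_id, ins_code) keys of polymer residues."""
        keys = []
        seen = set()
        for cid, rid, ins in zip(
            self.atoms.chain_id, self.atoms.res_id, self.atoms.ins_code
        ):
            k = (str(cid), int(rid), str(ins))
            if k not in seen:
                seen.add(k)
                keys.append(k)
        return keys

    def atom_residue_index(self) -> np.ndarray:
        """Per-atom index into :meth:`residue_keys`."""
        keys = {k: i for i, k in enumerate(self.residue_keys())}
        return np.array(
            [
                keys[(str(c), int(r), str(i))]
                for c, r, i in zip(
                    self.atoms.chain_id, self.atoms.res_id, self.atoms.ins_code
                )
            ],
            dtype=int,
        )

    def residue_names(self) -> list:
        """Residue 3-letter codes aligned with :meth:`residue_keys`."""
        out = {}
        for name, c, r, i in zip(
            self.atoms.res_name, self.atoms.chain_id, self.atoms.res_id,
            self.atoms.ins_code,
        ):
            out.setdefault((str(c), int(r), str(i)), str(name))
        return [out[k] for k in self.residue_keys()]


def _empty_atom_array(template: struc.AtomArray) -> struc.AtomArray:
    return template[:0]


def parse_pdb(text: str) -> ProteinStructure:
    """Parse PDB-format content into a :class:`ProteinStructure`.

    Alternate locations are resolved to the highest-occupancy conformer (ties
    keep the first listed), waters are removed, multi-model files keep model 1,
    and HETATM records are kept only for the seven cofactor component codes
    (routed to ``ligand_atoms``).  Selenomethionine (MSE) is retained as a
    polymer residue and treated as methionine.
    """
    lines = text.splitlines()
    if not any(line.startswith("ATOM") for line in lines):
        raise ParseError("no ATOM records found")
    for i, line in enumerate(lines, start=1):
        if line.startswith(("ATOM", "HETATM")):
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fieldstr = line[lo:hi].strip()
                try:
                    float(fieldstr)
                except ValueError:
                    raise ParseError(
                        f"malformed coordinate field {fieldstr!r} on line {i}"
                    ) from None
    try:
        pdb = PDBFile.read(io.StringIO(text))
        arr = pdb.get_structure(
            model=1,
            altloc="occupancy",
            extra_fields=["atom_id", "occupancy", "b_factor"],
        )
    except ParseError:
        raise
    except Exception as exc:  # pragma: no cover - biotite error paths vary
        raise ParseError(f"could not parse PDB content: {exc}") from exc

    arr = arr[~np.isin(arr.res_name, list(_WATER_CODES))]
    # MSE is chemically methionine; keep it in the polymer
    mse = arr.res_name == "MSE"
    if mse.any():
        arr.res_name[mse] = "MET"
        arr.hetero[mse] = False

    is_ligand = arr.hetero & np.isin(arr.res_name, COFACTOR_CODES)
    protein = arr[~arr.hetero]
    ligands = arr[is_ligand]
    if len(protein) == 0:
        raise ParseError("no polymer atoms after filtering")
    return ProteinStructure(atoms=protein, ligand_atoms=ligands)


def select_chains(s: ProteinStructure, chains) -> ProteinStructure:
    """Restrict a structure to the given chain ids (ligands follow their chain)."""
    chains = set(chains)
    missing = chains - s.chains
    if missing:
        avail = ", ".join(sorted(s.chains))
        raise ChainError(
            f"chain {', '.join(sorted(missing))} not found; available: {avail}"
        )
    keep = np.isin(s.atoms.chain_id, list(chains))
    lig_keep = np.isin(s.ligand_atoms.chain_id, list(chains))
    return ProteinStructure(atoms=s.atoms[keep], ligand_atoms=s.ligand_atoms[lig_keep])


def merge(a: ProteinStructure, b: ProteinStructure) -> ProteinStructure:
    """Concatenate two structures (chain ids must not collide)."""
    overlap = a.chains & b.chains
    if overlap:
        raise ChainError(f"chain id collision: {sorted(overlap)}")
    return ProteinStructure(
        atoms=a.atoms + b.atoms,
        ligand_atoms=a.ligand_atoms + b.ligand_atoms,
    )


# --------------------------------------------------------------------------
# Pharmacophore typing
# --------------------------------------------------------------------------

_AROMATIC_ATOMS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "CD2", "CE1"},
}

_POSITIVE_ATOMS = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
}

_NEGATIVE_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}

_DONOR_ATOMS = {
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "TRP": {"NE1"},
    "HIS": {"ND1"},
    "CYS": {"SG"},
}

_ACCEPTOR_ATOMS = {
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "HIS": {"NE2"},
}


def _pharmacophore_class(res_name: str, atom_name: str, element: str) -> str:
    """Pharmacophore class from a fixed residue/atom-name lookup.

    Aromatic ring atoms resolve to ``aromatic`` even though they are also
    hydrophobic; charged groups win over their donor/acceptor character.
    Atoms of unknown residues fall back to element-based typing.
    """
    if element == "H":
        return "neutral"
    # backbone
    if atom_name == "N":
        return "neutral" if res_name == "PRO" else "donor"
    if atom_name in ("O", "OXT"):
        return "acceptor"
    if atom_name == "C":
        return "neutral"
    if atom_name in _POSITIVE_ATOMS.get(res_name, ()):
        return "positive"
    if atom_name in _NEGATIVE_ATOMS.get(res_name, ()):
        return "negative"
    if atom_name in _AROMATIC_ATOMS.get(res_name, ()):
        return "aromatic"
    if atom_name in _DONOR_ATOMS.get(res_name, ()):
        return "donor"
    if atom_name in _ACCEPTOR_ATOMS.get(res_name, ()):
        return "acceptor"
    # element fallback (covers remaining side-chain atoms and unknown residues)
    if element == "C":
        return "hydrophobic"
    if element == "N":
        return "donor"
    if element == "O":
        return "acceptor"
    if element in ("S", "SE"):
        return "hydrophobic"
    return "neutral"


def _ligand_class(element: str) -> str:
    if element == "C":
        return "hydrophobic"
    if element == "N":
        return "donor"
    if element == "O":
        return "acceptor"
    if element in ("P", "S"):
        return "neutral"
    if element in ("FE", "MG", "ZN", "MN", "CU"):
        return "positive"
    return "neutral"


def _type_array(arr: struc.AtomArray, is_ligand: bool) -> struc.AtomArray:
    arr = arr.copy()
    radii = np.empty(len(arr), dtype=float)
    pharm = np.empty(len(arr), dtype="U11")
    for i in range(len(arr)):
        element = str(arr.element[i]).upper()
        if element not in _VDW_RADII:
            raise TypingError(
                f"unknown element {element!r} for atom "
                f"{arr.res_name[i]} {arr.atom_name[i]}"
            )
        radii[i] = _VDW_RADII[element]
        if is_ligand:
            pharm[i] = _ligand_class(element)
        else:
            pharm[i] = _pharmacophore_class(
                str(arr.res_name[i]), str(arr.atom_name[i]), element
            )
    arr.set_annotation("vdw_radius", radii)
    arr.set_annotation("pharmacophore", pharm)
    return arr


def assign_typing(s: ProteinStructure) -> ProteinStructure:
    """Attach van der Waals radii and pharmacophore classes to every atom."""
    return ProteinStructure(
        atoms=_type_array(s.atoms, is_ligand=False),
        ligand_atoms=_type_array(s.ligand_atoms, is_ligand=True),
    )


# --------------------------------------------------------------------------
# Annotated output
# --------------------------------------------------------------------------


def write_annotated_pdb(s: ProteinStructure, scores) -> str:
    """Serialize a structure with per-residue scores in the b-factor column.

    The b-factor of every atom in a scored residue is 100 x score, rounded to
    two decimals; atoms of unscored residues get 0.00.
    """
    lookup = {}
    for sc in scores:
        if not (0.0 <= sc.score <= 1.0):
            raise ValueError(f"score {sc.score} outside [0, 1]")
        lookup[(sc.chain_id, sc.residue_number, sc.insertion)] = sc.score
    if not lookup:
        raise ValueError("at least one residue score is required")

    arr = s.atoms.copy()
    lig = s.ligand_atoms.copy()
    for a in (arr, lig):
        b = np.zeros(len(a))
        for i in range(len(a)):
            key = (str(a.chain_id[i]), int(a.res_id[i]), str(a.ins_code[i]))
            b[i] = round(100.0 * lookup.get(key, 0.0), 2)
        if "b_factor" in a.get_annotation_categories():
            a.b_factor[:] = b
        else:
            a.set_annotation("b_factor", b)

    combined = arr + lig if len(lig) else arr
    pdb = PDBFile()
    pdb.set_structure(combined)
    return "\n".join(pdb.lines) + "\n"
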