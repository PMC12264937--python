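"""Molecular structure ingestion, atom typing and binding-pocket extraction.

Atoms are typed by chemical element, residue and role (protein / ligand /
metal).  Protein atoms come from PDB ATOM records; HETATM records whose
element belongs to the metal alphabet {Zn, Mg, Mn, Ca, Na, Fe, Ni} become
metal atoms (Cu is deliberately absent: too infrequent in metalloprotein
binding pockets to model).  Waters are dropped.  Ligands are read from SDF
(via rdkit) or MOL2.

The binding pocket keeps all ligand atoms, protein atoms within 12 A of the
ligand and metal atoms within 15 A (atom-atom minimum distance, closed
thresholds).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from scipy.spatial.distance import cdist

METAL_ELEMENTS = ("Zn", "Mg", "Mn", "Ca", "Na", "Fe", "Ni")
PROTEIN_ELEMENTS = ("C", "N", "O", "S")
LIGAND_ELEMENTS = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "H")

#: amino-acid categories by side-chain character: hydrophobic (H),
#: uncharged polar (U), negatively charged (N), positively charged (P)
RESIDUE_CATEGORIES = {
    **{r: "H" for r in ("GLY", "ALA", "VAL", "LEU", "ILE", "MET", "PRO", "PHE", "TRP")},
    **{r: "U" for r in ("SER", "THR", "ASN", "GLN", "TYR", "CYS")},
    **{r: "N" for r in ("ASP", "GLU")},
    **{r: "P" for r in ("LYS", "ARG", "HIS")},
}

CATEGORY_TAGS = ("H", "U", "N", "P")


@dataclass
class Atom:
    element: str
    coords: np.ndarray
    residue_name: str = ""
    role: str = "protein"  # protein | ligand | metal

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)
        self.element = str(self.element)
        self.residue_name = str(self.residue_name)
        if not self.element:
            raise ValueError("atom element must be non-empty")
        if self.role == "metal" and self.element not in METAL_ELEMENTS:
            raise ValueError(f"{self.element} is not in the metal alphabet")


@dataclass
class MolecularComplex:
    atoms: List[Atom]
    identifier: str = ""

    def by_role(self, role: str) -> List[Atom]:
        return [a for a in self.atoms if a.role == role]

    def coords(self, atoms: Sequence[Atom] | None = None) -> np.ndarray:
        atoms = self.atoms if atoms is None else atoms
        if not atoms:
            return np.zeros((0, 3))
        return np.stack([a.coords for a in atoms])

    @property
    def has_metal(self) -> bool:
        return any(a.role == "metal" for a in self.atoms)


def residue_category(residue_name: str) -> str:
    """Side-chain category (H/U/N/P) of a standard 3-letter residue code."""
    try:
        return RESIDUE_CATEGORIES[residue_name.strip().upper()]
    except KeyError:
        raise ValueError(f"unknown residue code: {residue_name!r}") from None


def _normalize_element(symbol: str) -> str:
    s = symbol.strip()
    if not s:
        return ""
    return s[0].upper() + s[1:].lower()


def _element_from_atom_name(name: str) -> str:
    """Heuristic element from a PDB atom name when columns 77-78 are blank."""
    alpha = "".join(c for c in name if c.isalpha())
    if not alpha:
        return ""
    two = _normalize_element(alpha[:2])
    if two in METAL_ELEMENTS or two in ("Cl", "Br"):
        return two
    return alpha[0].upper()


def read_protein_pdb(path) -> List[Atom]:
    """Parse ATOM/HETATM records from a PDB file.

    ATOM records become protein atoms; HETATM records with a metal element
    become metal atoms; waters and other heteroatoms are skipped.  Only the
    first alternate location of each atom is kept.  Parse failures raise
    with the offending line number.
    """
    atoms: List[Atom] = []
    seen_altloc = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6].strip()
            if record not in ("ATOM", "HETATM"):
                continue
            resname = line[17:20].strip().upper()
            if resname == "HOH":
                continue
            try:
                name = line[12:16].strip()
                altloc = line[16].strip() if len(line) > 16 else ""
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError):
                raise ValueError(
                    f"unparseable {record} record at line {lineno} of {path}"
                ) from None
            element = _normalize_element(line[76:78]) if len(line) > 76 else ""
            if not element:
                element = _element_from_atom_name(name)
            if not element:
                raise ValueError(f"no element for atom at line {lineno} of {path}")
            if altloc:
                key = (line[21], line[22:27], name)
                if key in seen_altloc:
                    continue
                seen_altloc.add(key)
            if record == "ATOM":
                atoms.append(Atom(element, (x, y, z), resname, "protein"))
            elif element in METAL_ELEMENTS:
                atoms.append(Atom(element, (x, y, z), resname, "metal"))
    return atoms


def _read_sdf(path) -> List[Atom]:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    mol = next(iter(supplier), None)
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError(f"no molecule in SDF file {path}")
    conf = mol.GetConformer()
    atoms = []
    for i, atom in enumerate(mol.GetAtoms()):
        pos = conf.GetAtomPosition(i)
        atoms.append(Atom(atom.GetSymbol(), (pos.x, pos.y, pos.z), "", "ligand"))
    return atoms


def _read_mol2(path) -> List[Atom]:
    atoms: List[Atom] = []
    in_atoms = False
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("@<TRIPOS>"):
                in_atoms = stripped == "@<TRIPOS>ATOM"
                continue
            if in_atoms and stripped:
                parts = stripped.split()
                x, y, z = (float(v) for v in parts[2:5])
                # SYBYL atom type "C.3", "N.ar", "Cl" -> element before the dot
                element = _normalize_element(parts[5].split(".")[0])
                atoms.append(Atom(element, (x, y, z), "", "ligand"))
    if not atoms:
        raise ValueError(f"no atoms in MOL2 file {path}")
    return atoms


def read_ligand(path) -> List[Atom]:
    """Read a ligand structure (SDF/MOL or MOL2); all atoms get role=ligand."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".sdf", ".mol"):
        return _read_sdf(path)
    if ext == ".mol2":
        return _read_mol2(path)
    raise ValueError(f"unsupported ligand format: {ext!r} (expected .sdf/.mol/.mol2)")


def pocket_atoms(
    mc: MolecularComplex, protein_cutoff: float = 12.0, metal_cutoff: float = 15.0
) -> MolecularComplex:
    """Binding-pocket subset: ligand + nearby protein (<=12 A) + metals (<=15 A)."""
    ligand = mc.by_role("ligand")
    if not ligand:
        raise ValueError("no ligand atoms in complex")
    lig_xyz = mc.coords(ligand)
    kept = list(ligand)
    for role, cutoff in (("protein", protein_cutoff), ("metal", metal_cutoff)):
        candidates = mc.by_role(role)
        if not candidates:
            continue
        dmin = cdist(mc.coords(candidates), lig_xyz).min(axis=1)
        kept.extend(a for a, d in zip(candidates, dmin) if d <= cutoff)
    return MolecularComplex(kept, identifier=mc.identifier)


def write_pdb(path, mc: MolecularComplex) -> None:
    """Minimal PDB writer (protein/metal atoms; ligand atoms as HETATM LIG)."""
    with open(path, "w") as fh:
        for i, a in enumerate(mc.atoms, start=1):
            record = "ATOM  " if a.role == "protein" else "HETATM"
            resname = a.residue_name or ("LIG" if a.role == "ligand" else a.element.upper())
            x, y, z = a.coords
            fh.write(
                f"{record}{i:>5} {a.element.upper():<4}{resname:>4} A{i:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                f"{a.element.upper():>2}\n"
            )
        fh.write("END\n")
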