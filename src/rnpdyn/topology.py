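"""Molecular topology: atoms, residues, chains, and polymer classification.

The topology is deliberately minimal: it records what a PDB file states
(names, residue numbering kept verbatim, chains) plus a fixed
element-to-mass table, and classifies residues into polymer classes
(protein / nucleic / ion / solvent / other) through a fixed lookup.  It
never renumbers residues, so domain windows expressed in author numbering
(e.g. an RNA-recognition motif spanning residues 20-98) apply directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "AtomRecord",
    "Residue",
    "Topology",
    "polymer_class_of",
    "ELEMENT_MASSES",
    "EmptyStructureError",
    "PDBFormatError",
    "read_pdb_topology",
]


# Standard atomic masses (u), sufficient for biomolecular systems with
# common counter-ions.  Unknown elements fall back to 1.0 u with the
# element preserved, so geometry that only needs positions still works.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "NA": 22.990, "CL": 35.45, "K": 39.098, "MG": 24.305,
    "ZN": 65.38, "CA": 40.078, "F": 18.998, "BR": 79.904, "I": 126.904,
    "FE": 55.845, "MN": 54.938, "SE": 78.971,
}

_PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # common protonation-state variants
    "HID", "HIE", "HIP", "ASH", "GLH", "LYN", "CYX", "CYM",
}
_NUCLEIC_RESNAMES = {
    "A", "U", "G", "C", "I",
    "RA", "RU", "RG", "RC",
    "DA", "DT", "DG", "DC",
    "A3", "A5", "U3", "U5", "G3", "G5", "C3", "C5N",
}
_ION_RESNAMES = {
    "NA", "NA+", "CL", "CL-", "K", "K+", "MG", "MG2", "ZN", "CA2", "CS",
    "LI", "RB", "BR-", "F-", "IOD",
}
_SOLVENT_RESNAMES = {"HOH", "WAT", "SOL", "TIP3", "TIP4", "SPC", "H2O"}


def polymer_class_of(residue_name: str) -> str:
    """Classify a residue name into a polymer class via a fixed lookup."""
    name = residue_name.strip().upper()
    if name in _PROTEIN_RESNAMES:
        return "protein"
    if name in _NUCLEIC_RESNAMES:
        return "nucleic"
    if name in _ION_RESNAMES:
        return "ion"
    if name in _SOLVENT_RESNAMES:
        return "solvent"
    return "other"


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    mass: float
    residue_name: str
    residue_index: int
    chain_id: str
    polymer_class: str

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.serial}: mass must be positive")


@dataclass(frozen=True)
class Residue:
    chain_id: str
    residue_index: int
    residue_name: str
    first_atom: int  # 0-based index into Topology.atoms
    last_atom: int   # exclusive

    @property
    def atom_indices(self) -> range:
        return range(self.first_atom, self.last_atom)


class EmptyStructureError(ValueError):
    """Raised when a structure source contains no atoms."""


class PDBFormatError(ValueError):
    """Raised when a mandatory PDB column cannot be parsed."""


@dataclass
class Topology:
    """Ordered atom list partitioned into residues (file order preserved)."""

    atoms: list[AtomRecord]
    covalent_pairs: set[tuple[int, int]] = field(default_factory=set)
    residues: list[Residue] = field(init=False)

    def __post_init__(self) -> None:
        self.residues = _build_residues(self.atoms)
        self.covalent_pairs = {
            (min(i, j), max(i, j)) for i, j in self.covalent_pairs
        }

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self):
        import numpy as np

        return np.array([a.mass for a in self.atoms], dtype=float)

    def residue_of(self, atom_index: int) -> Residue:
        for res in self.residues:
            if res.first_atom <= atom_index < res.last_atom:
                return res
        raise IndexError(f"atom index {atom_index} out of range")

    def residue_key_per_atom(self) -> list[tuple[str, int]]:
        """(chain_id, residue_index) per atom, for grouping by residue."""
        keys: list[tuple[str, int]] = []
        for res in self.residues:
            keys.extend([(res.chain_id, res.residue_index)] * (res.last_atom - res.first_atom))
        return keys


def _build_residues(atoms: Sequence[AtomRecord]) -> list[Residue]:
    residues: list[Residue] = []
    start = 0
    for i, atom in enumerate(atoms):
        key = (atom.chain_id, atom.residue_index, atom.residue_name)
        prev = atoms[i - 1] if i > 0 else None
        prev_key = (
            (prev.chain_id, prev.residue_index, prev.residue_name)
            if prev is not None
            else None
        )
        if prev_key is not None and key != prev_key:
            residues.append(
                Residue(prev.chain_id, prev.residue_index, prev.residue_name, start, i)
            )
            start = i
    if atoms:
        last = atoms[-1]
        residues.append(
            Residue(last.chain_id, last.residue_index, last.residue_name, start, len(atoms))
        )
    return residues


def _infer_element(atom_name: str, residue_name: str) -> str:
    """Element from the atom name when the element column is absent.

    Two-letter ions (NA, CL, MG ...) are recognized when the residue is an
    ion; otherwise the first alphabetic character wins, which is correct
    for standard biopolymer atom names (CA is carbon, not calcium).
    """
    stripped = "".join(ch for ch in atom_name if ch.isalpha()).upper()
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    if polymer_class_of(residue_name) == "ion" and stripped in ELEMENT_MASSES:
        return stripped
    return stripped[0]


def _mass_of(element: str) -> float:
    return ELEMENT_MASSES.get(element.upper(), 1.0)


def read_pdb_topology(source: str | Iterable[str]) -> Topology:
    """Parse ATOM/HETATM records of the first MODEL into a Topology.

    Coordinates are ignored (see :func:`rnpdyn.trajectory.read_frames`).
    Residue indices are kept exactly as printed in the file.
    """
    if isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = list(source)

    atoms: list[AtomRecord] = []
    in_first_model = True
    seen_model = False
    for lineno, line in enumerate(lines, start=1):
        record = line[:6].strip()
        if record == "MODEL":
            if seen_model:
                break
            seen_model = True
            continue
        if record == "ENDMDL":
            in_first_model = False
            continue
        if record not in ("ATOM", "HETATM") or not in_first_model:
            continue
        try:
            serial = int(line[6:11])
            name = line[12:16].strip()
            resname = line[17:20].strip() or line[17:21].strip()
            chain = line[21] if len(line) > 21 else " "
            resid = int(line[22:26])
        except (ValueError, IndexError) as exc:
            raise PDBFormatError(
                f"line {lineno}: unparseable mandatory column ({exc})"
            ) from None
        element = line[76:78].strip().upper() if len(line) >= 77 else ""
        if not element:
            element = _infer_element(name, resname)
        atoms.append(
            AtomRecord(
                serial=serial,
                name=name,
                element=element,
                mass=_mass_of(element),
                residue_name=resname,
                residue_index=resid,
                chain_id=chain if chain.strip() else " ",
                polymer_class=polymer_class_of(resname),
            )
        )
    if not atoms:
        raise EmptyStructureError("no ATOM/HETATM records found")
    return Topology(atoms=atoms)
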