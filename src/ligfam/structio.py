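"""Read and write PDB-format structures and extract SAM/SAH ligand instances.

Parsing is delegated to gemmi's fixed-column PDB reader; the classes here are
the thin, normalized view the rest of the package works with:

* atom names are normalized from the PDB-v2 asterisk dialect (``O2*``) to the
  primed dialect (``O2'``) at parse time;
* alternate locations are collapsed to a single conformer (highest occupancy,
  ties broken by altloc identifier order);
* only model 1 of multi-model files is read;
* hydrogens are dropped (all downstream geometry is heavy-atom-only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "LigandInstance",
    "ParseError",
    "read_pdb",
    "write_pdb",
    "structure_to_pdb_string",
    "normalize_atom_name",
    "extract_ligands",
    "RIBOSE_RING_ATOMS",
    "AMINO_ACIDS",
]

#: Ribose ring atoms required for pucker analysis.
RIBOSE_RING_ATOMS = ("C1'", "C2'", "C3'", "C4'", "O4'")

#: Standard amino-acid residue codes (protein side of contact analysis).
AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO
       SER THR TRP TYR VAL""".split()
)


class ParseError(ValueError):
    """Raised for unreadable or atom-free coordinate files."""


@dataclass
class Atom:
    """One heavy atom of a structure, in normalized naming."""

    name: str
    element: str
    residue_name: str
    residue_number: int
    insertion_code: str
    chain: str
    coords: np.ndarray  # shape (3,), Angstrom
    b_factor: float  # Angstrom^2
    occupancy: float = 1.0
    altloc: str = ""
    het: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.b_factor < 0:
            raise ValueError(f"negative B-factor for atom {self.name}")


@dataclass
class Structure:
    """An ordered heavy-atom list from one coordinate file (model 1 only)."""

    structure_id: str
    atoms: list[Atom]
    models: int = 1

    def protein_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.residue_name in AMINO_ACIDS]


@dataclass
class LigandInstance:
    """One bound SAM or SAH copy: the atoms of a single HET residue."""

    ligand_code: str
    structure_id: str
    chain: str
    residue_number: int
    atoms: list[Atom]
    complete_ribose: bool = field(init=False)

    def __post_init__(self) -> None:
        for a in self.atoms:
            if a.residue_name != self.ligand_code:
                raise ValueError("ligand atoms must share the ligand residue name")
        names = {a.name for a in self.atoms}
        self.complete_ribose = all(n in names for n in RIBOSE_RING_ATOMS)

    @property
    def instance_id(self) -> str:
        return f"{self.structure_id}:{self.chain}:{self.residue_number}:{self.ligand_code}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self, names=None) -> np.ndarray:
        atoms = self.atoms if names is None else [self.atom(n) for n in names]
        missing = [n for n, a in zip(names or [], atoms) if a is None]
        if missing:
            raise KeyError(f"missing ligand atoms: {missing}")
        return np.array([a.coords for a in atoms])

    def mean_b_factor(self) -> float:
        return float(np.mean([a.b_factor for a in self.atoms]))


def normalize_atom_name(name: str) -> str:
    """Map asterisk-dialect sugar names (O2*) onto primed names (O2')."""
    return name.strip().replace("*", "'")


def _collapse_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep a single conformer per (chain, residue, atom name).

    Highest occupancy wins; ties go to the earliest altloc identifier.
    """
    best: dict[tuple, Atom] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a.chain, a.residue_number, a.insertion_code, a.residue_name, a.name)
        if key not in best:
            best[key] = a
            order.append(key)
        else:
            b = best[key]
            if (a.occupancy, _altloc_rank(a.altloc)) > (b.occupancy, _altloc_rank(b.altloc)):
                best[key] = a
    return [best[k] for k in order]


def _altloc_rank(altloc: str) -> float:
    # earlier altloc letters rank higher; blank highest of all
    return 0.0 if not altloc else -ord(altloc)


def read_pdb(path: str | Path, structure_id: str | None = None) -> Structure:
    """Parse a fixed-column PDB file into a :class:`Structure`.

    Model 1 only; hydrogens discarded; atom names normalized; altlocs collapsed.
    Raises :class:`ParseError` for unreadable or atom-free files.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.element.name == "H" or atom.element.name == "D":
                    continue
                atoms.append(
                    Atom(
                        name=normalize_atom_name(atom.name),
                        element=atom.element.name,
                        residue_name=residue.name.strip(),
                        residue_number=residue.seqid.num,
                        insertion_code=(residue.seqid.icode or "").strip(),
                        chain=chain.name,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        b_factor=max(atom.b_iso, 0.0),
                        occupancy=atom.occ,
                        altloc=(atom.altloc or "").strip(),
                        het=residue.het_flag == "H",
                    )
                )
    atoms = _collapse_altlocs(atoms)
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records")
    sid = structure_id or (st.name.strip() if st.name.strip() else path.stem).upper()
    return Structure(structure_id=sid, atoms=atoms, models=len(st))


def _format_atom_name(name: str, element: str) -> str:
    """PDB columns 13-16: one-letter elements start at column 14."""
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def structure_to_pdb_string(structure: Structure) -> str:
    """Format standard-conformant ATOM/HETATM records (occupancy 55-60, B 61-66)."""
    lines = []
    for i, a in enumerate(structure.atoms, start=1):
        record = "HETATM" if a.het else "ATOM  "
        lines.append(
            f"{record}{i:5d} {_format_atom_name(a.name, a.element)}"
            f"{a.altloc or ' '}{a.residue_name:<3s} {a.chain[:1]}"
            f"{a.residue_number:4d}{a.insertion_code or ' ':1s}   "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{a.occupancy:6.2f}{a.b_factor:6.2f}          "
            f"{a.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write the structure as a PDB file (see :func:`structure_to_pdb_string`)."""
    Path(path).write_text(structure_to_pdb_string(structure))


def extract_ligands(
    structure: Structure, codes: set[str] | None = None
) -> list[LigandInstance]:
    """Group HET atoms into per-residue ligand instances.

    One :class:`LigandInstance` per (chain, residue number) whose residue name
    is in ``codes`` (default ``{"SAM", "SAH"}``). An empty list is a valid
    result.
    """
    codes = codes or {"SAM", "SAH"}
    if not codes:
        raise ValueError("codes must be non-empty")
    groups: dict[tuple, list[Atom]] = {}
    order: list[tuple] = []
    for a in structure.atoms:
        if a.residue_name in codes:
            key = (a.chain, a.residue_number, a.insertion_code, a.residue_name)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(a)
    return [
        LigandInstance(
            ligand_code=key[3],
            structure_id=structure.structure_id,
            chain=key[0],
            residue_number=key[1],
            atoms=groups[key],
        )
        for key in order
    ]
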