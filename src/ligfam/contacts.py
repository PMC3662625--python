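"""Geometric ligand-protein hydrogen-bond detection and interaction profiles.

Crystal structures rarely include hydrogens, so a heavy-atom criterion is
used: a contact is scored when a ligand N/O/S atom and a protein N/O/S atom
lie within a distance cutoff (default 3.35 A) and one partner can donate a
hydrogen while the other can accept, according to fixed per-atom role tables.
No angle term is applied. Ligand SD is excluded from the tables (the
sulfonium/thioether sulfur essentially never hydrogen-bonds to protein).

Profiles aggregate contacts across a family's representatives into per-ligand-
atom residue-type counts, with charged / hydrophobic / polar class fractions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .structio import AMINO_ACIDS, LigandInstance, Structure

__all__ = [
    "HBondContact",
    "InteractionProfile",
    "hydrogen_bonds",
    "interaction_profile",
    "DEFAULT_HBOND_CUTOFF",
    "RESIDUE_CLASSES",
]

#: Heavy-atom donor-acceptor distance cutoff, Angstrom.
DEFAULT_HBOND_CUTOFF = 3.35

# Ligand-side roles. Adenine ring nitrogens N1/N3/N7 accept; the exocyclic
# amine N6 donates; the 2'/3' hydroxyls both donate and accept; the ring O4'
# and carboxylate O/OXT accept; the terminal ammonium N donates. SD and the
# ring junction N9 are excluded.
LIGAND_DONORS = frozenset({"N6", "O2'", "O3'", "N"})
LIGAND_ACCEPTORS = frozenset({"N1", "N3", "N7", "O2'", "O3'", "O4'", "O", "OXT"})

# Protein side-chain roles, keyed (residue, atom). D = donor, A = acceptor.
_SIDECHAIN_ROLES: dict[tuple[str, str], str] = {
    ("ARG", "NE"): "D", ("ARG", "NH1"): "D", ("ARG", "NH2"): "D",
    ("ASN", "OD1"): "A", ("ASN", "ND2"): "D",
    ("ASP", "OD1"): "A", ("ASP", "OD2"): "A",
    ("CYS", "SG"): "DA",
    ("GLN", "OE1"): "A", ("GLN", "NE2"): "D",
    ("GLU", "OE1"): "A", ("GLU", "OE2"): "A",
    ("HIS", "ND1"): "DA", ("HIS", "NE2"): "DA",
    ("LYS", "NZ"): "D",
    ("MET", "SD"): "A",
    ("SER", "OG"): "DA",
    ("THR", "OG1"): "DA",
    ("TRP", "NE1"): "D",
    ("TYR", "OH"): "DA",
}

#: Residue chemical classes used when summarising interaction profiles.
RESIDUE_CLASSES = {
    "charged": frozenset("DEKRH"),
    "hydrophobic": frozenset("AVLIMFWC"),
    "polar": frozenset("STNQYG"),
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def _protein_roles(residue_name: str, atom_name: str) -> str:
    """Donor/acceptor role string for a protein heavy atom ('' if none)."""
    if atom_name == "N":
        return "" if residue_name == "PRO" else "D"  # backbone amide
    if atom_name in ("O", "OXT"):
        return "A"  # backbone carbonyl / C-terminal carboxylate
    return _SIDECHAIN_ROLES.get((residue_name, atom_name), "")


def _ligand_roles(atom_name: str) -> str:
    roles = ""
    if atom_name in LIGAND_DONORS:
        roles += "D"
    if atom_name in LIGAND_ACCEPTORS:
        roles += "A"
    return roles


@dataclass(frozen=True)
class HBondContact:
    ligand_atom: str
    protein_atom: str
    chain: str
    residue_number: int
    residue_name: str
    distance: float  # Angstrom

    @property
    def protein_residue(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_number, self.residue_name)


@dataclass
class InteractionProfile:
    """Per-ligand-atom residue-type counts over one or more contact lists."""

    counts: dict[str, Counter] = field(default_factory=dict)

    @property
    def total_contacts(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())

    def class_fractions(self, ligand_atom: str) -> dict[str, float]:
        """Fraction of contacts at an atom made by each residue class."""
        counter = self.counts.get(ligand_atom, Counter())
        total = sum(counter.values())
        out = {}
        for cls, members in RESIDUE_CLASSES.items():
            hits = sum(
                n for res3, n in counter.items() if _THREE_TO_ONE.get(res3) in members
            )
            out[cls] = hits / total if total else 0.0
        return out


def hydrogen_bonds(
    lig: LigandInstance, structure: Structure, cutoff: float = DEFAULT_HBOND_CUTOFF
) -> list[HBondContact]:
    """All donor-acceptor-compatible ligand-protein pairs within ``cutoff``.

    Sorted by ligand atom name, then distance. An empty list is a valid
    result (a solvent-exposed or apo-like pose).
    """
    protein = [a for a in structure.atoms if a.residue_name in AMINO_ACIDS]
    polar_protein = [
        (a, _protein_roles(a.residue_name, a.name))
        for a in protein
        if a.element in ("N", "O", "S")
    ]
    polar_protein = [(a, r) for a, r in polar_protein if r]
    contacts = []
    for lat in lig.atoms:
        lroles = _ligand_roles(lat.name)
        if not lroles:
            continue
        for pat, proles in polar_protein:
            d = float(np.linalg.norm(lat.coords - pat.coords))
            if d > cutoff:
                continue
            if ("D" in lroles and "A" in proles) or ("A" in lroles and "D" in proles):
                contacts.append(
                    HBondContact(
                        ligand_atom=lat.name,
                        protein_atom=pat.name,
                        chain=pat.chain,
                        residue_number=pat.residue_number,
                        residue_name=pat.residue_name,
                        distance=d,
                    )
                )
    contacts.sort(key=lambda c: (c.ligand_atom, c.distance))
    return contacts


def interaction_profile(contact_lists: list[list[HBondContact]]) -> InteractionProfile:
    """Aggregate contact lists into per-atom residue-type counts."""
    profile = InteractionProfile()
    for contacts in contact_lists:
        for c in contacts:
            profile.counts.setdefault(c.ligand_atom, Counter())[c.residue_name] += 1
    return profile


def contacts_to_tsv(structure_id: str, contacts: list[HBondContact]) -> str:
    header = "structure_id\tligand_atom\tchain\tresnum\tresname\tprotein_atom\tdistance"
    rows = [
        f"{structure_id}\t{c.ligand_atom}\t{c.chain}\t{c.residue_number}"
        f"\t{c.residue_name}\t{c.protein_atom}\t{c.distance:.2f}"
        for c in contacts
    ]
    return "\n".join([header] + rows) + "\n"
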