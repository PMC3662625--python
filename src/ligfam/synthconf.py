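"""Deterministic synthetic test structures: puckered riboses, full SAM/SAH
conformers, toy binding pockets, and toy family alignments.

These generators are the package's download-free test surface. Each one is an
inverse problem of an analysis module: ``make_ribose`` builds a closed
five-membered ring whose endocyclic torsions realise a requested
pseudorotation state (P, Vmax); ``make_conformer`` grows a full heavy-atom
SAM (27 atoms) or SAH (26 atoms) around that ring with requested chi, gamma
and delta dihedrals; ``make_pocket`` plants protein atoms at exact
hydrogen-bond distances from named ligand atoms; ``make_family`` emits an
aligned family with controlled column conservation. All are deterministic for
a fixed spec/seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from . import geometry
from .siterules import SUBSTITUTION_GROUPS, FamilyAlignment
from .structio import Atom, LigandInstance, Structure

__all__ = [
    "ConformerSpec",
    "PocketSpec",
    "PocketEntry",
    "GenerationError",
    "make_ribose",
    "make_conformer",
    "make_pocket",
    "make_family",
]


class GenerationError(RuntimeError):
    """The requested geometry could not be realised within tolerance."""


@dataclass(frozen=True)
class ConformerSpec:
    """Target internal state of one synthetic ligand."""

    P: float = 126.0  # pseudorotation phase, degrees
    Vmax: float = 40.0  # puckering amplitude, degrees
    chi: float = -60.0  # C4-N9-C1'-O4', degrees
    gamma: float = 75.0  # O3'-C4'-C5'-SD, degrees
    delta: float = 180.0  # C4'-C5'-SD-CG, degrees
    ligand_code: str = "SAM"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.Vmax <= 60.0:
            raise ValueError("Vmax must be in [0, 60] degrees")
        if self.ligand_code not in ("SAM", "SAH"):
            raise ValueError("ligand_code must be SAM or SAH")


@dataclass(frozen=True)
class PocketEntry:
    ligand_atom: str
    residue_type: str  # 3-letter code
    protein_atom: str
    distance: float  # Angstrom

    def __post_init__(self) -> None:
        if self.distance <= 1.5:
            raise ValueError("contact distances must exceed 1.5 A")


@dataclass(frozen=True)
class PocketSpec:
    entries: tuple[PocketEntry, ...] = ()
    decoy_atoms: int = 0
    seed: int = 0


# ---------------------------------------------------------------------------
# ribose ring

# ring cycle O4'-C1'-C2'-C3'-C4'; idealized bond lengths (Angstrom)
_RING_ORDER = ("O4'", "C1'", "C2'", "C3'", "C4'")
_RING_BONDS = (1.45, 1.52, 1.52, 1.52, 1.45)  # O4'-C1', C1'-C2', ..., C4'-O4'
_RING_ANGLE = 104.0  # soft target for endocyclic bond angles, degrees

_TORSION_TOL = 0.5  # degrees
# the five-torsion cosine wave is not exactly closure-consistent, so bonds
# flex slightly to absorb the residual; worst case ~0.06 A at Vmax 55
_BOND_TOL = 0.06  # Angstrom


def _ring_torsions(coords: np.ndarray) -> tuple[float, ...]:
    """nu0..nu4 from coordinates ordered (O4', C1', C2', C3', C4')."""
    o4, c1, c2, c3, c4 = coords
    return geometry.endocyclic_torsions(np.array([c1, c2, c3, c4, o4]))


def _target_nu(P: float, Vmax: float) -> np.ndarray:
    return np.array(
        [Vmax * math.cos(math.radians(P + 144.0 * (j - 2))) for j in range(5)]
    )


def _ring_residuals(x: np.ndarray, nu_target: np.ndarray) -> np.ndarray:
    coords = x.reshape(5, 3)
    res = []
    # bond lengths (firm but slightly elastic; see _BOND_TOL)
    for k in range(5):
        d = np.linalg.norm(coords[(k + 1) % 5] - coords[k])
        res.append(30.0 * (d - _RING_BONDS[k]))
    # torsions (dominant): wrap differences into (-180, 180]
    try:
        nus = np.array(_ring_torsions(coords))
    except geometry.DihedralError:
        return np.full(15, 1e3)
    diff = (nus - nu_target + 180.0) % 360.0 - 180.0
    res.extend(10.0 * diff)
    # bond angles (soft regularisation keeps the ring chemically shaped)
    for k in range(5):
        a, b, c = coords[(k - 1) % 5], coords[k], coords[(k + 1) % 5]
        v1, v2 = a - b, c - b
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
        res.append(0.02 * (ang - _RING_ANGLE))
    return np.array(res)


def _seed_ring(P: float, Vmax: float, phase_offset: float) -> np.ndarray:
    """Planar pentagon plus a pseudorotation-like out-of-plane wave."""
    radius = 1.49 / (2.0 * math.sin(math.pi / 5.0))
    amp = 0.0105 * max(Vmax, 1.0)  # ~0.4 A at Vmax 40
    coords = []
    for k in range(5):
        theta = 2.0 * math.pi * k / 5.0
        z = amp * math.cos(math.radians(P + phase_offset) + 2.0 * theta)
        coords.append([radius * math.cos(theta), radius * math.sin(theta), z])
    return np.array(coords)


def make_ribose(P: float, Vmax: float) -> dict[str, np.ndarray]:
    """Closed five-ring whose endocyclic torsions hit (P, Vmax) within 0.5 deg.

    Returns coordinates keyed by atom name (O4', C1'..C4'). Built by
    least-squares refinement of bond lengths and target torsions from an
    out-of-plane-displacement seed; several seed phases are tried in a fixed
    order, so the output is deterministic. Vmax = 0 gives a planar ring
    (pucker undefined downstream).
    """
    nu_target = _target_nu(P, Vmax)
    offsets = (90.0, 0.0, 180.0, 270.0, 45.0, 135.0, 225.0, 315.0)
    best = None
    for offset in offsets:
        x0 = _seed_ring(P, Vmax, offset).ravel()
        sol = least_squares(_ring_residuals, x0, args=(nu_target,), xtol=1e-14, ftol=1e-14)
        coords = sol.x.reshape(5, 3)
        try:
            nus = np.array(_ring_torsions(coords))
        except geometry.DihedralError:
            continue
        err = np.max(np.abs((nus - nu_target + 180.0) % 360.0 - 180.0))
        bond_err = max(
            abs(np.linalg.norm(coords[(k + 1) % 5] - coords[k]) - _RING_BONDS[k])
            for k in range(5)
        )
        if best is None or err < best[0]:
            best = (err, bond_err, coords)
        if err < _TORSION_TOL and bond_err < _BOND_TOL:
            return dict(zip(_RING_ORDER, coords))
    err, bond_err, _ = best
    raise GenerationError(
        f"ring closure failed for P={P}, Vmax={Vmax}: "
        f"torsion error {err:.2f} deg, bond error {bond_err:.3f} A"
    )


# ---------------------------------------------------------------------------
# full conformer (NeRF internal-coordinate construction)


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom d.

    d is placed so that |c-d| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (degrees, IUPAC sign).
    """
    ang = math.radians(angle)
    tor = -math.radians(torsion)  # frame below is left-handed w.r.t. IUPAC sign
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# Z-matrix rows: atom, (ref_a, ref_b, ref_c), bond, angle, torsion.
# Torsion None marks the externally-specified dihedrals (chi / gamma / delta).
# Geometry idealised from the PDB chemical-component definition of SAM.
_ZMATRIX: list[tuple[str, tuple[str, str, str], float, float, float | None]] = [
    # ribose substituents
    ("O2'", ("O4'", "C1'", "C2'"), 1.413, 110.5, None),  # filled at build time
    ("O3'", ("C1'", "C2'", "C3'"), 1.423, 110.8, None),
    ("C5'", ("C2'", "C3'", "C4'"), 1.515, 114.5, None),
    # adenine, planar; chi sets the base orientation via C4
    ("N9", ("C4'", "O4'", "C1'"), 1.468, 108.2, -120.0),
    ("C4", ("O4'", "C1'", "N9"), 1.374, 126.3, None),  # torsion = chi
    ("C5", ("C1'", "N9", "C4"), 1.382, 105.9, 180.0),
    ("N3", ("C1'", "N9", "C4"), 1.342, 126.5, 0.0),
    ("C6", ("N9", "C4", "C5"), 1.409, 117.1, 180.0),
    ("N7", ("N9", "C4", "C5"), 1.387, 110.7, 0.0),
    ("C8", ("C4", "C5", "N7"), 1.311, 104.1, 0.0),
    ("N1", ("C4", "C5", "C6"), 1.351, 117.6, 0.0),
    ("N6", ("C4", "C5", "C6"), 1.335, 123.6, 180.0),
    ("C2", ("C5", "C6", "N1"), 1.330, 118.6, 0.0),
    # sulfonium/thioether arm; gamma and delta set SD and CG
    ("SD", ("C3'", "C4'", "C5'"), 1.815, 112.7, None),  # rotated to hit gamma
    ("CG", ("C4'", "C5'", "SD"), 1.815, 100.6, None),  # torsion = delta
    ("CE", ("C4'", "C5'", "SD"), 1.791, 100.9, None),  # delta - 115 (SAM only)
    ("CB", ("C5'", "SD", "CG"), 1.520, 110.5, 180.0),
    ("CA", ("SD", "CG", "CB"), 1.532, 112.4, 180.0),
    ("N", ("CG", "CB", "CA"), 1.489, 110.3, -65.0),
    ("C", ("CG", "CB", "CA"), 1.522, 109.2, 60.0),
    ("O", ("CB", "CA", "C"), 1.231, 120.4, -30.0),
    ("OXT", ("CB", "CA", "C"), 1.250, 117.0, 150.0),
]

_ELEMENTS = {"SD": "S"}

# bonds used for the clash check (graph distance >= 3 must stay >= 1.8 A)
_BONDS = [
    ("O4'", "C1'"), ("C1'", "C2'"), ("C2'", "C3'"), ("C3'", "C4'"), ("C4'", "O4'"),
    ("C2'", "O2'"), ("C3'", "O3'"), ("C4'", "C5'"),
    ("C1'", "N9"), ("N9", "C4"), ("N9", "C8"), ("C8", "N7"), ("N7", "C5"),
    ("C5", "C4"), ("C4", "N3"), ("N3", "C2"), ("C2", "N1"), ("N1", "C6"),
    ("C6", "C5"), ("C6", "N6"),
    ("C5'", "SD"), ("SD", "CG"), ("SD", "CE"), ("CG", "CB"), ("CB", "CA"),
    ("CA", "N"), ("CA", "C"), ("C", "O"), ("C", "OXT"),
]

_CLASH_CUTOFF = 1.8  # Angstrom


def _element_of(name: str) -> str:
    return _ELEMENTS.get(name, name[0])


def _graph_distances(names: list[str]) -> dict[tuple[str, str], int]:
    import networkx as nx

    g = nx.Graph((a, b) for a, b in _BONDS if a in names and b in names)
    g.add_nodes_from(names)
    out = {}
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, dist in lengths.items():
            out[(src, dst)] = dist
    return out


def make_conformer(spec: ConformerSpec, structure_id: str | None = None) -> LigandInstance:
    """Full heavy-atom SAM/SAH at the requested (P, Vmax, chi, gamma, delta).

    Deterministic for a fixed spec; the seed field exists for symmetry with
    the other generators and does not perturb coordinates. Non-bonded atom
    pairs closer than 1.8 A raise :class:`GenerationError` with a clash
    report. Pass ``structure_id`` to keep instance ids unique when several
    synthetic conformers enter the same RMSD matrix.
    """
    coords = dict(make_ribose(spec.P, spec.Vmax))
    nus = _ring_torsions(np.array([coords[n] for n in _RING_ORDER]))
    # exocyclic torsions follow the ring pucker so substituents stay staggered;
    # face signs chosen so the base and the hydroxyls sit on opposite faces
    dynamic = {
        "O2'": nus[1] + 120.0,
        "O3'": nus[2] - 120.0,
        "C5'": nus[3] + 120.0,
    }
    for name, refs, bond, angle, torsion in _ZMATRIX:
        if spec.ligand_code == "SAH" and name == "CE":
            continue
        if name in dynamic:
            torsion = dynamic[name]
        elif name == "C4":
            torsion = spec.chi
        elif name == "CG":
            torsion = spec.delta
        elif name == "CE":
            torsion = spec.delta - 115.0
        elif name == "SD":
            torsion = 180.0  # provisional; corrected below to hit gamma
        a, b, c = (coords[r] for r in refs)
        coords[name] = _place(a, b, c, bond, angle, torsion)
        if name == "SD":
            # gamma is a generalized dihedral through the non-bonded O3';
            # rotation of SD about C4'-C5' shifts it one-to-one
            got = geometry.dihedral(coords["O3'"], coords["C4'"], coords["C5'"], coords["SD"])
            coords[name] = _place(a, b, c, bond, angle, 180.0 + (spec.gamma - got))

    names = list(coords)
    dists = _graph_distances(names)
    clashes = []
    for i, ni in enumerate(names):
        for nj in names[i + 1 :]:
            if dists.get((ni, nj), 99) < 3:
                continue
            d = float(np.linalg.norm(coords[ni] - coords[nj]))
            if d < _CLASH_CUTOFF:
                clashes.append((ni, nj, round(d, 2)))
    if clashes:
        raise GenerationError(f"steric clash in generated conformer: {clashes}")

    atoms = [
        Atom(
            name=name,
            element=_element_of(name),
            residue_name=spec.ligand_code,
            residue_number=900,
            insertion_code="",
            chain="L",
            coords=coords[name],
            b_factor=20.0,
            het=True,
        )
        for name in names
    ]
    return LigandInstance(
        ligand_code=spec.ligand_code,
        structure_id=structure_id or f"SYN-{spec.ligand_code}",
        chain="L",
        residue_number=900,
        atoms=atoms,
    )


def conformer_structure(spec: ConformerSpec, structure_id: str | None = None) -> Structure:
    """Ligand-only :class:`Structure` wrapper around :func:`make_conformer`."""
    lig = make_conformer(spec, structure_id=structure_id)
    return Structure(structure_id=lig.structure_id, atoms=list(lig.atoms))


# ---------------------------------------------------------------------------
# pockets

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 1e-9 else np.array([0.0, 0.0, 1.0])


def _fibonacci_directions(n: int = 400) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (golden-spiral sphere)."""
    k = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _place_contact_atom(
    lig: LigandInstance, lat: Atom, entry: "PocketEntry", outward: np.ndarray
) -> np.ndarray:
    """Position the contact atom at the exact distance from its ligand atom
    while every OTHER polar ligand atom stays clearly beyond H-bond range
    (so the constructed contact set is exactly the requested one).

    Directions are searched deterministically, most-outward first.
    """
    from .contacts import _ligand_roles

    candidates = _fibonacci_directions()
    order = np.argsort(-candidates @ outward)
    for idx in order:
        pos = lat.coords + entry.distance * candidates[idx]
        ok = True
        for other in lig.atoms:
            if other.name == entry.ligand_atom:
                continue
            d = float(np.linalg.norm(other.coords - pos))
            if d < 2.0 or (_ligand_roles(other.name) and d < 3.45):
                ok = False
                break
        if ok:
            return pos
    raise GenerationError(
        f"cannot place {entry}: no direction keeps other polar ligand atoms "
        f"beyond hydrogen-bond range"
    )


def make_pocket(lig: LigandInstance, spec: PocketSpec) -> Structure:
    """Ligand plus single-residue fragments at exact contact distances.

    For each entry the named protein atom is placed along the outward
    direction from the ligand centroid through the named ligand atom, at
    exactly the requested distance; a carbon scaffold atom accompanies it
    1.5 A further out so the fragment is residue-like without adding polar
    atoms. Decoy carbons are scattered (seeded) at least 5 A from every
    ligand atom.
    """
    rng = np.random.default_rng(spec.seed)
    lig_coords = lig.coords()
    centroid = lig_coords.mean(axis=0)
    atoms: list[Atom] = list(lig.atoms)
    resnum = 1
    for entry in spec.entries:
        lat = lig.atom(entry.ligand_atom)
        if lat is None:
            raise GenerationError(f"ligand atom {entry.ligand_atom} not present")
        outward = lat.coords - centroid
        norm = np.linalg.norm(outward)
        outward = outward / norm if norm > 1e-6 else np.array([0.0, 0.0, 1.0])
        pos = _place_contact_atom(lig, lat, entry, outward)
        element = entry.protein_atom[0] if entry.protein_atom[0] in "NOS" else "C"
        atoms.append(
            Atom(
                name=entry.protein_atom,
                element=element,
                residue_name=entry.residue_type,
                residue_number=resnum,
                insertion_code="",
                chain="P",
                coords=pos,
                b_factor=15.0,
            )
        )
        atoms.append(
            Atom(
                name="CA",
                element="C",
                residue_name=entry.residue_type,
                residue_number=resnum,
                insertion_code="",
                chain="P",
                coords=pos + 1.5 * _unit(pos - lat.coords),
                b_factor=15.0,
            )
        )
        resnum += 1
    placed = 0
    tries = 0
    while placed < spec.decoy_atoms:
        tries += 1
        if tries > 10000:
            raise GenerationError("could not place decoy atoms")
        pos = centroid + rng.uniform(-15.0, 15.0, size=3)
        if np.min(np.linalg.norm(lig_coords - pos, axis=1)) < 5.0:
            continue
        atoms.append(
            Atom(
                name="CB",
                element="C",
                residue_name="ALA",
                residue_number=resnum,
                insertion_code="",
                chain="P",
                coords=pos,
                b_factor=30.0,
            )
        )
        resnum += 1
        placed += 1
    return Structure(structure_id=f"POCKET-{lig.ligand_code}", atoms=atoms)


# ---------------------------------------------------------------------------
# toy families


def make_family(
    n_members: int,
    rep_length: int,
    strict_positions: dict[int, str] | None = None,
    conservative_positions: dict[int, str] | None = None,
    nonconserved_positions: tuple[int, ...] = (),
    mutation_rate: float = 0.0,
    seed: int = 0,
    family_id: str = "SF_TOY",
) -> FamilyAlignment:
    """Seeded toy alignment with controlled conservation.

    Positions are 1-based representative residue numbers. ``strict_positions``
    force one residue type down the whole column; ``conservative_positions``
    keep the column within the residue's substitution group while guaranteeing
    at least two distinct residues; ``nonconserved_positions`` guarantee
    residues from at least two different groups. Remaining columns start from
    the representative residue and mutate independently at ``mutation_rate``.
    No gaps are introduced at controlled positions.
    """
    if n_members < 2:
        raise ValueError("need at least two members")
    strict_positions = dict(strict_positions or {})
    conservative_positions = dict(conservative_positions or {})
    for pos in (
        list(strict_positions) + list(conservative_positions) + list(nonconserved_positions)
    ):
        if not 1 <= pos <= rep_length:
            raise ValueError(f"position {pos} outside 1..{rep_length}")
    rng = np.random.default_rng(seed)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    rep = [alphabet[i] for i in rng.integers(0, len(alphabet), size=rep_length)]
    for pos, res in strict_positions.items():
        rep[pos - 1] = res
    for pos, res in conservative_positions.items():
        rep[pos - 1] = res
    rows = {f"{family_id}_rep": "".join(rep)}
    controlled = set(strict_positions) | set(conservative_positions) | set(nonconserved_positions)
    for m in range(1, n_members):
        seq = list(rep)
        for pos, res in conservative_positions.items():
            group = sorted(_group_containing(res))
            # guarantee >= 2 residue types in the column: members cycle the group
            seq[pos - 1] = group[m % len(group)] if len(group) > 1 else res
        for pos in nonconserved_positions:
            other = _different_group_residue(rep[pos - 1], rng)
            seq[pos - 1] = other if m == 1 else rep[pos - 1]
        for i in range(rep_length):
            if (i + 1) in controlled:
                continue
            if mutation_rate and rng.random() < mutation_rate:
                seq[i] = alphabet[rng.integers(0, len(alphabet))]
        rows[f"{family_id}_m{m}"] = "".join(seq)
    return FamilyAlignment(
        family_id=family_id, sequences=rows, representative_id=f"{family_id}_rep"
    )


def _group_containing(residue: str) -> frozenset:
    for g in SUBSTITUTION_GROUPS:
        if residue in g:
            return g
    return frozenset(residue)


def _different_group_residue(residue: str, rng: np.random.Generator) -> str:
    group = _group_containing(residue)
    candidates = [c for c in "ACDEFGHIKLMNPQRSTVWY" if c not in group]
    return candidates[int(rng.integers(0, len(candidates)))]
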