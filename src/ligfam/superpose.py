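"""Rigid-body ligand superposition, RMSD matrices and conformation typing.

Ligands are superposed pairwise by least-squares (Kabsch SVD, proper rotations
only) over either the five ribose ring atoms — the common reference frame for
comparing SAM/SAH poses — or all shared heavy atoms (the SAM/SAH intersection
drops SAM's S-methyl carbon CE). Pairwise RMSDs are collected into a symmetric
matrix and clustered (complete linkage) into conformation "Types", numbered by
descending cluster size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .geometry import B_FACTOR_CUTOFF, reliability
from .structio import LigandInstance, RIBOSE_RING_ATOMS

__all__ = [
    "SuperpositionResult",
    "RMSDMatrix",
    "ConformationTyping",
    "DegenerateFitError",
    "PairingError",
    "kabsch",
    "pair_atoms",
    "rmsd_matrix",
    "assign_types",
    "DEFAULT_TYPING_THRESHOLD",
]

#: Default complete-linkage cut (Angstrom) separating conformation Types.
DEFAULT_TYPING_THRESHOLD = 1.0


class DegenerateFitError(ValueError):
    """Fewer than three non-collinear atom pairs."""


class PairingError(ValueError):
    """Two ligands share too few atoms for the requested atom set."""


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, proper (det +1)
    translation: np.ndarray  # 3-vector, Angstrom
    rmsd: float  # Angstrom
    atom_set: str
    n_atoms: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class RMSDMatrix:
    ids: list[str]
    values: np.ndarray  # square, symmetric, Angstrom; NaN marks masked cells

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id list")

    @property
    def masked(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_tsv(self) -> str:
        lines = ["\t".join(["id"] + self.ids)]
        for i, row_id in enumerate(self.ids):
            row = "\t".join(f"{v:.4f}" for v in self.values[i])
            lines.append(f"{row_id}\t{row}")
        return "\n".join(lines) + "\n"


@dataclass
class ConformationTyping:
    matrix: RMSDMatrix
    threshold: float
    labels: dict[str, str]  # ligand id -> "Type N"


def _check_noncollinear(coords: np.ndarray) -> None:
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateFitError("collinear atom set: rotation underdetermined")


def kabsch(mobile: np.ndarray, target: np.ndarray, atom_set: str = "custom") -> SuperpositionResult:
    """Optimal proper rotation + translation mapping ``mobile`` onto ``target``.

    Coordinates must already be paired row-for-row. Reflections are forbidden:
    if the SVD correlation matrix has negative determinant the smallest
    singular direction is flipped, giving the best proper rotation.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("paired (n,3) coordinate arrays required")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateFitError("at least three atom pairs required")
    _check_noncollinear(mobile)
    _check_noncollinear(target)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, atom_set=atom_set, n_atoms=n)


def pair_atoms(
    a: LigandInstance, b: LigandInstance, atom_set: str = "ribose"
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Build 1:1 coordinate pairs by atom name.

    ``atom_set`` is "ribose" (the five ring atoms), "all" (intersection of
    shared heavy-atom names — SAM vs SAH drops CE) or an explicit name list.
    Returns (coords_a, coords_b, used_names, dropped_names).
    """
    names_a = [at.name for at in a.atoms]
    names_b = [at.name for at in b.atoms]
    if atom_set == "ribose":
        wanted = list(RIBOSE_RING_ATOMS)
    elif atom_set == "all":
        wanted = [n for n in names_a if n in set(names_b)]
    else:
        wanted = list(atom_set)
    shared = [n for n in wanted if n in set(names_a) and n in set(names_b)]
    dropped = sorted(set(names_a).symmetric_difference(names_b)) if atom_set == "all" else [
        n for n in wanted if n not in shared
    ]
    if len(shared) < 3:
        raise PairingError(
            f"{a.instance_id} vs {b.instance_id}: only {len(shared)} shared atoms"
        )
    if atom_set == "ribose" and len(shared) < 5:
        raise PairingError(
            f"{a.instance_id} vs {b.instance_id}: incomplete ribose ring"
        )
    return a.coords(shared), b.coords(shared), shared, dropped


def superpose_ligands(
    mobile: LigandInstance,
    target: LigandInstance,
    atom_set: str = "ribose",
    rmsd_atom_set: str | None = None,
) -> SuperpositionResult:
    """Superpose on ``atom_set``; optionally evaluate RMSD on another set.

    ``rmsd_atom_set`` supports the two-stage comparison of poses: fit on the
    ribose frame, measure deviation over all shared atoms.
    """
    ma, ta, _, _ = pair_atoms(mobile, target, atom_set)
    fit = kabsch(ma, ta, atom_set=atom_set if isinstance(atom_set, str) else "custom")
    if rmsd_atom_set is None:
        return fit
    mb, tb, names, _ = pair_atoms(mobile, target, rmsd_atom_set)
    moved = fit.transform(mb)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - tb) ** 2, axis=1))))
    return SuperpositionResult(
        rotation=fit.rotation,
        translation=fit.translation,
        rmsd=rmsd,
        atom_set=f"fit:{fit.atom_set}/rmsd:{rmsd_atom_set}",
        n_atoms=len(names),
    )


def rmsd_matrix(
    ligands: list[LigandInstance],
    atom_set: str = "ribose",
    rmsd_atom_set: str | None = "all",
    exclude_flagged: bool = True,
    b_factor_cutoff: float = B_FACTOR_CUTOFF,
) -> RMSDMatrix:
    """All-vs-all RMSD after per-pair superposition.

    By default each pair is fitted on the ribose moiety and the deviation is
    evaluated over all shared atoms. Ligands with mean B-factor above the
    cutoff are excluded when ``exclude_flagged`` is set. Pairs that cannot be
    matched are masked (NaN) with a warning.
    """
    import warnings

    kept = [
        lig
        for lig in ligands
        if not (exclude_flagged and reliability(lig, b_factor_cutoff).flagged)
    ]
    if len(kept) < 2:
        raise ValueError("need at least two (unflagged) ligands")
    ids = [lig.instance_id for lig in kept]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ligand instance ids; label instances uniquely")
    n = len(kept)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                res = superpose_ligands(kept[i], kept[j], atom_set, rmsd_atom_set)
                values[i, j] = values[j, i] = res.rmsd
            except (PairingError, DegenerateFitError) as exc:
                warnings.warn(f"masked pair: {exc}")
                values[i, j] = values[j, i] = np.nan
    return RMSDMatrix(ids=[lig.instance_id for lig in kept], values=values)


def assign_types(matrix: RMSDMatrix, threshold: float = DEFAULT_TYPING_THRESHOLD) -> ConformationTyping:
    """Complete-linkage clustering of the RMSD matrix cut at ``threshold``.

    Types are numbered from 1 by descending cluster size; ties broken by the
    smallest member id. Masked matrices are rejected (exclude the offending
    ligands and rebuild).
    """
    if matrix.masked:
        raise ValueError("matrix has masked cells; exclude unpairable ligands first")
    n = len(matrix.ids)
    if n == 1:
        return ConformationTyping(matrix, threshold, {matrix.ids[0]: "Type 1"})
    condensed = squareform(matrix.values, checks=False)
    Z = linkage(condensed, method="complete")
    raw = fcluster(Z, t=threshold, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for lig_id, c in zip(matrix.ids, raw):
        clusters.setdefault(int(c), []).append(lig_id)
    ordered = sorted(clusters.values(), key=lambda ids: (-len(ids), min(ids)))
    labels = {
        lig_id: f"Type {rank}"
        for rank, members in enumerate(ordered, start=1)
        for lig_id in members
    }
    return ConformationTyping(matrix=matrix, threshold=threshold, labels=labels)
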