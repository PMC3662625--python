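"""Ribose pucker and ligand-dihedral geometry.

The five endocyclic torsions nu0..nu4 of the furanose ring are reduced to the
Altona-Sundaralingam pseudorotation pair: phase angle P (0-360 deg, which ring
atoms pucker out of plane) and amplitude Vmax (the maximum endocyclic torsion,
how far out of plane). With nu2 as the reference torsion,

    tan P = ((nu4 + nu1) - (nu3 + nu0)) / (2 * nu2 * (sin 36 + sin 72))
    Vmax  = nu2 / cos P

and each torsion satisfies nu_j = Vmax * cos(P + 144*(j-2)).

On top of the pucker the overall extended/folded shape of SAM and SAH is
described by three dihedrals: chi (C4-N9-C1'-O4', base orientation about the
glycosidic bond), gamma (O3'-C4'-C5'-SD) and delta (C4'-C5'-SD-CG, the
methionine/homocysteine arm). Ligands whose mean B-factor exceeds 80 A^2 are
flagged as conformationally unreliable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structio import LigandInstance, RIBOSE_RING_ATOMS

__all__ = [
    "DihedralError",
    "PuckerResult",
    "LigandDihedrals",
    "ReliabilityFlag",
    "dihedral",
    "endocyclic_torsions",
    "pseudorotation",
    "conformer_name",
    "analyze_pucker",
    "ligand_dihedrals",
    "reliability",
    "B_FACTOR_CUTOFF",
    "PLANARITY_CUTOFF",
]

#: Mean ligand B-factor above which the conformation is considered unreliable.
B_FACTOR_CUTOFF = 80.0

#: Max |nu_j| below which the ring is treated as planar (pucker undefined).
PLANARITY_CUTOFF = 1.0

# Envelope labels at the odd multiples of 18 degrees on the pseudorotation
# wheel; each covers the surrounding 36-degree arc (nearest-midpoint naming).
_WHEEL = {
    18: "C3'-endo",
    54: "C4'-exo",
    90: "O4'-endo",
    126: "C1'-exo",
    162: "C2'-endo",
    198: "C3'-exo",
    234: "C4'-endo",
    270: "O4'-exo",
    306: "C1'-endo",
    342: "C2'-exo",
}


class DihedralError(ValueError):
    """Raised for degenerate four-point configurations."""


@dataclass
class PuckerResult:
    """Pseudorotation analysis of one furanose ring."""

    nu: tuple[float, float, float, float, float]
    P: float  # degrees in [0, 360)
    Vmax: float  # degrees, >= 0
    conformer: str
    defined: bool

    @property
    def P_signed(self) -> float:
        """P mapped to (-180, 180] (tables that report negative phases)."""
        return _wrap_signed(self.P)


@dataclass
class LigandDihedrals:
    """chi/gamma/delta torsions; None where defining atoms are missing."""

    chi: float | None
    gamma: float | None
    delta: float | None


@dataclass
class ReliabilityFlag:
    mean_b: float
    flagged: bool


def _wrap_signed(angle: float) -> float:
    """Wrap degrees into (-180, 180]."""
    a = math.fmod(angle, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


def dihedral(a, b, c, d) -> float:
    """Signed torsion angle a-b-c-d in degrees, IUPAC convention, (-180, 180].

    Positive when, looking down b->c, the far bond c->d is rotated clockwise
    from the near bond b->a.
    """
    a, b, c, d = (np.asarray(p, dtype=float) for p in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n2 = np.linalg.norm(b2)
    if n2 < 1e-9:
        raise DihedralError("central bond has zero length")
    v1 = np.cross(b1, b2)
    v2 = np.cross(b2, b3)
    if np.linalg.norm(v1) < 1e-9 or np.linalg.norm(v2) < 1e-9:
        raise DihedralError("collinear points: torsion undefined")
    x = float(np.dot(v1, v2))
    y = float(np.dot(np.cross(v1, b2 / n2), v2))
    ang = math.degrees(math.atan2(y, x))
    return _wrap_signed(ang)


def endocyclic_torsions(ring_coords: np.ndarray) -> tuple[float, ...]:
    """nu0..nu4 for ring coordinates ordered (C1', C2', C3', C4', O4').

    nu0 = C4'-O4'-C1'-C2', nu1 = O4'-C1'-C2'-C3', nu2 = C1'-C2'-C3'-C4',
    nu3 = C2'-C3'-C4'-O4', nu4 = C3'-C4'-O4'-C1'.
    """
    ring_coords = np.asarray(ring_coords, dtype=float)
    if ring_coords.shape != (5, 3):
        raise ValueError("expected five ring atoms (C1',C2',C3',C4',O4')")
    c1, c2, c3, c4, o4 = ring_coords
    return (
        dihedral(c4, o4, c1, c2),
        dihedral(o4, c1, c2, c3),
        dihedral(c1, c2, c3, c4),
        dihedral(c2, c3, c4, o4),
        dihedral(c3, c4, o4, c1),
    )


def ring_coords_from_ligand(lig: LigandInstance) -> np.ndarray:
    if not lig.complete_ribose:
        raise ValueError(f"{lig.instance_id}: incomplete ribose ring")
    return lig.coords(RIBOSE_RING_ATOMS)


def pseudorotation(nu) -> PuckerResult:
    """Reduce five endocyclic torsions to (P, Vmax) and a wheel name.

    Near-planar rings (max |nu_j| < 1 degree) give ``defined=False`` and the
    label "planar" rather than an error.
    """
    nu = tuple(float(v) for v in nu)
    if len(nu) != 5 or not all(math.isfinite(v) for v in nu):
        raise ValueError("five finite torsions required")
    if max(abs(v) for v in nu) < PLANARITY_CUTOFF:
        return PuckerResult(nu=nu, P=0.0, Vmax=0.0, conformer="planar", defined=False)
    nu0, nu1, nu2, nu3, nu4 = nu
    denom_scale = 2.0 * (math.sin(math.radians(36.0)) + math.sin(math.radians(72.0)))
    y = (nu4 + nu1) - (nu3 + nu0)
    x = nu2 * denom_scale
    # atan2 places P so that Vmax = nu2/cos(P) is non-negative directly
    P = math.degrees(math.atan2(y, x)) % 360.0
    cosP = math.cos(math.radians(P))
    if abs(cosP) > 1e-8:
        vmax = nu2 / cosP
    else:  # nu2 ~ 0: amplitude carried entirely by the sine term
        vmax = y / (denom_scale * math.sin(math.radians(P)))
    if vmax < 0:  # numerically possible only at the cos(P) ~ 0 boundary
        vmax = -vmax
        P = (P + 180.0) % 360.0
    return PuckerResult(nu=nu, P=P, Vmax=vmax, conformer=conformer_name(P), defined=True)


def conformer_name(P: float) -> str:
    """Envelope label by nearest 18-degree-odd midpoint of the wheel."""
    P = P % 360.0
    best = min(_WHEEL, key=lambda m: min(abs(P - m), 360.0 - abs(P - m)))
    return _WHEEL[best]


def analyze_pucker(lig: LigandInstance) -> PuckerResult:
    """Full pucker analysis of a ligand's ribose ring."""
    return pseudorotation(endocyclic_torsions(ring_coords_from_ligand(lig)))


_DIHEDRAL_DEFS = {
    "chi": ("C4", "N9", "C1'", "O4'"),
    "gamma": ("O3'", "C4'", "C5'", "SD"),
    "delta": ("C4'", "C5'", "SD", "CG"),
}


def ligand_dihedrals(lig: LigandInstance) -> LigandDihedrals:
    """chi/gamma/delta for a SAM or SAH instance.

    Angles whose defining atoms are absent come back as None (per-angle
    degradation, not a hard error). SAH uses the same CG of the homocysteine
    arm for delta.
    """
    values: dict[str, float | None] = {}
    for key, names in _DIHEDRAL_DEFS.items():
        atoms = [lig.atom(n) for n in names]
        if any(a is None for a in atoms):
            values[key] = None
            continue
        try:
            values[key] = dihedral(*(a.coords for a in atoms))
        except DihedralError:
            values[key] = None
    return LigandDihedrals(**values)


def reliability(lig: LigandInstance, cutoff: float = B_FACTOR_CUTOFF) -> ReliabilityFlag:
    """Mean ligand B-factor; flagged iff strictly above ``cutoff`` (80 A^2)."""
    if not lig.atoms:
        raise ValueError("ligand has no atoms")
    mean_b = lig.mean_b_factor()
    return ReliabilityFlag(mean_b=mean_b, flagged=mean_b > cutoff)
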