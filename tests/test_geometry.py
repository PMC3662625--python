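"""Torsion primitives, pseudorotation analysis, dihedral recovery, B-policy."""

import math

import numpy as np
import pytest

from ligfam.geometry import (
    DihedralError,
    analyze_pucker,
    conformer_name,
    dihedral,
    endocyclic_torsions,
    ligand_dihedrals,
    pseudorotation,
    reliability,
)
from ligfam.structio import LigandInstance
from ligfam.synthconf import ConformerSpec, make_conformer, make_ribose

RING = ("C1'", "C2'", "C3'", "C4'", "O4'")


def _ring_array(ring: dict) -> np.ndarray:
    return np.array([ring[n] for n in RING])


@pytest.mark.parametrize(
    "d,expected",
    [((1, -1, 0), 180.0), ((1, 1, 0), 0.0), ((1, 0, 1), -90.0)],
)
def test_dihedral_sign_convention(d, expected):
    """Planar anti is 180, syn is 0, and the out-of-plane case is signed per
    the clockwise-positive (IUPAC) convention."""
    assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), d) == pytest.approx(expected)


def test_dihedral_degenerate_raises():
    with pytest.raises(DihedralError):
        dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))  # collinear a,b,c
    with pytest.raises(DihedralError):
        dihedral((0, 1, 0), (0, 0, 0), (0, 0, 0), (1, 0, 0))  # zero central bond


def test_planar_pentagon_has_zero_torsions():
    pent = np.array(
        [[math.cos(2 * math.pi * k / 5), math.sin(2 * math.pi * k / 5), 0.0] for k in range(5)]
    )
    assert np.allclose(endocyclic_torsions(pent), 0.0, atol=1e-9)


def test_generated_ring_matches_closed_form():
    """A ring built at (P=18, Vmax=40) shows nu = Vmax*cos(P + 144*(j-2))."""
    nu = endocyclic_torsions(_ring_array(make_ribose(18.0, 40.0)))
    expected = [40.0 * math.cos(math.radians(18.0 + 144.0 * (j - 2))) for j in range(5)]
    assert np.allclose(nu, expected, atol=0.5)
    # spec'd reference values
    assert np.allclose(nu, (0.0, -23.5, 38.0, -38.0, 23.5), atol=0.5)


def test_mirror_ring_negates_torsions():
    ring = _ring_array(make_ribose(54.0, 30.0))
    mirrored = ring * np.array([1.0, 1.0, -1.0])
    assert np.allclose(
        endocyclic_torsions(mirrored), [-v for v in endocyclic_torsions(ring)], atol=1e-9
    )


def test_pseudorotation_reference_case():
    res = pseudorotation((0.0, -23.5, 38.0, -38.0, 23.5))
    assert res.defined
    assert res.P == pytest.approx(18.0, abs=0.5)
    assert res.Vmax == pytest.approx(40.0, abs=0.5)
    assert res.conformer == "C3'-endo"
    # internal consistency: nu2 = Vmax * cos(P)
    assert res.nu[2] == pytest.approx(res.Vmax * math.cos(math.radians(res.P)), abs=0.01)


def test_planar_ring_pucker_undefined():
    res = pseudorotation((0.0, 0.0, 0.0, 0.0, 0.0))
    assert not res.defined and res.conformer == "planar"


@pytest.mark.parametrize("P", range(0, 360, 18))
@pytest.mark.parametrize("Vmax", [10.0, 25.0, 40.0, 55.0])
def test_pucker_recovery_over_wheel(P, Vmax):
    """Generator -> analysis round-trip recovers (P, Vmax) within 1 degree."""
    res = pseudorotation(endocyclic_torsions(_ring_array(make_ribose(float(P), Vmax))))
    dP = abs((res.P - P + 180.0) % 360.0 - 180.0)
    assert dP < 1.0
    assert abs(res.Vmax - Vmax) < 1.0


def test_pseudorotation_wave_fits_generated_torsions():
    """nu_j ~ Vmax*cos(P + 144*(j-2)) with small RMS residual."""
    for P, V in ((100.0, 35.0), (250.0, 20.0), (342.0, 55.0)):
        nu = endocyclic_torsions(_ring_array(make_ribose(P, V)))
        res = pseudorotation(nu)
        fitted = [res.Vmax * math.cos(math.radians(res.P + 144.0 * (j - 2))) for j in range(5)]
        rms = math.sqrt(np.mean((np.array(nu) - fitted) ** 2))
        assert rms < 2.0


@pytest.mark.parametrize(
    "P,name",
    [(18.0, "C3'-endo"), (126.0, "C1'-exo"), (162.0, "C2'-endo"),
     (90.0, "O4'-endo"), (198.0, "C3'-exo"), (0.0, "C3'-endo"), (350.0, "C2'-exo")],
)
def test_conformer_wheel_names(P, name):
    assert conformer_name(P) == name


def test_ligand_dihedral_recovery():
    spec = ConformerSpec(P=126.0, Vmax=38.0, chi=-60.0, gamma=75.0, delta=180.0)
    dh = ligand_dihedrals(make_conformer(spec))
    assert dh.chi == pytest.approx(-60.0, abs=0.5)
    assert dh.gamma == pytest.approx(75.0, abs=0.5)
    assert dh.delta == pytest.approx(180.0, abs=0.5)


def test_missing_sd_degrades_gamma_delta_only(sam_conformer):
    pruned = LigandInstance(
        ligand_code="SAM",
        structure_id="X",
        chain="L",
        residue_number=1,
        atoms=[a for a in sam_conformer.atoms if a.name != "SD"],
    )
    dh = ligand_dihedrals(pruned)
    assert dh.gamma is None and dh.delta is None
    assert dh.chi is not None


def test_rigid_motion_invariance(sam_conformer):
    """Rotation + translation of the complex leaves all angles unchanged."""
    from scipy.spatial.transform import Rotation

    R = Rotation.from_euler("xyz", [17.0, -48.0, 103.0], degrees=True).as_matrix()
    t = np.array([5.0, -3.0, 12.0])
    moved = LigandInstance(
        ligand_code="SAM",
        structure_id="X",
        chain="L",
        residue_number=1,
        atoms=[
            type(a)(
                name=a.name, element=a.element, residue_name=a.residue_name,
                residue_number=a.residue_number, insertion_code=a.insertion_code,
                chain=a.chain, coords=R @ a.coords + t, b_factor=a.b_factor, het=a.het,
            )
            for a in sam_conformer.atoms
        ],
    )
    p0, p1 = analyze_pucker(sam_conformer), analyze_pucker(moved)
    assert p1.P == pytest.approx(p0.P, abs=1e-6)
    assert p1.Vmax == pytest.approx(p0.Vmax, abs=1e-6)
    d0, d1 = ligand_dihedrals(sam_conformer), ligand_dihedrals(moved)
    for k in ("chi", "gamma", "delta"):
        assert getattr(d1, k) == pytest.approx(getattr(d0, k), abs=1e-6)


def test_chirality_flip_maps_P_to_complement(sam_conformer):
    flipped = LigandInstance(
        ligand_code="SAM",
        structure_id="X",
        chain="L",
        residue_number=1,
        atoms=[
            type(a)(
                name=a.name, element=a.element, residue_name=a.residue_name,
                residue_number=a.residue_number, insertion_code=a.insertion_code,
                chain=a.chain, coords=a.coords * np.array([1.0, 1.0, -1.0]),
                b_factor=a.b_factor, het=a.het,
            )
            for a in sam_conformer.atoms
        ],
    )
    # negating every nu_j shifts the cosine wave by half a turn: P -> P + 180
    # (an envelope and its mirror are endo/exo partners), Vmax unchanged
    p0, p1 = analyze_pucker(sam_conformer), analyze_pucker(flipped)
    assert p1.P == pytest.approx((p0.P + 180.0) % 360.0, abs=1e-6)
    assert p1.Vmax == pytest.approx(p0.Vmax, abs=1e-6)
    d0, d1 = ligand_dihedrals(sam_conformer), ligand_dihedrals(flipped)
    for k in ("chi", "gamma", "delta"):
        diff = (getattr(d1, k) + getattr(d0, k) + 180.0) % 360.0 - 180.0
        assert diff == pytest.approx(0.0, abs=1e-6)  # negated, mod 360


def _with_bfactors(lig, values):
    atoms = []
    for a, b in zip(lig.atoms, values):
        atoms.append(
            type(a)(
                name=a.name, element=a.element, residue_name=a.residue_name,
                residue_number=a.residue_number, insertion_code=a.insertion_code,
                chain=a.chain, coords=a.coords, b_factor=b, het=a.het,
            )
        )
    return LigandInstance(lig.ligand_code, lig.structure_id, lig.chain, lig.residue_number, atoms)


@pytest.mark.parametrize(
    "b_values,flagged",
    [
        ([50.0] * 27, False),
        ([79.0, 81.0] + [80.0] * 25, False),  # mean exactly 80: strict > keeps it
        ([80.2] * 27, True),
    ],
)
def test_b_factor_flag_is_strictly_greater_than_80(sam_conformer, b_values, flagged):
    lig = _with_bfactors(sam_conformer, b_values)
    rel = reliability(lig)
    assert rel.flagged is flagged


def test_b_factor_mean_value(sam_conformer):
    lig = _with_bfactors(sam_conformer, [50.0] * 27)
    assert reliability(lig).mean_b == pytest.approx(50.0)
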