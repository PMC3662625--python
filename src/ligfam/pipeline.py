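"""End-to-end orchestration: structures in, machine-readable report out.

``analyze`` runs the full per-structure chain (parse -> ligand extraction ->
pucker/dihedrals/B-factor reliability -> hydrogen bonds -> optional sheet
topology) and, across structures, conformation typing over all unflagged
ligands. ``batch_rules`` builds one site rule per family alignment. Reports
are deterministic: identical inputs and configuration yield byte-identical
JSON (sorted keys), and every skipped entity is logged with a reason.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .contacts import DEFAULT_HBOND_CUTOFF, hydrogen_bonds
from .geometry import (
    B_FACTOR_CUTOFF,
    analyze_pucker,
    ligand_dihedrals,
    reliability,
)
from .siterules import FamilyAlignment, build_rule
from .structio import ParseError, extract_ligands, read_pdb
from .superpose import DEFAULT_TYPING_THRESHOLD, assign_types, rmsd_matrix
from .topology import (
    TopologyError,
    assign_ligfold,
    build_sheet,
    read_dssp,
    read_ssa_tsv,
)

logger = logging.getLogger("ligfam")

__all__ = ["AnalysisConfig", "AnalysisReport", "analyze", "batch_rules"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Every numeric policy of the pipeline, in one place."""

    b_factor_cutoff: float = B_FACTOR_CUTOFF
    hbond_cutoff: float = DEFAULT_HBOND_CUTOFF
    typing_threshold: float = DEFAULT_TYPING_THRESHOLD
    typing_fit_atoms: str = "ribose"
    typing_rmsd_atoms: str = "all"
    conservation_mode: str = "strict"
    ligand_codes: tuple[str, ...] = ("SAM", "SAH")


@dataclass
class AnalysisReport:
    structures: dict = field(default_factory=dict)
    typing: dict | None = None
    skipped: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _round(x, ndigits=3):
    return None if x is None else round(float(x), ndigits)


def analyze(
    structure_paths: list[str | Path],
    ssa_paths: dict[str, str | Path] | None = None,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Run the ligand-centric analysis over a set of PDB files.

    ``ssa_paths`` maps structure id (upper-case file stem) to a DSSP file or
    sidecar TSV for topology assignment; structures without an entry simply
    have no topology section. Per-structure failures are logged and recorded
    in ``skipped``; only zero parsable structures is a global failure.
    """
    config = config or AnalysisConfig()
    ssa_paths = {k.upper(): v for k, v in (ssa_paths or {}).items()}
    report = AnalysisReport(
        metadata={
            "version": __version__,
            "config": dataclasses.asdict(config),
            "n_inputs": len(structure_paths),
        }
    )
    all_ligands = []
    for path in structure_paths:
        try:
            structure = read_pdb(path)
        except ParseError as exc:
            logger.warning("skipping %s: %s", path, exc)
            report.skipped.append(f"{path}: {exc}")
            continue
        entry: dict = {"ligands": [], "topology": None}
        for lig in extract_ligands(structure, set(config.ligand_codes)):
            rel = reliability(lig, config.b_factor_cutoff)
            lig_entry = {
                "instance_id": lig.instance_id,
                "ligand_code": lig.ligand_code,
                "chain": lig.chain,
                "residue_number": lig.residue_number,
                "n_atoms": len(lig.atoms),
                "complete_ribose": lig.complete_ribose,
                "mean_b": _round(rel.mean_b, 2),
                "flagged": rel.flagged,
                "pucker": None,
                "dihedrals": None,
                "contacts": [],
            }
            if lig.complete_ribose:
                pk = analyze_pucker(lig)
                lig_entry["pucker"] = {
                    "nu": [_round(v) for v in pk.nu],
                    "P": _round(pk.P),
                    "P_signed": _round(pk.P_signed),
                    "Vmax": _round(pk.Vmax),
                    "conformer": pk.conformer,
                    "defined": pk.defined,
                }
            else:
                report.skipped.append(f"{lig.instance_id}: incomplete ribose, pucker skipped")
            dh = ligand_dihedrals(lig)
            lig_entry["dihedrals"] = {
                "chi": _round(dh.chi),
                "gamma": _round(dh.gamma),
                "delta": _round(dh.delta),
            }
            lig_entry["contacts"] = [
                {
                    "ligand_atom": c.ligand_atom,
                    "protein_atom": c.protein_atom,
                    "chain": c.chain,
                    "residue_number": c.residue_number,
                    "residue_name": c.residue_name,
                    "distance": _round(c.distance, 2),
                }
                for c in hydrogen_bonds(lig, structure, config.hbond_cutoff)
            ]
            entry["ligands"].append(lig_entry)
            all_ligands.append(lig)
        sid = structure.structure_id
        if sid in ssa_paths:
            ssa_file = Path(ssa_paths[sid])
            try:
                ssa = (
                    read_dssp(ssa_file)
                    if ssa_file.suffix.lower() == ".dssp"
                    else read_ssa_tsv(ssa_file)
                )
                sheet = build_sheet(ssa)
                assignment = assign_ligfold(sheet)
                entry["topology"] = {
                    "order_string": sheet.order_string,
                    "n_core": sheet.n_core,
                    "ligfold_id": assignment.ligfold_id,
                    "subclass": assignment.subclass,
                    "novel": assignment.novel,
                    "ambiguous_reading": assignment.ambiguous_reading,
                }
            except TopologyError as exc:
                logger.warning("topology failed for %s: %s", sid, exc)
                report.skipped.append(f"{sid}: topology failed: {exc}")
        report.structures[sid] = entry
    if not report.structures:
        raise ParseError("no structures could be parsed")
    unflagged = [
        lig
        for lig in all_ligands
        if not reliability(lig, config.b_factor_cutoff).flagged and lig.complete_ribose
    ]
    if len(unflagged) >= 2:
        matrix = rmsd_matrix(
            unflagged,
            atom_set=config.typing_fit_atoms,
            rmsd_atom_set=config.typing_rmsd_atoms,
            exclude_flagged=True,
            b_factor_cutoff=config.b_factor_cutoff,
        )
        typing = assign_types(matrix, config.typing_threshold)
        report.typing = {
            "threshold": config.typing_threshold,
            "labels": dict(sorted(typing.labels.items())),
            "n_ligands": len(matrix.ids),
        }
    for lig in all_ligands:
        if reliability(lig, config.b_factor_cutoff).flagged:
            report.skipped.append(f"{lig.instance_id}: mean B > {config.b_factor_cutoff}, excluded from typing")
    return report


def batch_rules(
    families: list[tuple[FamilyAlignment, list[int]]],
    mode: str = "strict",
) -> tuple[dict[str, str], str]:
    """One site-rule JSON per family plus a summary TSV.

    ``families`` pairs each alignment with the representative residue numbers
    at hydrogen-bond distance from the ligand. Families without contacts are
    skipped with a warning. Returns ({family_id: rule_json}, summary_tsv).
    """
    rules: dict[str, str] = {}
    summary = ["family_id\tmode\tn_positions\tn_unmapped"]
    for aln, contact_resnums in families:
        if not contact_resnums:
            logger.warning("family %s has no contacts; skipped", aln.family_id)
            continue
        rule = build_rule(aln, contact_resnums, mode=mode)
        rules[aln.family_id] = rule.to_json()
        summary.append(
            f"{aln.family_id}\t{mode}\t{len(rule.positions)}\t{len(rule.unmapped_contacts)}"
        )
    return rules, "\n".join(summary) + "\n"
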