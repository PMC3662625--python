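"""Family site rules, rule propagation, and conserved MTase sequence motifs.

A site rule anchors a family's conserved SAM/SAH-binding residues to one
representative structure: positions that both hydrogen-bond the ligand in the
representative and are conserved across every member of the family's
alignment. Conservation comes in two modes: ``strict`` (one residue type in
the whole column, no gaps) and ``conservative`` (the column stays within one
substitution group, e.g. D/E). Rules are propagated to structure-less
sequences by global pairwise alignment to the representative (BLOSUM62,
affine gaps); a query is a positive match only when every rule position is
satisfied.

Motif detection covers the six conserved Rossmann-fold MTase motifs: the
glycine-rich Motif I (G/A-x-G/A-x-G/A preceded by an acidic residue at -2 and
hydrophobics at -3/-4) is purely sequence-based; Motifs II, III, IV and VI
need strand annotations; Motif V is a region report with no residue pattern.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "FamilyAlignment",
    "SiteRule",
    "RulePosition",
    "MotifHit",
    "PropagationResult",
    "conserved_columns",
    "build_rule",
    "propagate",
    "detect_motifs",
    "read_family_alignment",
    "SUBSTITUTION_GROUPS",
]

#: Dayhoff-style conservative substitution groups.
SUBSTITUTION_GROUPS: tuple[frozenset, ...] = (
    frozenset("DE"),
    frozenset("KR"),
    frozenset("ST"),
    frozenset("NQ"),
    frozenset("ILVM"),
    frozenset("FYW"),
    frozenset("AG"),
)

GAP = "-"
_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _group_of(residue: str) -> frozenset:
    for g in SUBSTITUTION_GROUPS:
        if residue in g:
            return g
    return frozenset(residue)


@dataclass
class FamilyAlignment:
    """An aligned family with one designated representative row."""

    family_id: str
    sequences: dict[str, str]  # id -> aligned sequence (equal lengths)
    representative_id: str

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal length")
        if self.representative_id not in self.sequences:
            raise ValueError(f"representative {self.representative_id} not in alignment")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def representative_row(self) -> str:
        return self.sequences[self.representative_id]

    def column(self, col: int) -> list[str]:
        return [s[col] for s in self.sequences.values()]

    def column_to_resnum(self) -> dict[int, int]:
        """0-based alignment column -> 1-based representative residue number."""
        mapping = {}
        num = 0
        for col, ch in enumerate(self.representative_row):
            if ch != GAP:
                num += 1
                mapping[col] = num
        return mapping

    def resnum_to_column(self) -> dict[int, int]:
        return {num: col for col, num in self.column_to_resnum().items()}

    def representative_sequence(self) -> str:
        return self.representative_row.replace(GAP, "")


@dataclass(frozen=True)
class RulePosition:
    residue_number: int  # representative numbering, 1-based
    residue: str  # one-letter code
    allowed: str  # residues satisfying the position, e.g. "DE"
    feature: str = "SAM binding"


@dataclass
class SiteRule:
    family_id: str
    representative_id: str
    mode: str  # strict | conservative
    positions: list[RulePosition]
    unmapped_contacts: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": "1.0",
                "family_id": self.family_id,
                "representative_id": self.representative_id,
                "mode": self.mode,
                "positions": [
                    {
                        "residue_number": p.residue_number,
                        "residue": p.residue,
                        "allowed": p.allowed,
                        "feature": p.feature,
                    }
                    for p in self.positions
                ],
                "unmapped_contacts": self.unmapped_contacts,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class MotifHit:
    motif: str  # I..VI
    positions: list[int]  # 0-based sequence positions
    residues: str
    note: str = ""


@dataclass
class PropagationResult:
    query_id: str
    positive: bool
    annotations: list[tuple[int, str, str]]  # (query position 1-based, residue, feature)
    diagnostics: list[str]


def read_family_alignment(path, family_id: str, representative_id: str) -> FamilyAlignment:
    """Load an aligned FASTA file as a :class:`FamilyAlignment`."""
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"{path}: no sequences")
    return FamilyAlignment(family_id=family_id, sequences=records, representative_id=representative_id)


def conserved_columns(aln: FamilyAlignment, mode: str = "strict") -> dict[int, str]:
    """Classify every column as strict / conservative / not_conserved.

    A gap anywhere in the column disqualifies it. ``mode`` does not change the
    labels (all three are always computed); it matters downstream when a rule
    decides which labels count as conserved.
    """
    if len(aln.sequences) < 2:
        raise ValueError("need at least two sequences")
    if mode not in ("strict", "conservative"):
        raise ValueError(f"unknown mode {mode!r}")
    status = {}
    for col in range(aln.n_columns):
        residues = aln.column(col)
        if GAP in residues:
            status[col] = "not_conserved"
        elif len(set(residues)) == 1:
            status[col] = "strict"
        elif any(all(r in g for r in residues) for g in SUBSTITUTION_GROUPS):
            status[col] = "conservative"
        else:
            status[col] = "not_conserved"
    return status


def _accepted_labels(mode: str) -> set[str]:
    return {"strict"} if mode == "strict" else {"strict", "conservative"}


def build_rule(
    aln: FamilyAlignment,
    contact_residue_numbers: list[int],
    mode: str = "strict",
    feature: str = "SAM binding",
) -> SiteRule:
    """Intersect ligand-contacting representative positions with conservation.

    ``contact_residue_numbers`` are representative residue numbers (e.g. the
    residues at hydrogen-bond distance from the ligand). Contacts that do not
    map onto an alignment column are reported in ``unmapped_contacts``. An
    empty rule is valid (warned about, not an error).
    """
    import warnings

    status = conserved_columns(aln, mode)
    res2col = aln.resnum_to_column()
    accepted = _accepted_labels(mode)
    positions = []
    unmapped = []
    for resnum in sorted(set(contact_residue_numbers)):
        col = res2col.get(resnum)
        if col is None:
            unmapped.append(resnum)
            continue
        if status[col] not in accepted:
            continue
        residue = aln.representative_row[col]
        if status[col] == "strict":
            allowed = residue
        else:
            allowed = "".join(sorted(_group_of(residue)))
        positions.append(RulePosition(resnum, residue, allowed, feature))
    if not positions:
        warnings.warn(f"{aln.family_id}: no conserved contact columns; empty rule")
    if unmapped:
        warnings.warn(f"{aln.family_id}: unmapped contact residues {unmapped}")
    return SiteRule(
        family_id=aln.family_id,
        representative_id=aln.representative_id,
        mode=mode,
        positions=positions,
        unmapped_contacts=unmapped,
    )


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def propagate(rule: SiteRule, aln: FamilyAlignment, query: str, query_id: str = "query") -> PropagationResult:
    """Check a structure-less sequence against a family rule.

    The query is globally aligned to the representative sequence; rule
    positions are mapped through the alignment. A positive match requires
    every rule position to be present and allowed; otherwise per-position
    diagnostics say what failed, and no annotation is emitted.
    """
    query = query.strip().upper()
    bad = sorted(set(query) - _AA)
    if bad:
        raise ValueError(f"non-amino-acid characters in query: {bad}")
    rep = aln.representative_sequence()
    aligner = _make_aligner()
    alignment = aligner.align(rep, query)[0]
    # rep residue number (1-based) -> query position (1-based)
    rep2query: dict[int, int] = {}
    for (rs, re_), (qs, qe) in zip(*alignment.aligned):
        for offset in range(int(re_ - rs)):
            rep2query[int(rs) + offset + 1] = int(qs) + offset + 1
    annotations = []
    diagnostics = []
    positive = True
    for pos in rule.positions:
        qpos = rep2query.get(pos.residue_number)
        if qpos is None:
            positive = False
            diagnostics.append(
                f"position {pos.residue_number} ({pos.residue}) unaligned in query"
            )
            continue
        qres = query[qpos - 1]
        if qres in pos.allowed:
            annotations.append((qpos, qres, pos.feature))
        else:
            positive = False
            diagnostics.append(
                f"position {pos.residue_number}: expected [{pos.allowed}], found {qres} at query {qpos}"
            )
    if not positive:
        annotations = []
    return PropagationResult(
        query_id=query_id, positive=positive, annotations=annotations, diagnostics=diagnostics
    )


# ---------------------------------------------------------------------------
# motifs

_HYDROPHOBIC_I = set("LVIYAF")  # observed at -3/-4 of the glycine-rich loop
_HYDROPHOBIC_II = set("IVFWY")
_ACIDIC = set("DE")
_MOTIF1_CORE = re.compile(r"(?=([GA].[GA].[GA]))")


def detect_motifs(
    seq: str, strands: dict[int, tuple[int, int]] | None = None
) -> list[MotifHit]:
    """Scan a sequence for the Rossmann-fold MTase motifs.

    ``strands`` maps strand number (1-based, N->C) to a 0-based half-open
    (start, end) span in the sequence. Motif I needs no annotations; Motifs
    II, III, IV and VI are skipped with a notice when annotations are absent;
    Motif V is reported as a region only (it has no conserved residues).
    """
    seq = seq.strip().upper()
    if len(seq) < 9:
        raise ValueError("sequence too short for motif analysis")
    hits: list[MotifHit] = []

    for m in _MOTIF1_CORE.finditer(seq):
        start = m.start()
        if start < 4:
            continue
        if (
            seq[start - 2] in _ACIDIC
            and seq[start - 3] in _HYDROPHOBIC_I
            and seq[start - 4] in _HYDROPHOBIC_I
        ):
            positions = list(range(start - 4, start + 5))
            hits.append(MotifHit("I", positions, seq[start - 4 : start + 5]))

    if strands is None:
        for motif in ("II", "III", "IV", "VI"):
            hits.append(MotifHit(motif, [], "", note="skipped: no strand annotations"))
        return hits

    # Motif II: acidic residue mid-strand-II with hydrophobics at -3/-4.
    span = strands.get(2)
    if span:
        s, e = span
        for i in range(s + 1, e - 1):  # interior of the strand
            if seq[i] in _ACIDIC and i >= 4 and seq[i - 3] in _HYDROPHOBIC_II and seq[i - 4] in _HYDROPHOBIC_II:
                hits.append(MotifHit("II", [i - 4, i - 3, i], seq[i - 4 : i + 1]))
                break

    # Motif III: hydrophilic residue at strand-III N-terminus; optional G at C-term.
    span = strands.get(3)
    if span:
        s, e = span
        for i in (s, s + 1):
            if i < e and seq[i] in set("DSTN"):
                note = "G at C-terminus" if seq[e - 1] == "G" else ""
                hits.append(MotifHit("III", [i], seq[i], note=note))
                break

    # Motif IV: acidic near strand-IV N-terminus with V/I at +2.
    span = strands.get(4)
    if span:
        s, e = span
        for i in range(s, min(s + 3, e)):
            if seq[i] in _ACIDIC and i + 2 < len(seq) and seq[i + 2] in "VI":
                hits.append(MotifHit("IV", [i, i + 2], seq[i] + seq[i + 2]))
                break

    # Motif V: the helix between strands IV and V; region report only.
    if strands.get(4) and strands.get(5):
        region = list(range(strands[4][1], strands[5][0]))
        hits.append(MotifHit("V", region, "", note="region only; no conserved residues"))

    # Motif VI: G at strand-V start with hydrophobics at +2/+3.
    span = strands.get(5)
    if span:
        s, e = span
        if seq[s] == "G" and s + 3 < len(seq) and seq[s + 2] in _HYDROPHOBIC_I and seq[s + 3] in _HYDROPHOBIC_I:
            hits.append(MotifHit("VI", [s, s + 2, s + 3], seq[s] + seq[s + 2] + seq[s + 3]))

    return hits
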