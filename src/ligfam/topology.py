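"""Beta-sheet strand-order topology and LigFold catalog assignment.

Secondary structure is an input (a DSSP file or a simple sidecar TSV), never
computed here. Strands are numbered 1..n by N->C sequence order; beta-ladder
pairs between strands define an adjacency graph whose linearization is the
left-to-right spatial strand order of the sheet, e.g. "3214567" for the
classical Rossmann-fold MTase arrangement. The order string is matched (in
both reading directions) against the packaged 14-entry LigFold catalog of
fold-type-I sub-classes; unmatched sheets are reported as NOVEL with nearest
catalog entries by edit distance. Structures with two SAM-binding sheets are
scanned per domain and may combine into a dual-domain class (e.g. one sheet
of each major arrangement).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx

__all__ = [
    "StrandElement",
    "LadderPair",
    "SecondaryStructureAnnotation",
    "SheetTopology",
    "LigFoldCatalog",
    "FoldRegistry",
    "TopologyError",
    "BarrelNotSupportedError",
    "build_sheet",
    "assign_ligfold",
    "dual_domain_scan",
    "read_ssa_tsv",
    "read_dssp",
    "load_ligfold_catalog",
    "load_fold_registry",
]


class TopologyError(ValueError):
    """Ladder graph cannot be linearized into a single sheet."""


class BarrelNotSupportedError(TopologyError):
    """Cyclic ladder graph (beta barrel)."""


@dataclass(frozen=True)
class StrandElement:
    chain: str
    start: int
    end: int
    kind: str = "strand"  # strand | helix
    sheet_id: str = "A"


@dataclass(frozen=True)
class LadderPair:
    strand_i: int  # 1-based N->C strand numbers
    strand_j: int
    orientation: str = "parallel"  # parallel | antiparallel


@dataclass
class SecondaryStructureAnnotation:
    elements: list[StrandElement]
    ladders: list[LadderPair]

    def __post_init__(self) -> None:
        per_chain: dict[str, list[StrandElement]] = {}
        for el in self.elements:
            if el.kind == "strand":
                per_chain.setdefault(el.chain, []).append(el)
        for els in per_chain.values():
            els = sorted(els, key=lambda e: e.start)
            for prev, nxt in zip(els, els[1:]):
                if nxt.start <= prev.end:
                    raise ValueError(
                        f"overlapping strands {prev} / {nxt} in chain {prev.chain}"
                    )

    @property
    def strands(self) -> list[StrandElement]:
        """Strand elements in N->C order (strand k is index k-1)."""
        return sorted(
            (e for e in self.elements if e.kind == "strand"),
            key=lambda e: (e.chain, e.start),
        )


@dataclass
class SheetTopology:
    core_strands: list[int]  # original N->C numbers of the core strands
    order_string: str  # canonical reading
    reverse_string: str  # the other reading direction
    antiparallel_strands: set[int] = field(default_factory=set)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_core(self) -> int:
        return len(self.core_strands)


@dataclass
class LigFoldAssignment:
    order_string: str
    ligfold_id: str | None
    subclass: str | None
    novel: bool
    matched_reading: str | None
    ambiguous_reading: bool
    nearest: list[tuple[str, str, int]] = field(default_factory=list)  # (string, id, distance)


@dataclass
class LigFoldCatalog:
    entries: dict[str, dict]  # order_string -> {ligfold_id, subclass, ...}

    def lookup(self, order_string: str) -> dict | None:
        return self.entries.get(order_string)


@dataclass
class FoldRegistry:
    entries: list[dict]  # {numeral, name, is_mtase}

    @property
    def n_mtase(self) -> int:
        return sum(1 for e in self.entries if e["is_mtase"])

    def by_numeral(self, numeral: str) -> dict:
        for e in self.entries:
            if e["numeral"] == numeral:
                return e
        raise KeyError(numeral)


def _load_data(name: str) -> dict:
    with resources.files("ligfam.data").joinpath(name).open() as fh:
        return json.load(fh)


def load_ligfold_catalog() -> LigFoldCatalog:
    """The packaged 14-entry fold-type-I strand-order catalog."""
    return LigFoldCatalog(entries=_load_data("ligfold_catalog.json")["entries"])


def load_fold_registry() -> FoldRegistry:
    """The packaged registry of the 18 SAM-binding fold types."""
    return FoldRegistry(entries=_load_data("fold_registry.json")["entries"])


def build_sheet(ssa: SecondaryStructureAnnotation) -> SheetTopology:
    """Linearize the ladder graph into a left-to-right strand order.

    Strands are numbered 1..n in N->C order. The largest ladder-connected
    component is taken as the core sheet (with a warning if strands are left
    out); its strands are renumbered 1..n_core in N->C order before the order
    string is read. Cyclic graphs (barrels) and branched graphs are rejected.
    A single isolated strand yields "1".
    """
    strands = ssa.strands
    if not strands:
        raise TopologyError("no strand elements")
    n = len(strands)
    notes: list[str] = []
    g = nx.Graph()
    g.add_nodes_from(range(1, n + 1))
    antiparallel: set[int] = set()
    for lp in ssa.ladders:
        if not (1 <= lp.strand_i <= n and 1 <= lp.strand_j <= n):
            raise TopologyError(f"ladder references undeclared strand: {lp}")
        g.add_edge(lp.strand_i, lp.strand_j)
        if lp.orientation == "antiparallel":
            antiparallel.update((lp.strand_i, lp.strand_j))
    components = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    core = sorted(components[0])
    if len(core) < n:
        msg = f"disconnected sheet: using largest component ({len(core)} of {n} strands)"
        warnings.warn(msg)
        notes.append(msg)
    sub = g.subgraph(core)
    if len(core) > 1:
        if any(True for _ in nx.cycle_basis(sub)):
            raise BarrelNotSupportedError("cyclic ladder graph (barrel) not supported")
        degrees = dict(sub.degree())
        if max(degrees.values()) > 2:
            raise TopologyError("branched ladder graph: bifurcated sheet not supported")
        ends = [v for v, d in degrees.items() if d == 1]
        path = [min(ends)]
        while len(path) < len(core):
            nbrs = [v for v in sub.neighbors(path[-1]) if v not in path]
            path.append(nbrs[0])
    else:
        path = core
    # renumber core strands 1..n_core by N->C order
    renumber = {orig: i for i, orig in enumerate(sorted(core), start=1)}
    seq = [renumber[v] for v in path]
    forward = _order_string(seq)
    backward = _order_string(seq[::-1])
    if seq[0] > seq[-1]:
        forward, backward = backward, forward
    return SheetTopology(
        core_strands=sorted(core),
        order_string=forward,
        reverse_string=backward,
        antiparallel_strands={renumber[s] for s in antiparallel if s in renumber},
        warnings=notes,
    )


def _order_string(seq: list[int]) -> str:
    return "".join(str(v) for v in seq) if max(seq) < 10 else " ".join(map(str, seq))


def _edit_distance(a: str, b: str) -> int:
    dp = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        prev, dp[0] = dp[0], i
        for j, cb in enumerate(b, start=1):
            prev, dp[j] = dp[j], min(dp[j] + 1, dp[j - 1] + 1, prev + (ca != cb))
    return dp[-1]


def assign_ligfold(
    topology: SheetTopology, catalog: LigFoldCatalog | None = None
) -> LigFoldAssignment:
    """Match a sheet's order string against the catalog.

    Both reading directions are tried. If exactly one matches, it wins; if
    both match (the catalog contains permutations that are mutual reversals),
    the reading whose first core strand has the lower number is used and the
    ambiguity is reported. No match at all yields a NOVEL assignment with the
    three nearest catalog strings by edit distance.
    """
    catalog = catalog or load_ligfold_catalog()
    fwd, bwd = topology.order_string, topology.reverse_string
    hit_f, hit_b = catalog.lookup(fwd), catalog.lookup(bwd)
    ambiguous = hit_f is not None and hit_b is not None and fwd != bwd
    if hit_f is not None:
        chosen, hit = fwd, hit_f
    elif hit_b is not None:
        chosen, hit = bwd, hit_b
    else:
        nearest = sorted(
            (
                (s, e["ligfold_id"], min(_edit_distance(fwd, s), _edit_distance(bwd, s)))
                for s, e in catalog.entries.items()
            ),
            key=lambda t: (t[2], t[0]),
        )[:3]
        return LigFoldAssignment(
            order_string=fwd,
            ligfold_id=None,
            subclass=None,
            novel=True,
            matched_reading=None,
            ambiguous_reading=False,
            nearest=nearest,
        )
    return LigFoldAssignment(
        order_string=fwd,
        ligfold_id=hit["ligfold_id"],
        subclass=hit["subclass"],
        novel=False,
        matched_reading=chosen,
        ambiguous_reading=ambiguous,
    )


@dataclass
class DualDomainResult:
    assignments: list[LigFoldAssignment]
    combined_ligfold_id: str | None
    summary: str


def dual_domain_scan(
    topologies: list[SheetTopology], catalog: LigFoldCatalog | None = None
) -> DualDomainResult:
    """Assign each sheet independently, then look for a combined class.

    A structure with two SAM-binding domains whose sheets match two catalog
    arrangements may itself be a catalog entry keyed "order1/order2"; both
    orderings of the join are tried.
    """
    catalog = catalog or load_ligfold_catalog()
    assignments = [assign_ligfold(t, catalog) for t in topologies]
    combined_id = None
    matched = [a.matched_reading for a in assignments if a.matched_reading]
    if len(matched) >= 2:
        for i in range(len(matched)):
            for j in range(len(matched)):
                if i == j:
                    continue
                hit = catalog.lookup(f"{matched[i]}/{matched[j]}")
                if hit is not None:
                    combined_id = hit["ligfold_id"]
                    break
            if combined_id:
                break
    if combined_id:
        summary = combined_id
    elif all(a.novel for a in assignments):
        summary = "NOVEL"
    else:
        summary = "+".join(a.ligfold_id or "NOVEL" for a in assignments)
    return DualDomainResult(assignments=assignments, combined_ligfold_id=combined_id, summary=summary)


# ---------------------------------------------------------------------------
# input readers


def read_ssa_tsv(elements_path: str | Path, ladders_path: str | Path | None = None) -> SecondaryStructureAnnotation:
    """Sidecar TSV reader.

    Elements file columns: chain, start, end, type (strand|helix), sheet_id.
    Ladder file columns: strand_i, strand_j, orientation. Lines starting with
    '#' are comments.
    """
    elements = []
    for line in Path(elements_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("chain\t"):
            continue
        chain, start, end, kind, sheet_id = line.split("\t")[:5]
        elements.append(StrandElement(chain, int(start), int(end), kind, sheet_id))
    ladders = []
    if ladders_path is not None:
        for line in Path(ladders_path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("strand_i"):
                continue
            i, j, orientation = line.split("\t")[:3]
            ladders.append(LadderPair(int(i), int(j), orientation))
    return SecondaryStructureAnnotation(elements=elements, ladders=ladders)


def read_dssp(path: str | Path) -> SecondaryStructureAnnotation:
    """Minimal classic-format DSSP reader (strands and beta-ladder partners).

    Parses the per-residue table: summary code 'E' marks strand residues;
    BP1/BP2 columns give the DSSP serial of the bridge partner; ladder-letter
    case encodes orientation (lower case = parallel, upper = antiparallel).
    Helices ('H','G','I') are recorded as helix elements.
    """
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines) if l.lstrip().startswith("#  RESIDUE"))
    except StopIteration:
        raise TopologyError(f"{path}: no DSSP residue table") from None
    records = []
    for line in lines[start + 1 :]:
        if len(line) < 38 or line[13] == "!":
            continue
        records.append(
            {
                "serial": int(line[0:5]),
                "resnum": int(line[5:10]),
                "chain": line[11].strip() or "A",
                "ss": line[16],
                "ladder1": line[23],
                "ladder2": line[24],
                "bp1": int(line[25:29]),
                "bp2": int(line[29:33]),
            }
        )
    by_serial = {r["serial"]: r for r in records}
    # segment into elements
    elements: list[StrandElement] = []
    strand_of_serial: dict[int, int] = {}
    run: list[dict] = []

    def flush(run: list[dict]) -> None:
        if not run:
            return
        kind = "strand" if run[0]["ss"] == "E" else "helix"
        elements.append(
            StrandElement(run[0]["chain"], run[0]["resnum"], run[-1]["resnum"], kind)
        )
        if kind == "strand":
            idx = sum(1 for e in elements if e.kind == "strand")
            for r in run:
                strand_of_serial[r["serial"]] = idx

    prev_kind = None
    for r in records:
        kind = "strand" if r["ss"] == "E" else ("helix" if r["ss"] in "HGI" else None)
        if kind != prev_kind or (run and r["chain"] != run[-1]["chain"]):
            flush(run)
            run = []
        if kind is not None:
            run.append(r)
        prev_kind = kind
    flush(run)

    ladder_pairs: dict[tuple[int, int], str] = {}
    for r in records:
        si = strand_of_serial.get(r["serial"])
        if si is None:
            continue
        for bp, ladder in ((r["bp1"], r["ladder1"]), (r["bp2"], r["ladder2"])):
            if bp == 0:
                continue
            sj = strand_of_serial.get(bp)
            if sj is None or sj == si:
                continue
            key = (min(si, sj), max(si, sj))
            orientation = "parallel" if ladder.islower() else "antiparallel"
            ladder_pairs.setdefault(key, orientation)
    ladders = [LadderPair(i, j, o) for (i, j), o in sorted(ladder_pairs.items())]
    return SecondaryStructureAnnotation(elements=elements, ladders=ladders)
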