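"""Sheet linearization, catalog lookup, dual-domain scan, input readers."""

import numpy as np
import pytest

from ligfam.topology import (
    BarrelNotSupportedError,
    LadderPair,
    SecondaryStructureAnnotation,
    StrandElement,
    TopologyError,
    assign_ligfold,
    build_sheet,
    dual_domain_scan,
    load_fold_registry,
    load_ligfold_catalog,
    read_dssp,
    read_ssa_tsv,
)

# ladder chains realising the two major Rossmann-fold MTase arrangements
IA_ORDER = [3, 2, 1, 4, 5, 6, 7]
IB_ORDER = [6, 7, 5, 4, 1, 2, 3]


def test_classical_arrangement_linearized(chain_oracle):
    sheet = build_sheet(chain_oracle(IA_ORDER, antiparallel={6}))
    assert sheet.order_string == "3214567"
    assert sheet.reverse_string == "7654123"
    assert 6 in sheet.antiparallel_strands


def test_single_strand(chain_oracle):
    ssa = SecondaryStructureAnnotation(elements=[StrandElement("A", 1, 5)], ladders=[])
    assert build_sheet(ssa).order_string == "1"


@pytest.mark.parametrize("n", [5, 6, 7, 8])
def test_random_permutation_round_trip(chain_oracle, n):
    """Permutation -> ladder graph -> linearization recovers the permutation
    up to the documented canonical reading, deterministically."""
    rng = np.random.default_rng(100 + n)
    for _ in range(25):
        perm = list(rng.permutation(np.arange(1, n + 1)))
        perm = [int(v) for v in perm]
        sheet = build_sheet(chain_oracle(perm))
        expected = perm if perm[0] < perm[-1] else perm[::-1]
        assert sheet.order_string == "".join(map(str, expected))
        assert {sheet.order_string, sheet.reverse_string} == {
            "".join(map(str, perm)),
            "".join(map(str, perm[::-1])),
        }


def test_barrel_rejected(chain_oracle):
    ssa = chain_oracle([1, 2, 3, 4])
    ssa.ladders.append(LadderPair(4, 1))  # close the cycle
    with pytest.raises(BarrelNotSupportedError):
        build_sheet(ssa)


def test_branched_sheet_rejected(chain_oracle):
    ssa = chain_oracle([1, 2, 3, 4])
    ssa.ladders.append(LadderPair(2, 5))
    ssa.elements.append(StrandElement("A", 100, 105))
    with pytest.raises(TopologyError):
        build_sheet(ssa)


def test_disconnected_sheet_uses_largest_component(chain_oracle):
    # strands 1..5 in a chain plus an isolated hairpin 6-7
    ssa = chain_oracle([5, 4, 1, 2, 3])
    ssa.elements.extend([StrandElement("A", 200, 205), StrandElement("A", 210, 215)])
    ssa.ladders.append(LadderPair(6, 7))
    with pytest.warns(UserWarning):
        sheet = build_sheet(ssa)
    assert sheet.n_core == 5
    assert sheet.order_string in ("54123", "32145")


def test_catalog_contents_are_the_fourteen_subclasses():
    cat = load_ligfold_catalog()
    assert len(cat.entries) == 14
    expected = {
        "3214567": "SAM_DM_Ia",
        "6754123": "SAM_DM_Ib",
        "32145": "SAM_DM_Ic",
        "54123": "SAM_DM_Id",
        "564312": "SAM_DM_Ie",
        "654321": "SAM_DM_If",
        "1762354": "SAM_DM_Ig",
        "7645321": "SAM_DM_Ih",
        "7654123": "SAM_DM_Ii",
        "17865234": "SAM_DM_Ij",
        "5671432": "SAM_DM_Ik",
        "6754123/3214567": "SAM_DM_Il",
        "3421567": "SAM_DM_Im",
        "34215687": "SAM_DM_In",
    }
    for order, ligfold in expected.items():
        assert cat.entries[order]["ligfold_id"] == ligfold


def test_fold_registry_counts():
    reg = load_fold_registry()
    assert len(reg.entries) == 18
    assert reg.n_mtase == 9
    assert sum(1 for e in reg.entries if not e["is_mtase"]) == 9
    assert reg.by_numeral("I")["is_mtase"] is True


def test_assignment_with_reversal_ambiguity(chain_oracle):
    """'3214567' and its reverse '7654123' are both catalog classes; the
    lower-first-strand reading wins and the ambiguity is reported."""
    a = assign_ligfold(build_sheet(chain_oracle(IA_ORDER)))
    assert a.ligfold_id == "SAM_DM_Ia"
    assert a.ambiguous_reading


def test_assignment_via_reverse_reading(chain_oracle):
    sheet = build_sheet(chain_oracle(IB_ORDER))
    assert sheet.order_string == "3214576"  # canonical reading, not in catalog
    a = assign_ligfold(sheet)
    assert a.ligfold_id == "SAM_DM_Ib"
    assert a.matched_reading == "6754123"
    assert not a.ambiguous_reading


def test_novel_topology_reports_nearest(chain_oracle):
    a = assign_ligfold(build_sheet(chain_oracle([2, 1, 3, 4, 5, 6, 7])))
    assert a.novel and a.ligfold_id is None
    assert len(a.nearest) == 3
    assert a.nearest[0][2] <= a.nearest[-1][2]


def test_mirror_reading_gives_same_assignment(chain_oracle):
    fwd = assign_ligfold(build_sheet(chain_oracle(IB_ORDER)))
    rev = assign_ligfold(build_sheet(chain_oracle(IB_ORDER[::-1])))
    assert fwd.ligfold_id == rev.ligfold_id


def test_dual_domain_combination(chain_oracle):
    ia = build_sheet(chain_oracle(IA_ORDER))
    ib = build_sheet(chain_oracle(IB_ORDER))
    result = dual_domain_scan([ia, ib])
    assert result.combined_ligfold_id == "SAM_DM_Il"
    assert result.summary == "SAM_DM_Il"


def test_dual_domain_single_and_novel(chain_oracle):
    single = dual_domain_scan([build_sheet(chain_oracle(IA_ORDER))])
    assert single.summary == "SAM_DM_Ia"
    novel = dual_domain_scan([build_sheet(chain_oracle([2, 1, 3, 4, 5, 6, 7]))])
    assert novel.summary == "NOVEL"


def test_ssa_tsv_reader(tmp_path, chain_oracle):
    elements = tmp_path / "elements.tsv"
    ladders = tmp_path / "ladders.tsv"
    elements.write_text(
        "chain\tstart\tend\ttype\tsheet_id\n"
        + "\n".join(f"A\t{10*k}\t{10*k+5}\tstrand\tA" for k in range(1, 8))
        + "\n"
    )
    ladders.write_text(
        "strand_i\tstrand_j\torientation\n"
        + "\n".join(
            f"{IA_ORDER[i]}\t{IA_ORDER[i+1]}\tparallel" for i in range(6)
        )
        + "\n"
    )
    ssa = read_ssa_tsv(elements, ladders)
    assert build_sheet(ssa).order_string == "3214567"


def _dssp_line(serial, resnum, chain, aa, ss, l1, l2, bp1, bp2):
    # classic column layout: serial 0-5, resnum 5-10, chain 11, aa 13,
    # ss 16, ladder letters 23-24, BP1 25-29, BP2 29-33, sheet 33
    return (
        f"{serial:5d} {resnum:4d} {chain} {aa}  {ss}      {l1}{l2}{bp1:4d}{bp2:4d}A"
        f"   0"
    )


def test_dssp_reader_builds_expected_sheet(tmp_path):
    """A synthetic classic-format DSSP file with three strands: 2-1-3 order,
    strand 3 antiparallel to 1."""
    lines = [
        "== DSSP synthetic fixture ==",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC",
    ]
    serial = 1
    # strand 1: serial 1-3, partners strand 2 (parallel, 'a') and 3 (anti, 'B')
    spans = {1: (1, 3), 2: (11, 13), 3: (21, 23)}

    def serial_of(strand, k):
        return {1: 0, 2: 10, 3: 20}[strand] + k + 1 - 10 * 0  # same as below

    serials = {1: [1, 2, 3], 2: [4, 5, 6], 3: [7, 8, 9]}
    resnums = {1: [10, 11, 12], 2: [30, 31, 32], 3: [50, 51, 52]}
    for strand in (1, 2, 3):
        for k in range(3):
            bp1 = bp2 = 0
            l1 = l2 = " "
            if strand == 1:
                bp1, l1 = serials[2][k], "a"  # parallel ladder to strand 2
                bp2, l2 = serials[3][2 - k], "B"  # antiparallel ladder to 3
            elif strand == 2:
                bp1, l1 = serials[1][k], "a"
            else:
                bp1, l1 = serials[1][2 - k], "B"
            lines.append(
                _dssp_line(serials[strand][k], resnums[strand][k], "A", "V", "E", l1, l2, bp1, bp2)
            )
        # helix spacer between strands
        base = {1: 20, 2: 40, 3: 60}[strand]
        for k in range(3):
            lines.append(_dssp_line(100 + strand * 10 + k, base + k, "A", "A", "H", " ", " ", 0, 0))
    path = tmp_path / "synthetic.dssp"
    path.write_text("\n".join(lines) + "\n")
    ssa = read_dssp(path)
    strands = ssa.strands
    assert len(strands) == 3
    sheet = build_sheet(ssa)
    assert sheet.order_string == "213"
    assert sheet.antiparallel_strands == {1, 3}
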