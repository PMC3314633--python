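"""Dicer cleavage-pattern analysis: realignment, arm calling, overhangs."""
import pytest

import mirnovel.fixtures as fx
from mirnovel.dicer import (
    analyze_candidate,
    call_arms,
    dicer_filter,
    duplex_overhangs,
    realign_to_precursor,
    split_by_arm,
    start_fluctuation,
)
from mirnovel.fold import fold
from mirnovel.types import CollapsedRead, PrecursorCandidate, Thresholds
from tests.conftest import make_structure


def _candidate(pre_seq):
    return PrecursorCandidate(sequence=pre_seq, structure=fold(pre_seq, "thermo"))


def test_realign_finds_star_on_3p_arm(precursors, homolog_matures):
    pre = precursors["rno-mir-509"]
    star = CollapsedRead(homolog_matures.loc["rno-miR-509-3p", "sequence"], {"S": 1})
    pileup = realign_to_precursor([star], pre)
    assert [(off) for _, off, _ in pileup] == [pre.find(star.sequence)]
    arms = split_by_arm(pileup, fold(pre, "thermo"))
    assert len(arms["3p"]) == 1 and not arms["5p"]


def test_realign_absent_read_and_multi_occurrence():
    assert realign_to_precursor([CollapsedRead("ACGUACGUACGUACGUA", {"S": 1})], "G" * 60) == []
    pre = "AAGCUAGCAUGGAAGCUAGCAUGG"
    pileup = realign_to_precursor([CollapsedRead("AAGCUAGCAUGG", {"S": 2})], pre)
    assert [off for _, off, _ in pileup] == [0, 12]


def test_single_nt_extension_isomir_recorded(precursors, homolog_matures, thresholds):
    pre = precursors["rno-mir-1839"]
    mat = homolog_matures.loc["rno-miR-1839-5p", "sequence"]
    ext = pre[pre.find(mat) : pre.find(mat) + len(mat) + 1]  # +1 3' extension
    cand = analyze_candidate(
        _candidate(pre),
        [CollapsedRead(mat, {"S": 100}), CollapsedRead(ext, {"S": 20})],
        thresholds,
    )
    assert cand.mature.sequence == mat
    assert [(seq, off) for seq, off, _ in cand.isomirs] == [(ext, pre.find(mat))]


def test_call_arms_from_published_counts(precursors, homolog_matures, ngs_counts):
    pre = precursors["rno-mir-1839"]
    reads = [
        CollapsedRead(
            homolog_matures.loc[name, "sequence"],
            dict(ngs_counts.loc[name].astype(int)),
        )
        for name in ("rno-miR-1839-5p", "rno-miR-1839-3p")
    ]
    mature, star = call_arms(realign_to_precursor(reads, pre), fold(pre, "thermo"))
    assert mature.arm == "5p"
    assert mature.sequence == homolog_matures.loc["rno-miR-1839-5p", "sequence"]
    assert star.sequence == homolog_matures.loc["rno-miR-1839-3p", "sequence"]
    assert mature.total == int(ngs_counts.loc["rno-miR-1839-5p"].sum())


def test_call_arms_single_arm_pileup(precursors, homolog_matures):
    pre = precursors["rno-mir-1839"]
    mat = CollapsedRead(homolog_matures.loc["rno-miR-1839-5p", "sequence"], {"S": 9})
    mature, star = call_arms(realign_to_precursor([mat], pre), fold(pre, "thermo"))
    assert mature is not None and star is None


def test_published_1839_duplex_overhang_is_2_2(precursors, homolog_matures):
    pre = precursors["rno-mir-1839"]
    m = homolog_matures.loc["rno-miR-1839-5p", "sequence"]
    s = homolog_matures.loc["rno-miR-1839-3p", "sequence"]
    mi, si = pre.find(m), pre.find(s)
    ovh, _ = duplex_overhangs(
        fold(pre, "thermo"), (mi, mi + len(m)), (si, si + len(s))
    )
    assert ovh == (2, 2)


def test_509_loop_end_overhang_masked_by_overpairing(precursors, homolog_matures):
    # the modern MFE structure zips the 509 duplex through the loop-side
    # cleavage site: the loop-end overhang honestly measures 0, not the
    # canonical 2 (frozen here as a regression value)
    pre = precursors["rno-mir-509"]
    m = homolog_matures.loc["rno-miR-509-5p", "sequence"]
    s = homolog_matures.loc["rno-miR-509-3p", "sequence"]
    mi, si = pre.find(m), pre.find(s)
    ovh, _ = duplex_overhangs(fold(pre, "thermo"), (mi, mi + len(m)), (si, si + len(s)))
    assert ovh == (0, 2)


def test_blunt_duplex_overhang_0_0():
    db = "(((((" + "." * 7 + ")))))" + "..."
    st = make_structure("A" * len(db), db)
    ovh, flags = duplex_overhangs(st, (0, 5), (12, 17))
    assert ovh == (0, 0) and flags == []


def test_designed_3nt_offset_duplex():
    db = "(((((" + "." * 7 + ")))))" + "..."
    st = make_structure("A" * len(db), db)
    # arms include 3 unpaired 3' nt on each side of the duplex
    ovh, _ = duplex_overhangs(st, (0, 8), (12, 20))
    assert ovh == (3, 3)


def test_overhang_symmetric_under_arm_exchange(precursors, homolog_matures):
    pre = precursors["rno-mir-1843"]
    m = homolog_matures.loc["rno-miR-1843-5p", "sequence"]
    s = homolog_matures.loc["rno-miR-1843-3p", "sequence"]
    st = fold(pre, "thermo")
    a = (pre.find(m), pre.find(m) + len(m))
    b = (pre.find(s), pre.find(s) + len(s))
    assert duplex_overhangs(st, a, b)[0] == duplex_overhangs(st, b, a)[0]


def test_overhang_undefined_without_register_anchor():
    db = "((((((((" + "." * 8 + "))))))))"
    st = make_structure("A" * len(db), db)
    # both 5' termini sit >2 nt away from any paired position (loop interior)
    ovh, _ = duplex_overhangs(st, (11, 13), (13, 15))
    assert ovh == (None, None)


@pytest.mark.parametrize(
    "starts, expected",
    [([10, 10, 10], 0), ([10, 10, 11], 1), ([10, 13], 3)],
)
def test_start_fluctuation(starts, expected):
    pileup = [(CollapsedRead("A" * 20, {"S": 1}), s, {"S": 1}) for s in starts]
    assert start_fluctuation(pileup, 10) == expected


def test_dicer_filter_modes(precursors, homolog_matures, thresholds):
    pre = precursors["rno-mir-1839"]
    mat = CollapsedRead(homolog_matures.loc["rno-miR-1839-5p", "sequence"], {"S": 90})
    star = CollapsedRead(homolog_matures.loc["rno-miR-1839-3p", "sequence"], {"S": 9})
    full = analyze_candidate(_candidate(pre), [mat, star], thresholds)
    ok, reasons, flags = dicer_filter(full, thresholds, require_star=True)
    assert ok and flags["perfect_overhang"] and flags["star_detected"]

    lone = analyze_candidate(_candidate(pre), [mat], thresholds)
    ok, reasons, _ = dicer_filter(lone, thresholds, require_star=True)
    assert not ok and "no_star" in reasons
    # species-specific mode: star optional, fluctuation still mandatory
    ok, reasons, flags = dicer_filter(lone, thresholds, require_star=False)
    assert ok and flags["star_detected"] is False


def test_high_fluctuation_discards_candidate(precursors, homolog_matures, thresholds):
    pre = precursors["rno-mir-1839"]
    mat = homolog_matures.loc["rno-miR-1839-5p", "sequence"]
    mi = pre.find(mat)
    shifted = pre[mi + 3 : mi + 3 + len(mat)]  # start 3 nt off the predominant
    cand = analyze_candidate(
        _candidate(pre),
        [CollapsedRead(mat, {"S": 50}), CollapsedRead(shifted, {"S": 2})],
        thresholds,
    )
    assert cand.start_fluct == 3
    ok, reasons, _ = dicer_filter(cand, thresholds, require_star=False)
    assert not ok and reasons == ["start_fluctuation"]
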