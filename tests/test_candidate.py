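"""Window extraction, hairpin forcing, pairing screen, precursor trimming."""
import numpy as np
import pytest

from mirnovel.candidate import (
    crop_to_hairpin,
    extract_windows,
    filter_hairpin,
    trim_precursor,
)
from mirnovel.fold import fold
from mirnovel.types import CandidateWindow, Thresholds, revcomp
from tests.conftest import make_cluster, make_structure


def _window_from_structure(seq, db, cluster_span, arm="5p", strand="+", start=0):
    cluster = make_cluster("c", strand, start + cluster_span[0], [("A" * (cluster_span[1] - cluster_span[0]), start + cluster_span[0], 5)])
    return CandidateWindow(
        cluster=cluster,
        chrom="c",
        strand=strand,
        start=start,
        end=start + len(seq),
        sequence=seq,
        structure=make_structure(seq, db),
        arm=arm,
    )


@pytest.fixture
def toy_genome():
    rng = np.random.default_rng(11)
    return {"chr": "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=400)])}


def test_two_windows_per_cluster_and_strand_contract(toy_genome):
    cluster = make_cluster("chr", "-", 200, [("A" * 22, 200, 3)])
    w5, w3 = extract_windows(cluster, toy_genome, flank=60, back_margin=10)
    assert {w5.arm, w3.arm} == {"5p", "3p"}
    for w in (w5, w3):
        plus = toy_genome["chr"][w.start : w.end]
        assert w.sequence == revcomp(plus).replace("T", "U")
        lo, hi = w.cluster_region
        # the window-local cluster slice is the cluster's transcript sequence
        assert w.sequence[lo:hi] == revcomp(toy_genome["chr"][200:222]).replace("T", "U")
    # 5p hypothesis on minus strand extends toward lower genomic coordinates
    assert w5.start == 200 - 60 and w3.end == 222 + 60


def test_window_clipped_at_contig_edge(toy_genome):
    cluster = make_cluster("chr", "+", 390, [("A" * 10, 390, 1)])
    for w in extract_windows(cluster, toy_genome, flank=90):
        assert w.end <= 400 and w.start >= 0
    assert any(w.clipped for w in extract_windows(cluster, toy_genome, flank=90))


def test_filter_passes_published_precursor_with_mature_cluster(precursors, homolog_matures, thresholds):
    pre = precursors["rno-mir-1843"]
    mat = homolog_matures.loc["rno-miR-1843-5p", "sequence"]
    lo = pre.find(mat)
    w = _window_from_structure(pre, fold(pre, "thermo").dotbracket, (lo, lo + len(mat)))
    ok, reasons = filter_hairpin(w, thresholds)
    assert ok and reasons == []


def test_filter_rejects_unstructured_window(thresholds):
    w = _window_from_structure("A" * 40, "." * 40, (5, 27))
    ok, reasons = filter_hairpin(w, thresholds)
    assert not ok
    assert "min_total_pairs" in reasons


def test_filter_rejects_cluster_sitting_in_the_loop(thresholds):
    db = "(" * 20 + "." * 6 + ")" * 20
    w = _window_from_structure("A" * 46, db, (20, 26))
    ok, reasons = filter_hairpin(w, thresholds)
    assert not ok
    assert reasons == ["min_cluster_pairs"]


def test_crop_descends_to_cluster_stem_loop():
    db = "((((....))))....((((((....))))))"
    seq = "G" * len(db)
    w = _window_from_structure(seq, db, (18, 28), start=1000)
    c = crop_to_hairpin(w, pad=2)
    assert c is not None
    assert c.structure.dotbracket == ".." + "((((((....))))))"
    assert (c.start, c.end) == (1014, 1032)
    # a cluster touching no stem at all yields nothing
    w2 = _window_from_structure(db.replace(".", "A"), db, (12, 16), start=0)
    assert crop_to_hairpin(w2, pad=0) is None


def _stem_window(flank5=10, stem=25, loop=8, tail=22, bulge_at=None):
    """dot-flank + perfect stem (optional 1-nt 5'-side bulge) + dot-tail."""
    n = flank5 + 2 * stem + loop + tail + (1 if bulge_at is not None else 0)
    db = list("." * flank5)
    left = ["("] * stem
    if bulge_at is not None:
        left.insert(bulge_at, ".")
    db += left + ["."] * loop + [")"] * stem + ["."] * tail
    return "".join(db), n


def test_trim_no_bulge_gives_exactly_65_nt(thresholds):
    db, n = _stem_window()
    # mature starts right at the stem base: scanning 5'-ward hits the
    # unpaired flank immediately; place it at the very start instead so no
    # position 5' of the anchor exists -> the no-bulge floor applies
    db2 = db[10:]  # drop the 5' flank: stem starts at 0
    w = _window_from_structure("A" * len(db2), db2, (0, 22))
    cand = trim_precursor(w, (0, 22), thresholds)
    assert len(cand.sequence) == 65
    assert not cand.clipped


def test_trim_boundary_at_planted_bulge(thresholds):
    db, n = _stem_window(flank5=10, bulge_at=4)  # bulge 4 nt into the stem
    w = _window_from_structure("A" * n, db, (15, 37), start=500)
    # mature begins 5 nt above the bulge (local 15); boundary = local 14
    cand = trim_precursor(w, (15, 37), thresholds)
    assert cand.start == 500 + 14
    # ends at the structure partner of the first paired position
    assert cand.sequence == ("A" * n)[14 : 14 + len(cand.sequence)]
    assert len(cand.sequence) < 65  # an authoritative bulge overrides the floor


def test_trim_flank_bulge_given_unpaired_flank(thresholds):
    db, n = _stem_window(flank5=10)
    w = _window_from_structure("A" * n, db, (10, 32))
    cand = trim_precursor(w, (10, 32), thresholds)
    # boundary at the last unpaired flank position (local 9)
    assert len(cand.sequence) == (2 * 25 + 8) + 1  # stem-loop plus the bulge base


def test_trim_mature_at_window_edge_clips_and_flags(thresholds):
    db = "(" * 22 + "." * 6 + ")" * 22 + "." * 4
    w = _window_from_structure("A" * len(db), db, (0, 22))
    cand = trim_precursor(w, (0, 22), thresholds)
    assert cand.clipped
    assert len(cand.sequence) <= len(db)


def test_trim_rejects_mature_outside_window(thresholds):
    db, n = _stem_window()
    w = _window_from_structure("A" * n, db, (10, 32))
    with pytest.raises(ValueError):
        trim_precursor(w, (50, 99), thresholds)


def test_filter_pass_implies_hairpin(thresholds):
    from mirnovel.fold import is_hairpin

    for db, span in [
        ("(" * 20 + "." * 6 + ")" * 20, (0, 20)),
        ("((..))..((..))", (0, 6)),
        ("." * 30, (0, 10)),
    ]:
        w = _window_from_structure("A" * len(db), db, span)
        ok, _ = filter_hairpin(w, thresholds)
        if ok:
            assert is_hairpin(w.structure)
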