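"""Cross-sample consensus, expression cutoffs, classification and naming."""
import pytest

import mirnovel.fixtures as fx
from mirnovel.consensus import (
    classify_and_name,
    cross_sample_merge,
    expression_filter,
    is_homologous_arm,
)
from mirnovel.types import ArmProduct, NovelMiRNACall, PrecursorCandidate, ReferenceSet
from tests.conftest import make_structure


def _cand(chrom, strand, start, end, counts, mature_seq="ACGUACGUACGUACGUACGUAC"):
    n = end - start
    pre = PrecursorCandidate(
        sequence="A" * n,
        structure=make_structure("A" * n, "." * n),
        chrom=chrom,
        strand=strand,
        start=start,
        end=end,
        mature=ArmProduct("5p", 5, 5 + len(mature_seq), mature_seq, dict(counts)),
    )
    return pre


def _call(counts, mature_seq="ACGUACGUACGUACGUACGUAC", star_seq=None):
    pre = _cand("c", "+", 0, 70, counts, mature_seq)
    if star_seq:
        pre.mature_star = ArmProduct("3p", 40, 40 + len(star_seq), star_seq, {})
    return NovelMiRNACall(name="", mirna_class="", precursor=pre, sample_counts=dict(counts))


def test_merge_keeps_loci_in_enough_samples():
    by_sample = {
        f"S{i}": [_cand("c", "+", 100, 170, {f"S{i}": 20})] for i in range(5)
    }
    by_sample["S9"] = [_cand("c", "+", 900, 970, {"S9": 20})]  # one-sample locus
    calls = cross_sample_merge(by_sample, min_samples=4)
    assert [(c.precursor.start, c.n_samples_detected) for c in calls] == [(100, 5)]


def test_merge_tolerates_boundary_jitter():
    by_sample = {
        f"S{i}": [_cand("c", "+", 100 + d, 170 + d, {f"S{i}": 10})]
        for i, d in enumerate([-1, 0, 1, 0])
    }
    calls = cross_sample_merge(by_sample, min_samples=4)
    assert len(calls) == 1 and calls[0].n_samples_detected == 4


def test_merge_is_strand_aware():
    by_sample = {
        f"S{i}": [
            _cand("c", "+", 100, 170, {f"S{i}": 10}),
            _cand("c", "-", 120, 190, {f"S{i}": 10}),
        ]
        for i in range(4)
    }
    assert len(cross_sample_merge(by_sample, min_samples=4)) == 2


def test_consensus_is_highest_pooled_count_candidate():
    by_sample = {
        "S1": [_cand("c", "+", 100, 170, {"S1": 5}, mature_seq="A" * 22)],
        "S2": [_cand("c", "+", 102, 172, {"S2": 500}, mature_seq="G" * 22)],
        "S3": [_cand("c", "+", 100, 170, {"S3": 5}, mature_seq="A" * 22)],
        "S4": [_cand("c", "+", 100, 170, {"S4": 5}, mature_seq="A" * 22)],
    }
    (call,) = cross_sample_merge(by_sample, min_samples=4)
    assert call.precursor.mature.sequence == "G" * 22


def test_expression_filter_published_examples():
    counts_3598 = dict(fx.ngs_counts("specific").loc["rno-miR-3598"].astype(int))
    assert expression_filter(_call(counts_3598), scope="every-sample")
    counts_1306 = dict(fx.ngs_counts("homolog").loc["rno-miR-1306-3p"].astype(int))
    assert not expression_filter(_call(counts_1306), scope="any-sample", min_samples=4)
    assert not expression_filter(_call({s: 0 for s in counts_3598}), scope="every-sample")
    # the homolog-mode cutoff is strict: 10 reads everywhere is not >10
    assert not expression_filter(_call({f"S{i}": 10 for i in range(8)}), scope="any-sample")
    with pytest.raises(ValueError):
        expression_filter(_call(counts_3598), scope="sometimes")


@pytest.mark.parametrize(
    "novel, known, expected",
    [
        # printed divergent pairs: all homologous
        ("UUGGAGUUCAUGCAAGUUCUAACCA", "UUGGAGUUCAUGCAAGUUCUAACC", True),  # +1 3' ext
        ("UGAUUGACAUGUCUGCAGUGGA", "UGAUUGACACGUCUGCAGAUAGA", True),  # core mm + 3' tail
        ("GACGUUGGCUCUGGUGGUGAUG", "ACGUUGGCUCUGGUGGUGAU", True),  # 1-nt 5' extension
        ("AAGGUAGAUAGAACAGGUCUUG", "AAGGUAGAUAGAACAGGUCUUG", True),  # identity
        ("AAGGUAGAUAGAACAGGUCUUG", "UUGGAGUUCAUGCAAGUUCUAACC", False),
        ("ACGUACGUACGUACGUACGUAC", "ACGUCCGUACGAACGAACGUAC", False),  # 4 core mm
    ],
)
def test_homology_tolerance_reproduces_printed_cases(novel, known, expected):
    assert is_homologous_arm(novel, known) is expected


def test_classification_and_naming():
    other = ReferenceSet(
        "other", "other-species-mirna", {"mmu-miR-1839-5p": "AAGGUAGAUAGAACAGGUCUUG"}
    )
    used = set()
    # exact homolog inherits the family number with arm suffix
    call, nxt = classify_and_name(
        _call({"S": 20}, mature_seq="AAGGUAGAUAGAACAGGUCUUG"), other, 5001, used_names=used
    )
    assert call.mirna_class == "homologous"
    assert call.name == "rno-mir-1839"
    assert call.matures[0][2] == "rno-miR-1839-5p"
    assert nxt == 5001
    # a pure 3' extension is still homologous
    call, nxt = classify_and_name(
        _call({"S": 20}, mature_seq="AAGGUAGAUAGAACAGGUCUUGA"), other, nxt, used_names=used
    )
    assert call.mirna_class == "homologous"
    # no homolog: sequential new index, lowercase precursor / miR mature
    call, nxt = classify_and_name(
        _call({"S": 20}, mature_seq="CCAUCGAUUAAGCCAUGUACGG", star_seq="GUACAUGGCUUAAUCGAUGGAA"),
        other,
        nxt,
        used_names=used,
    )
    assert call.mirna_class == "species-specific"
    assert call.name == "rno-mir-5001" and nxt == 5002
    names = {n for _, _, n in call.matures}
    assert names == {"rno-miR-5001", "rno-miR-5001*"}


def test_name_collision_gets_deterministic_suffix():
    other = ReferenceSet(
        "other", "other-species-mirna", {"mmu-miR-1839-5p": "AAGGUAGAUAGAACAGGUCUUG"}
    )
    used = set()
    first, _ = classify_and_name(
        _call({"S": 1}, mature_seq="AAGGUAGAUAGAACAGGUCUUG"), other, 1, used_names=used
    )
    second, _ = classify_and_name(
        _call({"S": 1}, mature_seq="AAGGUAGAUAGAACAGGUCUUG"), other, 1, used_names=used
    )
    assert first.name == "rno-mir-1839"
    assert second.name == "rno-mir-1839a"
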