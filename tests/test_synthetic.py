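"""Synthetic benchmark generator: determinism, planted geometry, noise model."""
import numpy as np
import pytest

import mirnovel.fixtures as fx
from mirnovel.fold import count_pairs, fold, is_hairpin
from mirnovel.synthetic import (
    TRUE,
    build_reference_sets,
    plant_genome,
    sample_ids,
    simulate_intensities,
    simulate_reads,
)
from mirnovel.array import expressed_samples, group_test
from mirnovel.dicer import duplex_overhangs
from mirnovel.types import canonical_rna


SMALL = dict(n_true=3, n_decoy=2, contig_len=60_000, n_known=1, n_ncrna=1)


@pytest.fixture(scope="module")
def small_truth():
    return plant_genome(seed=5, **SMALL)


def test_regeneration_is_bit_identical(small_truth):
    again = plant_genome(seed=5, **SMALL)
    assert again.genome == small_truth.genome
    assert [(l.name, l.start, l.end, l.strand) for l in again.loci] == [
        (l.name, l.start, l.end, l.strand) for l in small_truth.loci
    ]
    r1 = simulate_reads(small_truth, seed=5)
    r2 = simulate_reads(again, seed=5)
    assert {s: {x.sequence: x.counts for x in rs} for s, rs in r1.items()} == {
        s: {x.sequence: x.counts for x in rs} for s, rs in r2.items()
    }
    m1, _ = simulate_intensities(small_truth, seed=5)
    m2, _ = simulate_intensities(again, seed=5)
    assert m1.values.equals(m2.values)


def test_planted_hairpins_fold_with_designed_geometry(small_truth):
    th_pairs = 19
    for locus in small_truth.by_class(TRUE):
        pre = small_truth.genome[locus.chrom][locus.start : locus.end]
        from mirnovel.types import revcomp

        if locus.strand == "-":
            pre = revcomp(pre)
        s = fold(canonical_rna(pre), "thermo")
        assert count_pairs(s) >= th_pairs, locus.name
        # designed duplex shows the 2-nt Dicer offset in the folded structure
        if locus.strand == "+":
            m = (locus.mature[0] - locus.start, locus.mature[1] - locus.start)
            st = (locus.star[0] - locus.start, locus.star[1] - locus.start)
        else:
            m = (locus.end - locus.mature[1], locus.end - locus.mature[0])
            st = (locus.end - locus.star[1], locus.end - locus.star[0])
        ovh, _ = duplex_overhangs(s, m, st)
        assert ovh == (2, 2), locus.name


def test_mature_star_expression_asymmetry(small_truth):
    reads = simulate_reads(small_truth, seed=5)
    pooled = {}
    for rs in reads.values():
        for r in rs:
            pooled[r.sequence] = pooled.get(r.sequence, 0) + r.total
    for locus in small_truth.by_class(TRUE):
        m, s = pooled.get(locus.mature_seq, 0), pooled.get(locus.star_seq, 0)
        assert m > s > 0, locus.name


def test_depth_zero_silences_a_locus(small_truth):
    name = small_truth.by_class(TRUE)[0].name
    reads = simulate_reads(small_truth, depth={name: 0.0}, seed=5)
    target = small_truth.by_class(TRUE)[0].mature_seq
    assert all(target not in {r.sequence for r in rs} for rs in reads.values())


def test_reference_sets_reflect_truth(small_truth):
    refs = {r.role: r for r in build_reference_sets(small_truth)}
    assert set(refs) == {"known-rat-mirna", "other-species-mirna", "exclusion", "genome"}
    homolog_matures = {l.mature_seq for l in small_truth.by_class(TRUE) if l.homolog}
    assert homolog_matures <= set(refs["other-species-mirna"].sequences.values())
    known = {l.mature_seq for l in small_truth.by_class("known-mirna")}
    assert known <= set(refs["known-rat-mirna"].sequences.values())


def test_intensities_structure_and_dropout(small_truth):
    matrix, probe_seqs = simulate_intensities(small_truth, seed=5, dropout=0.0)
    assert len(matrix.samples) == 6
    assert sorted(set(matrix.groups.values())) == ["control", "treated"]
    for locus in small_truth.by_class(TRUE):
        assert expressed_samples(matrix, locus.name, 32.0) == 6
        assert probe_seqs[locus.name] == locus.mature_seq
    bg = [p for p in matrix.probes if p.startswith("bg-probe")]
    assert bg and all(expressed_samples(matrix, p, 32.0) == 0 for p in bg)


def test_group_effect_detectable_for_responsive_locus():
    # large effect, fixed seed: a treatment-responsive locus tests significant
    truth = plant_genome(seed=2, **SMALL)
    matrix, _ = simulate_intensities(truth, seed=2, group_effect=4.0)
    responsive = [l for l in truth.by_class(TRUE) if l.aa_responsive]
    if not responsive:  # this seed plants none; regenerate deterministically
        truth = plant_genome(seed=4, **SMALL)
        matrix, _ = simulate_intensities(truth, seed=4, group_effect=4.0)
        responsive = [l for l in truth.by_class(TRUE) if l.aa_responsive]
    assert responsive
    t, p = group_test(matrix, responsive[0].name)
    assert p < 0.05


def test_verbatim_planting_recovers_printed_arm_positions():
    hm = fx.homologous_matures().set_index("name")
    pre = fx.all_precursors()["rno-mir-1839"]
    verbatim = [
        (
            "rno-mir-1839",
            pre,
            hm.loc["rno-miR-1839-5p", "sequence"],
            hm.loc["rno-miR-1839-3p", "sequence"],
        )
    ]
    truth = plant_genome(
        n_true=0, n_decoy=0, contig_len=30_000, seed=1, n_known=0, n_ncrna=0, verbatim=verbatim
    )
    (locus,) = truth.by_class(TRUE)
    g = truth.genome[locus.chrom]
    assert canonical_rna(g[locus.start : locus.end]) == pre
    assert canonical_rna(g[locus.mature[0] : locus.mature[1]]) == hm.loc[
        "rno-miR-1839-5p", "sequence"
    ]


def test_sample_design_mirrors_study():
    assert sample_ids(8) == ["CTL1", "CTL2", "CTL3", "CTL4", "AA1", "AA2", "AA3", "AA4"]
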