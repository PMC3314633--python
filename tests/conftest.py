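"""Shared fixtures: published reference data and small builders."""
from __future__ import annotations

import pytest

import mirnovel.fixtures as fx
from mirnovel.fold import pair_table
from mirnovel.types import Alignment, CollapsedRead, HairpinStructure, ReadCluster, Thresholds


@pytest.fixture(scope="session")
def precursors():
    """All nine published precursor sequences (RNA)."""
    return fx.all_precursors()


@pytest.fixture(scope="session")
def homolog_matures():
    """name -> mature sequence for the ten homologous products."""
    return fx.homologous_matures().set_index("name")


@pytest.fixture(scope="session")
def specific_matures():
    return fx.specific_matures().set_index("name")


@pytest.fixture(scope="session")
def ngs_counts():
    return fx.ngs_counts("homolog")


@pytest.fixture(scope="session")
def array_matrix():
    return fx.array_intensities("homolog")


@pytest.fixture
def thresholds():
    return Thresholds()


def make_structure(sequence: str, dotbracket: str) -> HairpinStructure:
    """Hand-built structure (no folding) for geometry tests."""
    return HairpinStructure(sequence, dotbracket, pair_table(dotbracket), 0.0, model="manual")


def make_cluster(chrom: str, strand: str, start: int, seqs_counts) -> ReadCluster:
    """Cluster of stacked reads; ``seqs_counts`` = [(sequence, start, total)]."""
    members = [
        Alignment(CollapsedRead(seq, {"s": n}), chrom, pos, strand, 0)
        for seq, pos, n in seqs_counts
    ]
    return ReadCluster(
        chrom,
        strand,
        min(a.start for a in members),
        max(a.end for a in members),
        members,
    )
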