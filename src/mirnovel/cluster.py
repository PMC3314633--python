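"""Grouping of genome alignments into read clusters (putative mature loci).

Clusters are strand-aware single-linkage merges of overlapping
alignments; with the default ``max_gap=0`` genuine interval overlap is
required, since Dicer read stacks overlap by construction.  Opposite
strands never merge: the mature and star of a minus-strand locus both
map to the minus strand.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from typing import Dict, List, Sequence

from .types import Alignment, CollapsedRead, ReadCluster

logger = logging.getLogger(__name__)


def cluster_reads(alignments: Sequence[Alignment], max_gap: int = 0) -> List[ReadCluster]:
    """Single-linkage merge of same-chrom/strand alignments.

    Two alignments join the same cluster when their intervals overlap, or
    lie within ``max_gap`` nt of each other when ``max_gap > 0``.
    Clusters are reported in genome order; every alignment belongs to
    exactly one cluster.
    """
    groups: Dict[tuple, List[Alignment]] = defaultdict(list)
    for a in alignments:
        groups[(a.ref_id, a.strand)].append(a)

    clusters: List[ReadCluster] = []
    for (chrom, strand), members in sorted(groups.items()):
        members.sort(key=lambda a: (a.start, a.end, a.read.sequence))
        current: List[Alignment] = []
        cur_end = None
        for a in members:
            joins = cur_end is not None and (
                a.start < cur_end or (max_gap > 0 and a.start - cur_end <= max_gap)
            )
            if joins:
                current.append(a)
                cur_end = max(cur_end, a.end)
            else:
                if current:
                    clusters.append(_make_cluster(chrom, strand, current))
                current, cur_end = [a], a.end
        if current:
            clusters.append(_make_cluster(chrom, strand, current))
    clusters.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return clusters


def _make_cluster(chrom: str, strand: str, members: List[Alignment]) -> ReadCluster:
    return ReadCluster(
        chrom=chrom,
        strand=strand,
        start=min(a.start for a in members),
        end=max(a.end for a in members),
        members=list(members),
    )


def predominant_read(cluster: ReadCluster) -> CollapsedRead:
    """The member read with the highest summed count across samples.

    Ties break toward the longer sequence, then the 5'-most start
    (strand-aware); a tie is logged.
    """
    if not cluster.members:
        raise ValueError("empty cluster has no predominant read")

    def five_prime_rank(a: Alignment) -> int:
        return a.start if cluster.strand == "+" else -(a.end - 1)

    best = max(
        cluster.members,
        key=lambda a: (a.read.total, len(a.read.sequence), -five_prime_rank(a), a.read.sequence),
    )
    ties = [
        a
        for a in cluster.members
        if a.read.total == best.read.total and a.read.sequence != best.read.sequence
    ]
    if ties:
        logger.info(
            "predominant-read tie at %s:%d-%d (%d reads at count %d); "
            "kept longest / 5'-most",
            cluster.chrom,
            cluster.start,
            cluster.end,
            len(ties) + 1,
            best.read.total,
        )
    return best.read


def predominant_alignment(cluster: ReadCluster) -> Alignment:
    """The alignment carrying the predominant read (same tie-break rule)."""
    seq = predominant_read(cluster).sequence
    for a in cluster.members:
        if a.read.sequence == seq:
            return a
    raise AssertionError("unreachable")
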