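"""Read mapping with a 5'-anchored exact seed plus a full-read mismatch cap.

The contract mirrors classic seed-and-extend short-read mapping: the
5'-most ``seed_len`` bases of the read must match the reference exactly,
and the full read may carry at most ``max_mm`` mismatches (necessarily
3' of the seed).  The minus strand is searched through the reverse
complement.  Designed for desk-scale references (reference sets and toy
genomes up to ~10 Mb), not for indexed whole-genome work.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from typing import Dict, List, Sequence, Tuple

from .types import Alignment, CollapsedRead, ReferenceSet, revcomp

logger = logging.getLogger(__name__)


def _to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def align(
    reads: Sequence[CollapsedRead],
    ref: ReferenceSet,
    seed_len: int = 19,
    max_mm: int = 1,
    both_strands: bool = False,
    max_hits: int | None = None,
) -> List[Alignment]:
    """Map ``reads`` to every locus of ``ref`` satisfying the seed contract.

    Returns alignments in deterministic ``(ref_id, start, strand)`` order.
    Reads shorter than ``seed_len`` are skipped with a logged warning.
    Multi-mapping reads contribute one alignment per locus, optionally
    capped at ``max_hits`` loci per read (in deterministic order).
    """
    # seed k-mer -> [(read, strand, seed offset within the genomic pattern)]
    index: Dict[str, List[Tuple[CollapsedRead, str, int, str]]] = defaultdict(list)
    n_short = 0
    for r in reads:
        pattern = _to_dna(r.sequence)
        if len(pattern) < seed_len:
            logger.debug("read %s shorter than seed length %d; skipped", r.sequence, seed_len)
            n_short += 1
            continue
        # plus strand: the read's 5' seed is the pattern prefix
        index[pattern[:seed_len]].append((r, "+", 0, pattern))
        if both_strands:
            rc = revcomp(pattern)
            # minus strand: the read's 5' seed maps to the pattern suffix
            index[rc[-seed_len:]].append((r, "-", len(rc) - seed_len, rc))
    if n_short:
        logger.warning("%d reads shorter than seed length %d were skipped", n_short, seed_len)

    hits: List[Alignment] = []
    for ref_id in ref.sequences:
        refseq = _to_dna(ref.sequences[ref_id])
        L = len(refseq)
        for i in range(L - seed_len + 1):
            for read, strand, offset, pattern in index.get(refseq[i : i + seed_len], ()):
                start = i - offset
                if start < 0 or start + len(pattern) > L:
                    continue
                mm = _hamming(pattern, refseq[start : start + len(pattern)])
                if mm <= max_mm:
                    hits.append(Alignment(read, ref_id, start, strand, mm))

    hits.sort(key=lambda a: (a.ref_id, a.start, a.strand, a.read.sequence))
    if max_hits is not None:
        per_read: Dict[str, int] = defaultdict(int)
        capped = []
        for a in hits:
            if per_read[a.read.sequence] < max_hits:
                capped.append(a)
                per_read[a.read.sequence] += 1
        hits = capped
    return hits


def brute_force_align(
    reads: Sequence[CollapsedRead],
    ref: ReferenceSet,
    seed_len: int = 19,
    max_mm: int = 1,
    both_strands: bool = False,
) -> List[Alignment]:
    """Full-scan Hamming reference aligner (independent oracle for tests)."""
    hits: List[Alignment] = []
    for r in reads:
        pat_fwd = _to_dna(r.sequence)
        if len(pat_fwd) < seed_len:
            continue
        patterns = [("+", pat_fwd, 0)]
        if both_strands:
            rc = revcomp(pat_fwd)
            patterns.append(("-", rc, len(rc) - seed_len))
        for ref_id, refseq in ref.sequences.items():
            refseq = _to_dna(refseq)
            for start in range(len(refseq) - len(pat_fwd) + 1):
                for strand, pattern, offset in patterns:
                    window = refseq[start : start + len(pattern)]
                    if pattern[offset : offset + seed_len] != window[offset : offset + seed_len]:
                        continue
                    mm = _hamming(pattern, window)
                    if mm <= max_mm:
                        hits.append(Alignment(r, ref_id, start, strand, mm))
    hits.sort(key=lambda a: (a.ref_id, a.start, a.strand, a.read.sequence))
    return hits


def _matched_reads(
    reads: Sequence[CollapsedRead], ref: ReferenceSet, seed_len: int, max_mm: int
) -> set:
    hits = align(reads, ref, seed_len=seed_len, max_mm=max_mm, both_strands=False)
    return {a.read.sequence for a in hits}


def route_reads(
    reads: Sequence[CollapsedRead],
    refsets: Sequence[ReferenceSet],
    mode: str,
    seed_len: int = 19,
    max_mm: int = 1,
) -> Dict[str, List[CollapsedRead]]:
    """Hierarchical keep/exclude routing of the two discovery passes.

    ``homologous`` mode removes reads hitting known rat miRNAs, then keeps
    only reads hitting the known-miRNA set of other species.  In
    ``species-specific`` mode a read is kept only when it hits *no*
    reference set (known miRNAs of any species plus every exclusion set).
    The returned buckets are an exhaustive, disjoint partition of the
    input; the ``kept`` bucket feeds the genome-mapping stage.
    """
    by_role: Dict[str, List[ReferenceSet]] = defaultdict(list)
    for rs in refsets:
        by_role[rs.role].append(rs)

    if mode == "homologous":
        required = ["known-rat-mirna", "other-species-mirna"]
    elif mode == "species-specific":
        required = ["known-rat-mirna"]
    else:
        raise ValueError(f"unknown routing mode: {mode!r}")
    for role in required:
        if not by_role.get(role):
            raise ValueError(f"routing mode {mode!r} requires a reference set with role {role!r}")

    buckets: Dict[str, List[CollapsedRead]] = {}
    remaining = list(reads)

    def drain(matched: set, bucket: str) -> None:
        nonlocal remaining
        buckets.setdefault(bucket, [])
        still = []
        for r in remaining:
            (buckets[bucket] if r.sequence in matched else still).append(r)
        remaining = still

    if mode == "homologous":
        for rs in by_role["known-rat-mirna"]:
            drain(_matched_reads(remaining, rs, seed_len, max_mm), f"removed:{rs.name}")
        matched_other = set()
        for rs in by_role["other-species-mirna"]:
            matched_other |= _matched_reads(remaining, rs, seed_len, max_mm)
        buckets["kept"] = [r for r in remaining if r.sequence in matched_other]
        buckets["unmatched"] = [r for r in remaining if r.sequence not in matched_other]
    else:
        for rs in by_role["known-rat-mirna"] + by_role.get("other-species-mirna", []) + by_role.get(
            "exclusion", []
        ):
            drain(_matched_reads(remaining, rs, seed_len, max_mm), f"removed:{rs.name}")
        buckets["kept"] = remaining

    for name, bucket in buckets.items():
        logger.info("route_reads[%s] %s: %d unique reads", mode, name, len(bucket))
    return buckets
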