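"""From read clusters to precursor candidates.

A cluster is tried under two arm hypotheses — as the 5' arm of a hairpin
(window extended 3' by ``flank``) and as the 3' arm (extended 5') — each
window is folded and screened with the pairing filters, and the best
passing window is trimmed to a precursor using the first-bulge boundary
rule.  The default flank of 90 nt keeps a 25-nt cluster inside a <=115-nt
window, which covers typical mammalian precursors (roughly 60-140 nt); a
second pass at twice the flank handles the long tail when the first pass
fails.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .fold import count_pairs, fold_cached, is_hairpin, pair_table
from .io import extract_interval
from .types import (
    CandidateWindow,
    HairpinStructure,
    PrecursorCandidate,
    ReadCluster,
    Thresholds,
)

DEFAULT_FLANK = 90
#: context kept behind the cluster on its own side of the hairpin, nt.
#: The mature product starts up to ~20 nt inside the precursor (lower stem
#: plus Drosha offset), so the window must reach past the cluster there too.
BACK_MARGIN = 25


def extract_windows(
    cluster: ReadCluster,
    genome: Dict[str, str],
    flank: int = DEFAULT_FLANK,
    back_margin: int = BACK_MARGIN,
    model: str = "auto",
) -> List[CandidateWindow]:
    """Fold the two arm-hypothesis windows around a cluster.

    Windows are clipped at contig edges (flagged, not an error); minus
    strand windows are reverse complemented before folding, so window
    sequences always read 5'->3' along the transcript.
    """
    contig = genome[cluster.chrom]
    windows: List[CandidateWindow] = []
    for arm in ("5p", "3p"):
        if (arm == "5p") == (cluster.strand == "+"):
            # extend transcript-3' across the hairpin, transcript-5' a little
            start, end = cluster.start - back_margin, cluster.end + flank
        else:
            start, end = cluster.start - flank, cluster.end + back_margin
        clipped = start < 0 or end > len(contig)
        start, end = max(0, start), min(len(contig), end)
        seq = extract_interval(genome, cluster.chrom, start, end, cluster.strand)
        structure = fold_cached(seq, model) if len(seq) >= 10 else None
        windows.append(
            CandidateWindow(
                cluster=cluster,
                chrom=cluster.chrom,
                strand=cluster.strand,
                start=start,
                end=end,
                sequence=seq,
                structure=structure,
                arm=arm,
                clipped=clipped,
            )
        )
    return windows


def _child_spans(pairs: Dict[int, int], i: int, j: int) -> List[Tuple[int, int]]:
    """Pair spans directly nested inside the half-open region (i, j)."""
    out: List[Tuple[int, int]] = []
    k = i
    while k < j:
        partner = pairs.get(k)
        if partner is not None and partner > k:
            out.append((k, partner))
            k = partner + 1
        else:
            k += 1
    return out


def crop_to_hairpin(window: CandidateWindow, pad: int = 15) -> Optional[CandidateWindow]:
    """Force a hairpin: crop the window to the stem-loop over the cluster.

    Genomic flanks routinely fold into side stems, so the raw window
    structure is rarely a single stem-loop even over a genuine precursor.
    This walks the structure tree from the top-level component with the
    greatest cluster overlap, descending through multiloops toward the
    branch covering the read cluster, and crops the window (with ``pad``
    unpaired nt of context) to the first single stem-loop found.  Returns
    ``None`` when the cluster region touches no stem-loop at all.
    """
    s = window.structure
    if s is None or not s.pairs:
        return None
    n = len(s.sequence)
    lo, hi = window.cluster_region
    lo, hi = max(0, lo), min(n, hi)

    def overlap(span: Tuple[int, int]) -> int:
        return max(0, min(span[1] + 1, hi) - max(span[0], lo))

    spans = _child_spans(s.pairs, 0, n)
    while True:
        spans = [sp for sp in spans if overlap(sp) > 0]
        if not spans:
            return None
        i, j = max(spans, key=overlap)
        sub = s.dotbracket[i : j + 1]
        if sub.rindex("(") < sub.index(")"):  # single stem-loop
            break
        spans = _child_spans(s.pairs, i + 1, j)

    a, b = max(0, i - pad), min(n, j + 1 + pad)
    db = "." * (i - a) + s.dotbracket[i : j + 1] + "." * (b - j - 1)
    cropped = HairpinStructure(s.sequence[a:b], db, pair_table(db), s.energy, model=s.model)
    if window.strand == "+":
        g_start, g_end = window.start + a, window.start + b
    else:
        g_start, g_end = window.end - b, window.end - a
    return CandidateWindow(
        cluster=window.cluster,
        chrom=window.chrom,
        strand=window.strand,
        start=g_start,
        end=g_end,
        sequence=s.sequence[a:b],
        structure=cropped,
        arm=window.arm,
        clipped=window.clipped,
    )


def filter_hairpin(window: CandidateWindow, th: Thresholds) -> Tuple[bool, List[str]]:
    """Pairing/topology screen: single hairpin, >=19 total pairs, >=11 in cluster.

    Returns ``(passed, reasons)`` with machine-readable failure reasons.
    """
    reasons: List[str] = []
    s = window.structure
    if s is None:
        return False, ["unfoldable"]
    if not is_hairpin(s):
        reasons.append("not_hairpin")
    if count_pairs(s) < th.min_total_pairs:
        reasons.append("min_total_pairs")
    lo, hi = window.cluster_region
    lo, hi = max(0, lo), min(len(s.sequence), hi)
    if count_pairs(s, (lo, hi)) < th.min_cluster_pairs:
        reasons.append("min_cluster_pairs")
    return (not reasons), reasons


def best_window(windows: List[CandidateWindow], th: Thresholds) -> Optional[CandidateWindow]:
    """The energetically best window among those passing the hairpin screen."""
    passing = [w for w in windows if filter_hairpin(w, th)[0]]
    if not passing:
        return None
    return min(passing, key=lambda w: (w.structure.energy, w.arm))


def _first_bulge_boundary(structure: HairpinStructure, anchor: int) -> Optional[int]:
    """Scan 5'-ward from ``anchor`` for the first stem bulge; return its position.

    A bulge is the first position where either strand of the stem is
    unpaired: the scanned position itself, or a gap on the opposite
    strand (the partner series jumping by more than one).
    """
    prev_partner = None
    for p in range(anchor - 1, -1, -1):
        partner = structure.partner(p)
        if partner is None:
            return p  # unpaired on the 5' strand
        if prev_partner is not None and partner > prev_partner + 1:
            return p  # insertion on the opposite strand
        prev_partner = partner
    return None


def trim_precursor(
    window: CandidateWindow,
    mature: Tuple[int, int],
    th: Thresholds,
) -> PrecursorCandidate:
    """Trim a passing window to a precursor around the mature interval.

    The precursor starts at the first bulge 5' of the 5'-arm product and
    ends at the structure-paired position corresponding to that boundary
    on the opposite arm.  When the flank reaches no bulge, the precursor
    is extended symmetrically to ``th.min_precursor_len``.  ``mature`` is
    the window-local half-open interval of the cluster product.

    The precursor keeps the window's structure restricted to the trimmed
    span (pairs crossing the boundary are dropped) rather than being
    refolded: refolding the excised sequence in isolation can shift the
    duplex register near the terminal loop and misreport the overhang
    that the full-context structure shows.
    """
    s = window.structure
    if s is None:
        raise ValueError("cannot trim an unfolded window")
    m_lo, m_hi = mature
    if not (0 <= m_lo < m_hi <= len(s.sequence)):
        raise ValueError("mature interval outside window")

    # the boundary is anchored on the 5' arm: the mature itself when it is
    # the 5' arm, otherwise the partner of the mature's 3' end
    if window.arm == "5p":
        anchor = m_lo
    else:
        partner = None
        for p in range(m_hi - 1, m_lo - 1, -1):
            partner = s.partner(p)
            if partner is not None:
                break
        anchor = partner if partner is not None else m_lo

    clipped = False
    b5 = _first_bulge_boundary(s, anchor)
    bulge_found = b5 is not None
    if b5 is None:
        # perfect stem all the way out: fall back to the duplex span and
        # let the symmetric extension below impose the 65-nt floor
        b5 = anchor
    # corresponding 3' position: partner of the innermost paired position
    # at/inside the boundary
    q = None
    for p in range(b5, anchor + 1):
        q = s.partner(p)
        if q is not None:
            break
    if q is None:
        q = len(s.sequence) - 1
        clipped = True
    lo, hi = b5, q + 1

    # the 65-nt floor applies when the flank reaches no bulge; a found
    # bulge is an authoritative boundary even for a shorter precursor
    deficit = 0 if bulge_found else th.min_precursor_len - (hi - lo)
    if deficit > 0:
        grow5 = deficit // 2
        grow3 = deficit - grow5
        lo, hi = lo - grow5, hi + grow3
        if lo < 0:
            hi = min(len(s.sequence), hi - lo)
            lo = 0
        if hi > len(s.sequence):
            lo = max(0, lo - (hi - len(s.sequence)))
            hi = len(s.sequence)
        if hi - lo < th.min_precursor_len:
            clipped = True

    pre_seq = s.sequence[lo:hi]
    db = "".join(
        ("(" if s.pairs[p] > p else ")")
        if p in s.pairs and lo <= s.pairs[p] < hi
        else "."
        for p in range(lo, hi)
    )
    pre_structure = HairpinStructure(pre_seq, db, pair_table(db), s.energy, model=s.model)
    g = sorted((window.local_to_genomic(lo), window.local_to_genomic(hi - 1)))
    return PrecursorCandidate(
        sequence=pre_seq,
        structure=pre_structure,
        chrom=window.chrom,
        strand=window.strand,
        start=g[0],
        end=g[1] + 1,
        clipped=clipped or window.clipped,
    )
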