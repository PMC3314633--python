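"""Dicer cleavage-pattern analysis on precursor candidates.

Reads are realigned (exact match) to the precursor, the predominant read
of each arm defines the mature and mature* products, and three classic
cleavage criteria are evaluated: presence of both duplex strands, a 3'
overhang in the accepted 1-4 nt range at both duplex ends, and 5' start
fluctuation below 2 nt around the predominant read.

The 3' overhang is computed from the pair table under a duplex-register
convention: the antiparallel register is anchored at a *paired* 5'
terminus (miRNA 5' ends are the precisely processed ends), and each
end's overhang is the number of 3' nucleotides of one strand extending
past the register partner of the other strand's 5' terminus.  Anchoring
at a paired terminus makes the measurement robust to end fraying and to
small asymmetric loops near the helix ends, which would otherwise shift
a naive per-position partner lookup by one.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from typing import Dict, List, Optional, Sequence, Tuple

from .fold import is_hairpin, terminal_loop
from .types import ArmProduct, CollapsedRead, HairpinStructure, PrecursorCandidate, Thresholds

logger = logging.getLogger(__name__)

Pileup = List[Tuple[CollapsedRead, int, Dict[str, int]]]


def realign_to_precursor(reads: Sequence[CollapsedRead], precursor_seq: str) -> Pileup:
    """Exact-match offsets of every read within the precursor sequence.

    A read occurring at several offsets (e.g. on both arms) is reported at
    every offset.
    """
    pileup: Pileup = []
    for r in reads:
        start = 0
        while True:
            i = precursor_seq.find(r.sequence, start)
            if i < 0:
                break
            pileup.append((r, i, dict(r.counts)))
            start = i + 1
    pileup.sort(key=lambda t: (t[1], t[0].sequence))
    return pileup


def _arm_of(offset: int, length: int, loop: Tuple[int, int]) -> str:
    center = offset + length / 2
    loop_center = (loop[0] + loop[1]) / 2
    return "5p" if center < loop_center else "3p"


def split_by_arm(pileup: Pileup, structure: HairpinStructure) -> Dict[str, Pileup]:
    """Partition a pileup into 5p/3p arms relative to the terminal loop."""
    if is_hairpin(structure):
        loop = terminal_loop(structure)
    else:  # no defined loop: split at the middle
        mid = len(structure.sequence) // 2
        loop = (mid, mid)
    arms: Dict[str, Pileup] = {"5p": [], "3p": []}
    for read, offset, counts in pileup:
        arms[_arm_of(offset, len(read.sequence), loop)].append((read, offset, counts))
    return arms


def _predominant(pileup: Pileup) -> Tuple[CollapsedRead, int]:
    best = max(pileup, key=lambda t: (sum(t[2].values()), len(t[0].sequence), -t[1], t[0].sequence))
    return best[0], best[1]


def call_arms(
    pileup: Pileup, structure: HairpinStructure
) -> Tuple[Optional[ArmProduct], Optional[ArmProduct]]:
    """Call mature and mature* from the per-arm predominant reads.

    The mature is the predominant read overall; the mature* is the
    predominant read of the opposite arm, when any reads map there.  The
    length of each product is the length of its most expressed read.
    """
    if not pileup:
        return None, None
    arms = split_by_arm(pileup, structure)

    def product(arm: str) -> Optional[ArmProduct]:
        if not arms[arm]:
            return None
        read, offset = _predominant(arms[arm])
        counts: Dict[str, int] = defaultdict(int)
        for r, _, c in arms[arm]:
            for s, v in c.items():
                counts[s] += v
        return ArmProduct(arm, offset, offset + len(read.sequence), read.sequence, dict(counts))

    p5, p3 = product("5p"), product("3p")
    if p5 is None:
        return p3, None
    if p3 is None:
        return p5, None
    mature, star = (p5, p3) if p5.total >= p3.total else (p3, p5)
    return mature, star


def duplex_overhangs(
    structure: HairpinStructure,
    mature: Tuple[int, int],
    mature_star: Tuple[int, int],
) -> Tuple[Tuple[Optional[int], Optional[int]], List[str]]:
    """3' overhangs at the two duplex ends, from the pair table.

    Arguments are half-open local intervals of the two arms (either
    order).  Returns ``((overhang_5p_strand_3'_end, overhang_3p_strand_3'_end),
    flags)`` — the first element is the overhang where the 5'-arm
    strand's 3' end meets the 3'-arm strand's 5' end (loop-proximal), the
    second the opposite (base) end.  An end is ``None`` when no register
    anchor exists within 2 nt of either 5' terminus, in which case the
    cleavage criterion fails.
    """
    (x5, x3), (y5, y3) = sorted([mature, mature_star])  # x = 5' arm, y = 3' arm
    x3, y3 = x3 - 1, y3 - 1  # inclusive 3' termini
    flags: List[str] = []

    def register_from(pos: int) -> Optional[int]:
        """Antiparallel register constant i + partner(i), anchored at ``pos``.

        Falls back to the nearest paired position within 2 nt, corrected
        for the shift (flagged).
        """
        partner = structure.partner(pos)
        if partner is not None:
            return pos + partner
        for d in (1, 2, -1, -2):
            partner = structure.partner(pos + d)
            if partner is not None:
                flags.append(f"register_shifted_{d:+d}")
                return pos + d + partner
        return None

    reg_loop = register_from(y5)  # anchored at the 3'-arm 5' terminus
    reg_base = register_from(x5)  # anchored at the 5'-arm 5' terminus
    if structure.partner(y5) is None and reg_base is not None:
        reg_loop = reg_base
        flags.append("loop_end_register_inferred")
    if structure.partner(x5) is None and reg_loop is not None and structure.partner(y5) is not None:
        reg_base = reg_loop
        flags.append("base_end_register_inferred")

    ovh_loop = x3 - (reg_loop - y5) if reg_loop is not None else None
    ovh_base = y3 - (reg_base - x5) if reg_base is not None else None
    return (ovh_loop, ovh_base), flags


def overhang(
    structure: HairpinStructure, mature: ArmProduct, mature_star: ArmProduct
) -> Tuple[Optional[int], Optional[int]]:
    """Convenience wrapper of :func:`duplex_overhangs` for called arms."""
    ovh, _ = duplex_overhangs(
        structure, (mature.start, mature.end), (mature_star.start, mature_star.end)
    )
    return ovh


def start_fluctuation(arm_pileup: Pileup, predominant_offset: int) -> int:
    """Maximum |5' start - predominant 5' start| over same-arm reads."""
    if not arm_pileup:
        return 0
    return max(abs(offset - predominant_offset) for _, offset, _ in arm_pileup)


def analyze_candidate(
    candidate: PrecursorCandidate, reads: Sequence[CollapsedRead], th: Thresholds
) -> PrecursorCandidate:
    """Realign reads, call arms, and fill in the Dicer-pattern evidence."""
    pileup = realign_to_precursor(reads, candidate.sequence)
    arms = split_by_arm(pileup, candidate.structure)
    mature, star = call_arms(pileup, candidate.structure)
    candidate.mature, candidate.mature_star = mature, star
    candidate.isomirs = [
        (r.sequence, off, c)
        for r, off, c in pileup
        if mature is not None and (off, off + len(r.sequence)) != (mature.start, mature.end)
    ]
    if mature is not None:
        candidate.start_fluct = start_fluctuation(arms[mature.arm], mature.start)
    if mature is not None and star is not None:
        ovh, flags = _score_overhang(candidate.structure, arms, mature, star, th)
        candidate.overhangs = ovh
        for f in flags:
            candidate.flags[f] = True
    return candidate


def _score_overhang(
    structure: HairpinStructure,
    arms: Dict[str, Pileup],
    mature: ArmProduct,
    star: ArmProduct,
    th: Thresholds,
) -> Tuple[Tuple[Optional[int], Optional[int]], List[str]]:
    """Score the duplex overhang, preferring a perfect-overhang star read.

    When the most expressed star read is an extension isomiR whose duplex
    is not canonical, the highest-count star read showing the perfect
    overhang is used for scoring instead (flagged); both reads remain in
    the pileup.
    """
    ovh, flags = duplex_overhangs(structure, (mature.start, mature.end), (star.start, star.end))
    perfect = th.perfect_overhang
    if ovh != (perfect, perfect):
        star_reads = sorted(
            arms[star.arm], key=lambda t: (-sum(t[2].values()), t[1], t[0].sequence)
        )
        for read, offset, _ in star_reads:
            alt = (offset, offset + len(read.sequence))
            if alt == (star.start, star.end):
                continue
            alt_ovh, alt_flags = duplex_overhangs(
                structure, (mature.start, mature.end), alt
            )
            if alt_ovh == (perfect, perfect):
                logger.info(
                    "top star read lacks the perfect overhang; scored against "
                    "the next star read at offset %d",
                    offset,
                )
                return alt_ovh, alt_flags + ["star_isomir_rescored"]
    return ovh, flags


def dicer_filter(
    candidate: PrecursorCandidate, th: Thresholds, require_star: bool = True
) -> Tuple[bool, List[str], Dict[str, bool]]:
    """Apply the cleavage-pattern criteria.

    With ``require_star`` (homolog mode) the call needs mature and
    mature*, overhangs inside ``th.overhang_range`` at both ends, and
    start fluctuation < ``th.max_start_fluct``.  Without it
    (species-specific mode) only the fluctuation criterion is mandatory;
    star presence and overhang are recorded as evidence flags.
    """
    reasons: List[str] = []
    flags: Dict[str, bool] = dict(candidate.flags)
    lo, hi = th.overhang_range

    star_ok = candidate.mature_star is not None
    flags["star_detected"] = star_ok
    ovh_ok = False
    if candidate.overhangs is not None:
        ovh_ok = all(o is not None and lo <= o <= hi for o in candidate.overhangs)
        flags["perfect_overhang"] = candidate.overhangs == (
            th.perfect_overhang,
            th.perfect_overhang,
        )
    fluct_ok = candidate.start_fluct is not None and candidate.start_fluct < th.max_start_fluct

    if not fluct_ok:
        reasons.append("start_fluctuation")
    if require_star:
        if not star_ok:
            reasons.append("no_star")
        elif not ovh_ok:
            reasons.append("overhang")
    else:
        flags["overhang_ok"] = ovh_ok
    return (not reasons), reasons, flags
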