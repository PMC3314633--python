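"""Cross-sample aggregation, expression thresholds, classification, naming.

A candidate becomes a call when it is detected in at least
``min_samples`` of the sequencing samples.  Expression is filtered in
the two modes the discovery passes use: homolog calls need a read count
above the cutoff in at least ``min_samples`` samples, while
species-specific calls need the cutoff met in *every* sample.  Calls
whose arms match a known mature miRNA of another species inherit that
family's number; the rest receive sequential new indices.
"""
from __future__ import annotations

import logging
import re
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .types import NovelMiRNACall, PrecursorCandidate, ReferenceSet, Thresholds, canonical_rna

logger = logging.getLogger(__name__)

_FAMILY = re.compile(r"mir-?([0-9]+[a-z]?)", re.IGNORECASE)


def cross_sample_merge(
    candidates_by_sample: Mapping[str, Sequence[PrecursorCandidate]],
    min_samples: int = 4,
) -> List[NovelMiRNACall]:
    """Merge per-sample candidates at overlapping loci into consensus calls.

    Candidates whose precursor intervals overlap on the same chrom and
    strand are one locus; the consensus precursor is the candidate with
    the highest pooled mature count.  Loci detected in fewer than
    ``min_samples`` samples are dropped.
    """
    entries: List[Tuple[str, PrecursorCandidate]] = [
        (sample, c) for sample, cands in candidates_by_sample.items() for c in cands
    ]
    entries.sort(key=lambda t: (t[1].chrom, t[1].strand, t[1].start, t[1].end, t[0]))

    groups: List[List[Tuple[str, PrecursorCandidate]]] = []
    for sample, c in entries:
        if groups:
            _, last = groups[-1][-1]
            tail_end = max(p.end for _, p in groups[-1])
            if (c.chrom, c.strand) == (last.chrom, last.strand) and c.start < tail_end:
                groups[-1].append((sample, c))
                continue
        groups.append([(sample, c)])

    calls: List[NovelMiRNACall] = []
    for group in groups:
        samples = {s for s, _ in group}
        if len(samples) < min_samples:
            continue
        consensus = max(
            (c for _, c in group),
            key=lambda c: (sum(c.sample_counts.values()), -c.start, c.sequence),
        )
        counts: Dict[str, int] = dict(consensus.sample_counts)
        calls.append(
            NovelMiRNACall(
                name="",
                mirna_class="",
                precursor=consensus,
                n_samples_detected=len(samples),
                sample_counts=counts,
            )
        )
    calls.sort(key=lambda c: (c.chrom, c.precursor.start, c.strand))
    return calls


def expression_filter(
    call: NovelMiRNACall,
    min_reads: int = 10,
    scope: str = "any-sample",
    min_samples: int = 4,
) -> bool:
    """NGS expression cutoff in the two published modes.

    ``any-sample`` (homolog passes): read count strictly above
    ``min_reads`` in at least ``min_samples`` samples.  ``every-sample``
    (species-specific passes): count of at least ``min_reads`` in every
    sample.
    """
    counts = call.sample_counts
    if scope == "any-sample":
        return sum(1 for v in counts.values() if v > min_reads) >= min_samples
    if scope == "every-sample":
        return bool(counts) and all(v >= min_reads for v in counts.values())
    raise ValueError(f"unknown expression scope: {scope!r}")


def is_homologous_arm(
    arm_seq: str,
    known_seq: str,
    core_len: int = 18,
    max_mm: int = 1,
    max_shift: int = 1,
) -> bool:
    """Arm-to-known-miRNA homology test.

    Mature 5' ends are precisely processed while 3' ends wobble, so two
    sequences are homologous when their 5'-anchored cores (first
    ``core_len`` nt) agree up to ``max_mm`` substitutions, allowing a
    5'-end offset of up to ``max_shift`` nt; 3'-end length or sequence
    differences beyond the core are tolerated.
    """
    a, b = canonical_rna(arm_seq), canonical_rna(known_seq)
    for shift in range(-max_shift, max_shift + 1):
        if shift >= 0:
            x, y = a[shift:], b
        else:
            x, y = a, b[-shift:]
        k = min(len(x), len(y), core_len)
        if k < core_len - max_shift:
            continue
        if sum(c != d for c, d in zip(x[:k], y[:k])) <= max_mm:
            return True
    return False


def find_homologs(
    arm_seq: str, known_other_species: ReferenceSet, **kwargs
) -> List[str]:
    return [
        kid
        for kid, kseq in known_other_species.sequences.items()
        if is_homologous_arm(arm_seq, kseq, **kwargs)
    ]


def _family_number(homolog_id: str) -> Optional[str]:
    m = _FAMILY.search(homolog_id)
    return m.group(1) if m else None


def classify_and_name(
    call: NovelMiRNACall,
    known_other_species: Optional[ReferenceSet],
    next_free_index: int,
    species_prefix: str = "rno",
    used_names: Optional[set] = None,
) -> Tuple[NovelMiRNACall, int]:
    """Classify a call as homologous or species-specific and assign names.

    Homologous calls inherit the matched family number with the species
    prefix and -5p/-3p arm suffixes; species-specific calls receive the
    next free sequential index.  Returns the named call and the updated
    next free index.  Name collisions get a deterministic letter suffix
    and are logged.
    """
    used = used_names if used_names is not None else set()
    p = call.precursor
    arms = [a for a in (p.mature, p.mature_star) if a is not None]

    homolog_ids: List[str] = []
    if known_other_species is not None:
        for a in arms:
            homolog_ids.extend(find_homologs(a.sequence, known_other_species))

    def unique(name: str) -> str:
        if name not in used:
            used.add(name)
            return name
        for suffix in "abcdefghijklmnopqrstuvwxyz":
            cand = f"{name}{suffix}"
            if cand not in used:
                logger.info("name collision for %s; using %s", name, cand)
                used.add(cand)
                return cand
        raise RuntimeError(f"cannot deduplicate name {name}")

    if homolog_ids:
        family = next(
            (f for f in (_family_number(h) for h in homolog_ids) if f is not None),
            str(next_free_index),
        )
        call.mirna_class = "homologous"
        call.homolog_ids = sorted(set(homolog_ids))
        base = unique(f"{species_prefix}-mir-{family}")
        family = base.rsplit("-", 1)[1]
        call.name = base
        call.matures = [
            (a.arm, a.sequence, f"{species_prefix}-miR-{family}-{a.arm}") for a in arms
        ]
    else:
        call.mirna_class = "species-specific"
        base = unique(f"{species_prefix}-miR-{next_free_index}")
        idx = base.split("-")[-1]
        next_free_index += 1
        call.name = f"{species_prefix}-mir-{idx}"
        call.matures = []
        for a in arms:
            if p.mature is not None and a.arm == p.mature.arm:
                call.matures.append((a.arm, a.sequence, base))
            else:
                call.matures.append((a.arm, a.sequence, f"{base}*"))
    return call, next_free_index
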