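"""First-stage read cleaning.

Reads containing ambiguity codes (any character outside ACGU after
canonicalization) are dropped, reads shorter than ``min_len`` are
dropped, and reads longer than ``max_len`` are truncated at the 3' end
to ``max_len`` and re-collapsed — small-RNA reads run 5'->3' into the
adapter, so excess length is 3' sequence.
"""
from __future__ import annotations

from typing import Dict, List, Tuple

from .types import RNA_ALPHABET, CollapsedRead, PreprocessConfig, merge_reads


def clean_reads(
    reads: List[CollapsedRead], cfg: PreprocessConfig = PreprocessConfig()
) -> List[CollapsedRead]:
    """Apply the ambiguity / length-window filters and re-collapse.

    Total read count is conserved up to dropped reads, and the operation
    is idempotent.
    """
    kept: List[CollapsedRead] = []
    for r in reads:
        if set(r.sequence) - RNA_ALPHABET:
            continue
        if len(r.sequence) < cfg.min_len:
            continue
        seq = r.sequence[: cfg.max_len]
        kept.append(CollapsedRead(seq, dict(r.counts)))
    return merge_reads(kept)


def cleaning_report(
    reads: List[CollapsedRead], cfg: PreprocessConfig = PreprocessConfig()
) -> Dict[str, int]:
    """Counts of molecules dropped/truncated/kept, for funnel logging."""
    out = {"input": 0, "ambiguous": 0, "too_short": 0, "truncated": 0, "kept": 0}
    for r in reads:
        out["input"] += r.total
        if set(r.sequence) - RNA_ALPHABET:
            out["ambiguous"] += r.total
        elif len(r.sequence) < cfg.min_len:
            out["too_short"] += r.total
        else:
            if len(r.sequence) > cfg.max_len:
                out["truncated"] += r.total
            out["kept"] += r.total
    return out
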