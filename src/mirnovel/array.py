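"""Cross-platform validation against a normalized microarray matrix.

The pipeline consumes the already-normalized probe x sample intensity
table (background subtraction, LOWESS normalization and gene centering
happen upstream, on the vendor side).  Expression calls use the platform
intensity cutoff; group differences use a two-sample t-test on log2
intensities.
"""
from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
from scipy import stats

from .types import IntensityMatrix, NovelMiRNACall, Thresholds, canonical_rna


def expressed_samples(matrix: IntensityMatrix, probe: str, cutoff: float = 32.0) -> int:
    """Number of samples in which the probe's intensity reaches ``cutoff``."""
    row = matrix.row(probe)
    return int((row >= cutoff).sum())


def probe_for_call(
    call: NovelMiRNACall,
    matrix: IntensityMatrix,
    probe_sequences: Optional[Dict[str, str]] = None,
) -> Optional[str]:
    """Locate the probe matching a call.

    Probes are complementary to mature sequences, so linkage is by exact
    mature-sequence match when ``probe_sequences`` is given; otherwise
    the mature name (then the call name) is tried as a probe id.
    """
    if probe_sequences is not None:
        wanted = {canonical_rna(seq) for _, seq, _ in call.matures}
        if call.precursor.mature is not None:
            wanted.add(canonical_rna(call.precursor.mature.sequence))
        for pid, pseq in probe_sequences.items():
            if canonical_rna(pseq) in wanted and pid in matrix.values.index:
                return pid
    for _, _, name in call.matures:
        if name in matrix.values.index:
            return name
    if call.name in matrix.values.index:
        return call.name
    return None


def validate_call(
    call: NovelMiRNACall,
    matrix: IntensityMatrix,
    th: Thresholds,
    mode: str,
    probe_sequences: Optional[Dict[str, str]] = None,
    majority: float = 0.5,
) -> Dict[str, object]:
    """Array-validation flags for one call (the call is annotated in place).

    ``species-specific`` mode validates when the intensity reaches the
    cutoff in every array sample *and* the every-sample NGS expression
    filter passed.  ``homologous`` mode validates when the probe is
    expressed in more than ``majority`` of the array samples.  Calls
    without a probe are retained but flagged unvalidated (an NGS-only
    call remains reportable on biogenesis evidence alone).
    """
    from .consensus import expression_filter  # local import to avoid a cycle

    probe = probe_for_call(call, matrix, probe_sequences)
    n_samples = len(matrix.samples)
    result: Dict[str, object] = {
        "probe": probe,
        "expressed_samples": None,
        "n_array_samples": n_samples,
        "validated": False,
        "ngs_pass": None,
    }
    if mode == "species-specific":
        result["ngs_pass"] = expression_filter(
            call, min_reads=th.min_reads, scope="every-sample"
        )
    else:
        result["ngs_pass"] = expression_filter(
            call, min_reads=th.min_reads, scope="any-sample", min_samples=th.min_samples
        )
    if probe is not None:
        n_expr = expressed_samples(matrix, probe, th.array_cutoff)
        result["expressed_samples"] = n_expr
        if mode == "species-specific":
            result["validated"] = bool(n_expr == n_samples and result["ngs_pass"])
        elif mode == "homologous":
            result["validated"] = bool(n_expr > majority * n_samples)
        else:
            raise ValueError(f"unknown validation mode: {mode!r}")
    call.array = result
    return result


def group_test(
    matrix: IntensityMatrix,
    probe: str,
    groups: Optional[Dict[str, str]] = None,
    variant: str = "welch",
    epsilon: float = 0.01,
) -> Tuple[float, float]:
    """Two-sample t-test on log2 intensities between the two group labels.

    Zero intensities are floored at ``epsilon`` before the log2
    transform.  ``variant`` selects Welch (default) or pooled variance.
    Returns ``(t, two_sided_p)``; the sign of ``t`` follows the first
    group label in sorted order minus the second.
    """
    groups = groups if groups is not None else matrix.groups
    row = matrix.row(probe)
    labels = sorted(set(groups[s] for s in matrix.samples))
    if len(labels) != 2:
        raise ValueError(f"group_test needs exactly 2 groups, got {labels}")
    a = np.array([row[s] for s in matrix.samples if groups[s] == labels[0]], dtype=float)
    b = np.array([row[s] for s in matrix.samples if groups[s] == labels[1]], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    la, lb = np.log2(np.maximum(a, epsilon)), np.log2(np.maximum(b, epsilon))
    t, p = stats.ttest_ind(la, lb, equal_var=(variant == "pooled"))
    if np.isnan(t):  # both groups constant and equal: no evidence of difference
        return 0.0, 1.0
    return float(t), float(p)
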