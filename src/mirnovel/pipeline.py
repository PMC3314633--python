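"""End-to-end orchestration of the two discovery passes.

Each pass runs preprocess -> read routing -> genome alignment ->
clustering -> hairpin candidates -> Dicer-pattern filtering ->
cross-sample consensus -> expression thresholds -> naming, and (when an
intensity matrix is supplied) microarray cross-validation.  A funnel
report records per-stage input/output sizes, and every discarded
candidate is logged with its machine-readable failure reason.

Threshold defaults are the published values, so a default run *is* the
reference procedure.  Homologous calls are retained when they pass the
NGS expression cutoff or, failing that, are rescued by array evidence;
species-specific calls must meet the every-sample NGS cutoff and, when
arrays are present, the every-array intensity cutoff.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .align import align, route_reads
from .array import validate_call
from .candidate import (
    DEFAULT_FLANK,
    crop_to_hairpin,
    extract_windows,
    filter_hairpin,
    trim_precursor,
)
from .cluster import cluster_reads, predominant_alignment
from .consensus import (
    classify_and_name,
    cross_sample_merge,
    expression_filter,
    find_homologs,
)
from .dicer import analyze_candidate, dicer_filter
from .preprocess import clean_reads
from .types import (
    CollapsedRead,
    IntensityMatrix,
    NovelMiRNACall,
    PrecursorCandidate,
    PreprocessConfig,
    ReadCluster,
    ReferenceSet,
    Thresholds,
    merge_reads,
)

logger = logging.getLogger(__name__)

Funnel = List[Tuple[str, int]]


@dataclass
class PipelineConfig:
    thresholds: Thresholds = field(default_factory=Thresholds)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    flank: int = DEFAULT_FLANK
    seed_len: int = 19
    max_mm: int = 1
    fold_model: str = "auto"
    species_prefix: str = "rno"
    next_free_index: int = 5001
    seed: int = 0


def candidate_from_cluster(
    cluster: ReadCluster,
    genome: Dict[str, str],
    realign_pool: Sequence[CollapsedRead],
    cfg: PipelineConfig,
    require_star: bool,
    reject_log: Optional[Counter] = None,
) -> Optional[PrecursorCandidate]:
    """Run one cluster through windows -> hairpin screen -> trim -> Dicer.

    Tries both arm hypotheses at the default flank, then a wider pass at
    twice the flank when nothing passes the hairpin screen.  Returns the
    passing candidate from the energetically best window, or ``None``
    (recording the dominant failure reason in ``reject_log``).
    """
    th = cfg.thresholds
    reasons: Counter = Counter()
    for flank in (cfg.flank, 2 * cfg.flank):
        windows = extract_windows(cluster, genome, flank=flank, model=cfg.fold_model)
        passing = []
        for raw in windows:
            w = crop_to_hairpin(raw)
            if w is None:
                reasons.update(["no_hairpin_component"])
                continue
            ok, why = filter_hairpin(w, th)
            if ok:
                passing.append(w)
            else:
                reasons.update(why)
        for w in sorted(passing, key=lambda w: (w.structure.energy, w.arm)):
            pa = predominant_alignment(cluster)
            if w.strand == "+":
                lo = pa.start - w.start
            else:
                lo = w.end - pa.end
            hi = lo + len(pa.read.sequence)
            if lo < 0 or hi > len(w.sequence):
                reasons.update(["mature_outside_window"])
                continue
            cand = trim_precursor(w, (lo, hi), th)
            cand = analyze_candidate(cand, realign_pool, th)
            ok, why, flags = dicer_filter(cand, th, require_star=require_star)
            cand.flags.update(flags)
            if ok:
                return cand
            reasons.update(why)
    if reject_log is not None and reasons:
        reject_log.update([reasons.most_common(1)[0][0]])
    logger.debug(
        "cluster %s:%d-%d%s rejected: %s",
        cluster.chrom,
        cluster.start,
        cluster.end,
        cluster.strand,
        dict(reasons),
    )
    return None


def _run_pass(
    reads_by_sample: Dict[str, List[CollapsedRead]],
    refsets: Sequence[ReferenceSet],
    mode: str,
    cfg: PipelineConfig,
    matrix: Optional[IntensityMatrix] = None,
    probe_seqs: Optional[Dict[str, str]] = None,
) -> Tuple[List[NovelMiRNACall], Funnel]:
    th = cfg.thresholds
    funnel: Funnel = []
    samples = sorted(reads_by_sample)

    pooled = merge_reads(r for rs in reads_by_sample.values() for r in rs)
    funnel.append(("input_molecules", sum(r.total for r in pooled)))
    funnel.append(("input_unique_reads", len(pooled)))

    cleaned = clean_reads(pooled, cfg.preprocess)
    funnel.append(("cleaned_unique_reads", len(cleaned)))

    route_mode = "homologous" if mode == "homologous" else "species-specific"
    buckets = route_reads(cleaned, refsets, route_mode, seed_len=cfg.seed_len, max_mm=cfg.max_mm)
    kept = buckets["kept"]
    funnel.append(("routed_kept_reads", len(kept)))

    genome_sets = [rs for rs in refsets if rs.role == "genome"]
    if not genome_sets:
        raise ValueError("pipeline requires a reference set with role 'genome'")
    genome = genome_sets[0].sequences
    alignments = align(
        kept, genome_sets[0], seed_len=cfg.seed_len, max_mm=cfg.max_mm, both_strands=True
    )
    funnel.append(("genome_mapped_reads", len({a.read.sequence for a in alignments})))

    clusters = cluster_reads(alignments)
    funnel.append(("read_clusters", len(clusters)))

    reject_log: Counter = Counter()
    candidates: List[PrecursorCandidate] = []
    for cl in clusters:
        cand = candidate_from_cluster(
            cl, genome, cleaned, cfg, require_star=(mode == "homologous"), reject_log=reject_log
        )
        if cand is not None:
            candidates.append(cand)
    funnel.append(("dicer_candidates", len(candidates)))
    for reason, n in sorted(reject_log.items()):
        logger.info("pass[%s]: %d clusters rejected by %s", mode, n, reason)

    cands_by_sample = {
        s: [c for c in candidates if c.sample_counts.get(s, 0) > 0] for s in samples
    }
    calls = cross_sample_merge(cands_by_sample, min_samples=th.min_samples)
    funnel.append(("consensus_calls", len(calls)))

    # a novel call must not be a known miRNA of the target species (and, in
    # the specific pass, must not sit in any excluded RNA class): isomiR
    # stragglers escape the sequence-level read removal, so the rule is
    # re-applied to the called products
    known_sets = [rs for rs in refsets if rs.role == "known-rat-mirna"]
    excl_sets = [rs for rs in refsets if rs.role == "exclusion"] if mode != "homologous" else []

    def is_known(call: NovelMiRNACall) -> bool:
        p = call.precursor
        for arm in (p.mature, p.mature_star):
            if arm is None:
                continue
            for ks in known_sets:
                if find_homologs(arm.sequence, ks):
                    return True
        if p.mature is not None and excl_sets:
            probe = CollapsedRead(p.mature.sequence, {"_": 1})
            for es in excl_sets:
                if align([probe], es, seed_len=cfg.seed_len, max_mm=cfg.max_mm):
                    return True
        return False

    calls = [c for c in calls if not is_known(c)]
    funnel.append(("not_known_mirna", len(calls)))

    other_sets = [rs for rs in refsets if rs.role == "other-species-mirna"]
    used_names: set = set()
    next_idx = cfg.next_free_index
    for call in calls:
        call, next_idx = classify_and_name(
            call,
            other_sets[0] if other_sets else None,
            next_idx,
            species_prefix=cfg.species_prefix,
            used_names=used_names,
        )

    final: List[NovelMiRNACall] = []
    if mode == "homologous":
        for call in calls:
            ngs_ok = expression_filter(
                call, min_reads=th.min_reads, scope="any-sample", min_samples=th.min_samples
            )
            if matrix is not None:
                validate_call(call, matrix, th, "homologous", probe_sequences=probe_seqs)
                if ngs_ok or call.array.get("validated"):
                    final.append(call)
                else:
                    logger.info("homolog call %s dropped: no NGS or array support", call.name)
            elif ngs_ok:
                final.append(call)
            else:
                logger.info("homolog call %s dropped: below NGS expression cutoff", call.name)
    else:
        for call in calls:
            if call.mirna_class == "homologous":
                # a specific pass reports only candidates matching no known
                # miRNA; homologous loci belong to the homologous pass
                logger.info("specific call %s dropped: matches a known miRNA", call.name)
                continue
            ngs_ok = expression_filter(call, min_reads=th.min_reads, scope="every-sample")
            if not ngs_ok:
                logger.info("specific call %s dropped: every-sample NGS cutoff", call.name)
                continue
            if matrix is not None:
                validate_call(call, matrix, th, "species-specific", probe_sequences=probe_seqs)
                if not call.array.get("validated"):
                    logger.info("specific call %s dropped: array validation", call.name)
                    continue
            final.append(call)
    funnel.append(("final_calls", len(final)))
    return final, funnel


def run_homologous_pass(
    reads_by_sample: Dict[str, List[CollapsedRead]],
    refsets: Sequence[ReferenceSet],
    cfg: Optional[PipelineConfig] = None,
    matrix: Optional[IntensityMatrix] = None,
    probe_seqs: Optional[Dict[str, str]] = None,
) -> Tuple[List[NovelMiRNACall], Funnel]:
    """Discover miRNAs known in other species but novel in the target species."""
    return _run_pass(reads_by_sample, refsets, "homologous", cfg or PipelineConfig(), matrix, probe_seqs)


def run_specific_pass(
    reads_by_sample: Dict[str, List[CollapsedRead]],
    refsets: Sequence[ReferenceSet],
    cfg: Optional[PipelineConfig] = None,
    matrix: Optional[IntensityMatrix] = None,
    probe_seqs: Optional[Dict[str, str]] = None,
) -> Tuple[List[NovelMiRNACall], Funnel]:
    """Discover species-specific candidates (reads matching no known reference)."""
    return _run_pass(reads_by_sample, refsets, "specific", cfg or PipelineConfig(), matrix, probe_seqs)


def funnel_table(funnel: Funnel) -> str:
    width = max(len(stage) for stage, _ in funnel)
    return "\n".join(f"{stage.ljust(width)}  {n}" for stage, n in funnel)
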