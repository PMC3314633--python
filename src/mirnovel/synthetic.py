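"""Synthetic benchmark generator: planted hairpin loci plus noise.

Emulates the statistical structure the discovery procedure assumes, at
desk scale: an 8-sample small-RNA design (4 treated, 4 control), planted
pre-miRNA hairpins with Dicer-like read stacks (consistent 5' starts,
mature:star asymmetry, 3' isomiR heterogeneity, 2-nt duplex overhangs),
decoy loci (degradation pileups with uniform starts, shuffled-composition
windows with stacked reads), planted known-miRNA and other-ncRNA loci to
exercise read routing, and a matching 6-array intensity matrix (3
control + 3 treated).

Every output is reproducible bit-for-bit from (parameters, seed).
Planted true hairpins are *verified at construction*: a candidate locus
is rejected and redrawn unless its extraction window folds into a single
stem-loop that passes the pairing filters and shows the designed 2-nt
overhang, so the generator guarantees the geometry it claims to plant.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import write_fasta, write_intensities, write_reads
from .types import (
    Alignment,
    CollapsedRead,
    IntensityMatrix,
    ReadCluster,
    ReferenceSet,
    Thresholds,
    canonical_rna,
    merge_reads,
    revcomp,
)

NT = np.array(list("ACGT"))
_PAIR = {"A": "T", "T": "A", "G": "C", "C": "G"}

TRUE = "true-mirna"
DECOY_DEG = "decoy-degradation"
DECOY_SHUF = "decoy-shuffled-hairpin"
KNOWN = "known-mirna"
NCRNA = "other-ncRNA"


@dataclass
class PlantedLocus:
    """Ground-truth record of one planted feature (all coordinates genomic)."""

    name: str
    locus_class: str
    chrom: str
    strand: str
    start: int  # feature interval, 0-based half-open
    end: int
    mature: Optional[Tuple[int, int]] = None
    star: Optional[Tuple[int, int]] = None
    mature_seq: str = ""  # transcript-oriented RNA
    star_seq: str = ""
    depth_mean: float = 0.0
    homolog: bool = False  # mature listed in the other-species set
    aa_responsive: bool = False  # treatment effect on the array
    star_ext_dominant: bool = False  # +1 3'-extension star isomiR dominates
    dicer_overhang: int = 2


@dataclass
class SyntheticTruth:
    genome: Dict[str, str]
    loci: List[PlantedLocus]
    seed: int
    params: Dict[str, object] = field(default_factory=dict)

    def by_class(self, locus_class: str) -> List[PlantedLocus]:
        return [l for l in self.loci if l.locus_class == locus_class]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(NT[rng.integers(0, 4, size=n)])


def _design_hairpin(
    rng: np.random.Generator, mature_len: int
) -> Tuple[str, Tuple[int, int], Tuple[int, int]]:
    """One stem-loop in DNA space: lower stem, 1-nt bulge, duplex, loop.

    Returns (sequence, mature interval, star interval), local half-open.
    The star is the near-reverse-complement of the mature minus its last
    two bases plus two free 3' bases, which fixes a 2-nt 3' overhang at
    both duplex ends; 1-3 interior pairs are softened to G.T (G.U in
    RNA) wobbles.
    """
    L = mature_len
    mature = _random_dna(rng, L)
    star = list(revcomp(mature[: L - 2]) + _random_dna(rng, 2))
    # G.U softening at interior duplex positions (star[k] pairs mature[L-3-k])
    wobblable = [k for k in range(3, L - 5) if mature[L - 3 - k] in "GT"]
    rng.shuffle(wobblable)
    for k in wobblable[: int(rng.integers(1, 4))]:
        star[k] = "T" if mature[L - 3 - k] == "G" else "G"
    star = "".join(star)
    loop = _random_dna(rng, int(rng.integers(4, 11)))
    stem = _random_dna(rng, 8)
    bulge = _random_dna(rng, 1)
    if rng.random() < 0.5:  # mature on the 5' arm
        seq = stem + bulge + mature + loop + star + revcomp(stem)
        m0 = len(stem) + 1
        s0 = m0 + L + len(loop)
        return seq, (m0, m0 + L), (s0, s0 + L)
    seq = stem + bulge + star + loop + mature + revcomp(stem)
    s0 = len(stem) + 1
    m0 = s0 + L + len(loop)
    return seq, (m0, m0 + L), (s0, s0 + L)


def _verify_locus(
    seq: str, mature: Tuple[int, int], star: Tuple[int, int], flankL: str, flankR: str
) -> bool:
    """Check that the planted locus survives the candidate + Dicer stages.

    Runs the pipeline's own cluster-to-candidate stage around the mature
    stack and requires a passing candidate with the designed (perfect)
    duplex overhang.
    """
    from .pipeline import PipelineConfig, candidate_from_cluster

    contig = flankL + seq + flankR
    off = len(flankL)
    m0, m1 = mature[0] + off, mature[1] + off
    read = CollapsedRead(canonical_rna(contig[m0:m1]), {"s": 100})
    star_read = CollapsedRead(canonical_rna(contig[star[0] + off : star[1] + off]), {"s": 10})
    cluster = ReadCluster("c", "+", m0, m1, [Alignment(read, "c", m0, "+", 0)])
    cand = candidate_from_cluster(
        cluster, {"c": contig}, [read, star_read], PipelineConfig(), require_star=True
    )
    return cand is not None and cand.flags.get("perfect_overhang", False)


def _verbatim_flanks(
    rng: np.random.Generator,
    pre_d: str,
    mature: Tuple[int, int],
    max_retries: int,
) -> Tuple[str, str]:
    """Flanks that preserve a verbatim precursor's windowed hairpin.

    Real pri-miRNA context extends the precursor's lower stem rather than
    competing with it; random flanks can instead refold the window away
    from the printed structure.  Flanks are therefore redrawn (bounded
    rejection sampling) until the pipeline's own window screen — crop to
    the stem-loop over the mature stack, then the pairing filters —
    passes, so a planted printed precursor is testable for the *Dicer*
    criteria rather than lost to flank artifacts.
    """
    from .candidate import crop_to_hairpin, extract_windows, filter_hairpin

    th = Thresholds()
    read = CollapsedRead(canonical_rna(pre_d[mature[0] : mature[1]]), {"s": 1})
    # observed clusters are widened by isomiR end variants, and the window
    # (hence its fold) follows the cluster: screen the realistic extents
    jitters = [(0, 0), (-1, 0), (0, 2), (-1, 2), (-1, 1)]
    for _ in range(max_retries):
        flankL, flankR = _random_dna(rng, 100), _random_dna(rng, 100)
        contig = flankL + pre_d + flankR
        m0 = len(flankL) + mature[0]
        m1 = m0 + len(read.sequence)

        def screen(c_lo: int, c_hi: int) -> bool:
            cluster = ReadCluster("c", "+", c_lo, c_hi, [Alignment(read, "c", m0, "+", 0)])
            for raw in extract_windows(cluster, {"c": contig}):
                cropped = crop_to_hairpin(raw)
                if cropped is not None and filter_hairpin(cropped, th)[0]:
                    return True
            return False

        if all(screen(m0 + d5, m1 + d3) for d5, d3 in jitters):
            return flankL, flankR
    raise RuntimeError("could not find flanks preserving the verbatim precursor hairpin")


def plant_genome(
    n_true: int = 8,
    n_decoy: int = 8,
    contig_len: int = 1_000_000,
    seed: int = 0,
    n_known: int = 2,
    n_ncrna: int = 2,
    homolog_fraction: float = 0.5,
    verbatim: Optional[Sequence[Tuple[str, str, str, str]]] = None,
    max_retries: int = 200,
) -> SyntheticTruth:
    """Plant hairpin and decoy loci in a random contig.

    ``verbatim`` optionally plants real precursors: tuples of
    ``(name, precursor_seq, mature_seq, star_seq)`` (RNA), inserted on
    the plus strand without construction-time verification; ``star_seq``
    may be empty (no star product reads will be simulated), and a fifth
    tuple element may set the homolog flag (default True).  Half of the
    generated true loci (``homolog_fraction``) are flagged as having a
    known homolog in another species.
    """
    rng = np.random.default_rng(seed)
    genome = list(_random_dna(rng, contig_len))
    chrom = "chrS1"
    margin = 150
    occupied: List[Tuple[int, int]] = []

    def place(length: int) -> int:
        for _ in range(2000):
            pos = int(rng.integers(margin, contig_len - length - margin))
            if all(pos + length + margin <= s or pos >= e + margin for s, e in occupied):
                occupied.append((pos, pos + length))
                return pos
        raise RuntimeError("could not place locus; contig too crowded")

    loci: List[PlantedLocus] = []

    def plant_hairpin(name: str, locus_class: str, homolog: bool) -> PlantedLocus:
        for _ in range(max_retries):
            L = int(rng.integers(20, 25))
            seq, m_iv, s_iv = _design_hairpin(rng, L)
            flankL, flankR = _random_dna(rng, 100), _random_dna(rng, 100)
            if not _verify_locus(seq, m_iv, s_iv, flankL, flankR):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            insert = flankL + seq + flankR
            if strand == "-":
                insert = revcomp(insert)
            pos = place(len(insert))
            genome[pos : pos + len(insert)] = list(insert)
            if strand == "+":
                g = lambda iv: (pos + len(flankL) + iv[0], pos + len(flankL) + iv[1])
            else:
                n = len(insert)
                g = lambda iv: (
                    pos + n - len(flankL) - iv[1],
                    pos + n - len(flankL) - iv[0],
                )
            m_g, s_g = g(m_iv), g(s_iv)
            p_g = (min(g((0, len(seq)))), max(g((0, len(seq)))))
            return PlantedLocus(
                name=name,
                locus_class=locus_class,
                chrom=chrom,
                strand=strand,
                start=p_g[0],
                end=p_g[1],
                mature=m_g,
                star=s_g,
                mature_seq=canonical_rna(seq[m_iv[0] : m_iv[1]]),
                star_seq=canonical_rna(seq[s_iv[0] : s_iv[1]]),
                depth_mean=float(np.exp(rng.uniform(np.log(150), np.log(3000)))),
                homolog=homolog,
                aa_responsive=bool(rng.random() < 0.25),
                star_ext_dominant=bool(rng.random() < 0.3),
            )
        raise RuntimeError(f"failed to design a verifiable hairpin for {name}")

    n_homolog = int(round(n_true * homolog_fraction))
    for i in range(n_true):
        loci.append(plant_hairpin(f"syn-mir-{i + 1}", TRUE, homolog=i < n_homolog))
    for i in range(n_known):
        loci.append(plant_hairpin(f"known-mir-{i + 1}", KNOWN, homolog=False))

    for entry in verbatim or ():
        name, pre, mat, star = entry[:4]
        homolog = entry[4] if len(entry) > 4 else True
        pre_d = canonical_rna(pre).replace("U", "T")
        m_lo = canonical_rna(pre).find(canonical_rna(mat))
        if m_lo < 0:
            raise ValueError(f"verbatim arms of {name} not found in its precursor")
        flankL, flankR = _verbatim_flanks(
            rng, pre_d, (m_lo, m_lo + len(mat)), max_retries
        )
        insert = flankL + pre_d + flankR
        pos = place(len(insert))
        genome[pos : pos + len(insert)] = list(insert)
        m0 = m_lo
        s0 = canonical_rna(pre).find(canonical_rna(star)) if star else -1
        if star and s0 < 0:
            raise ValueError(f"verbatim star of {name} not found in its precursor")
        base = pos + len(flankL)
        loci.append(
            PlantedLocus(
                name=name,
                locus_class=TRUE,
                chrom=chrom,
                strand="+",
                start=base,
                end=base + len(pre_d),
                mature=(base + m0, base + m0 + len(mat)),
                star=(base + s0, base + s0 + len(star)) if star else None,
                mature_seq=canonical_rna(mat),
                star_seq=canonical_rna(star) if star else "",
                depth_mean=float(np.exp(rng.uniform(np.log(150), np.log(3000)))),
                homolog=homolog,
                aa_responsive=False,
                star_ext_dominant=False,
            )
        )

    for i in range(n_decoy):
        if i % 2 == 0:  # degradation region: plain genome, uniform read starts
            length = 200
            pos = place(length)
            loci.append(
                PlantedLocus(
                    name=f"decoy-deg-{i + 1}",
                    locus_class=DECOY_DEG,
                    chrom=chrom,
                    strand="+",
                    start=pos,
                    end=pos + length,
                    depth_mean=300.0,
                )
            )
        else:  # shuffled hairpin composition with a stacked read
            L = int(rng.integers(20, 25))
            seq, m_iv, _ = _design_hairpin(rng, L)
            shuffled = list(seq)
            rng.shuffle(shuffled)
            pos = place(len(shuffled))
            genome[pos : pos + len(shuffled)] = shuffled
            loci.append(
                PlantedLocus(
                    name=f"decoy-shuf-{i + 1}",
                    locus_class=DECOY_SHUF,
                    chrom=chrom,
                    strand="+",
                    start=pos,
                    end=pos + len(shuffled),
                    mature=(pos + m_iv[0], pos + m_iv[1]),
                    mature_seq=canonical_rna(
                        "".join(shuffled[m_iv[0] : m_iv[1]])
                    ),
                    depth_mean=300.0,
                )
            )

    for i in range(n_ncrna):  # e.g. tRNA/rRNA fragments source regions
        length = 120
        pos = place(length)
        loci.append(
            PlantedLocus(
                name=f"ncrna-{i + 1}",
                locus_class=NCRNA,
                chrom=chrom,
                strand="+",
                start=pos,
                end=pos + length,
                depth_mean=200.0,
            )
        )

    truth = SyntheticTruth(
        genome={chrom: "".join(genome)},
        loci=loci,
        seed=seed,
        params={
            "n_true": n_true,
            "n_decoy": n_decoy,
            "contig_len": contig_len,
            "n_known": n_known,
            "n_ncrna": n_ncrna,
            "homolog_fraction": homolog_fraction,
        },
    )
    return truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def sample_ids(n_samples: int = 8) -> List[str]:
    half = n_samples // 2
    return [f"CTL{i + 1}" for i in range(half)] + [f"AA{i + 1}" for i in range(n_samples - half)]


def _nbinom(rng: np.random.Generator, mean: float, size: float = 10.0) -> int:
    """Negative binomial draw parameterized by mean and dispersion size."""
    if mean <= 0:
        return 0
    p = size / (size + mean)
    return int(rng.negative_binomial(size, p))


def _shift_probs(sd: float) -> np.ndarray:
    """Discretized centered normal over shifts -2..2."""
    from scipy.stats import norm

    edges = np.array([-np.inf, -1.5, -0.5, 0.5, 1.5, np.inf])
    return np.diff(norm.cdf(edges, loc=0, scale=max(sd, 1e-9)))


def _arm_variants(
    truth: SyntheticTruth,
    locus: PlantedLocus,
    arm: Tuple[int, int],
    fluct_sd: float,
    isomir_rate: float,
    ext_dominant: bool,
) -> List[Tuple[str, float]]:
    """(sequence, probability) for the 5'/3' end-variant grid of one arm."""
    p5 = _shift_probs(fluct_sd)
    if ext_dominant:
        p3 = np.array([0.0, 0.1, 0.3, 0.6, 0.0])
    else:
        r = isomir_rate
        p3 = np.array([0.03 * r, 0.3 * r, 1 - r, 0.6 * r, 0.07 * r])
    contig = truth.genome[locus.chrom]
    out: List[Tuple[str, float]] = []
    for i5, s5 in enumerate(range(-2, 3)):
        for i3, s3 in enumerate(range(-2, 3)):
            prob = float(p5[i5] * p3[i3])
            if prob <= 0:
                continue
            if locus.strand == "+":
                lo, hi = arm[0] + s5, arm[1] + s3
            else:
                lo, hi = arm[0] - s3, arm[1] - s5
            if lo < 0 or hi > len(contig) or hi - lo < 16:
                continue
            seq = contig[lo:hi]
            if locus.strand == "-":
                seq = revcomp(seq)
            out.append((canonical_rna(seq), prob))
    total = sum(p for _, p in out)
    return [(s, p / total) for s, p in out]


def simulate_reads(
    truth: SyntheticTruth,
    n_samples: int = 8,
    depth: Optional[Dict[str, float]] = None,
    fluct_sd: float = 0.3,
    isomir_rate: float = 0.3,
    bg_rate: float = 1.0,
    star_ratio: float = 10.0,
    seed: int = 0,
) -> Dict[str, List[CollapsedRead]]:
    """Per-sample collapsed read sets over the planted truth.

    Per locus and sample, molecule counts are negative binomial around
    the locus depth (``depth`` overrides per locus name); the mature:star
    ratio defaults to 10:1; 5' starts are jittered tightly
    (``fluct_sd``), 3' ends more (``isomir_rate``), with a dominant +1
    3'-extension star isomiR regime at flagged loci.  Degradation and
    ncRNA loci emit uniform-start fragments scaled by ``bg_rate``.
    """
    rng = np.random.default_rng(seed + 1)
    samples = sample_ids(n_samples)
    reads_by_sample: Dict[str, List[CollapsedRead]] = {s: [] for s in samples}

    def emit(sample: str, variants: List[Tuple[str, float]], n: int) -> None:
        if n <= 0 or not variants:
            return
        probs = np.array([p for _, p in variants])
        counts = rng.multinomial(n, probs)
        for (seq, _), c in zip(variants, counts):
            if c > 0:
                reads_by_sample[sample].append(CollapsedRead(seq, {sample: int(c)}))

    for locus in truth.loci:
        mean = (depth or {}).get(locus.name, locus.depth_mean)
        if locus.locus_class in (TRUE, KNOWN):
            mat_var = _arm_variants(truth, locus, locus.mature, fluct_sd, isomir_rate, False)
            star_var = (
                _arm_variants(
                    truth, locus, locus.star, fluct_sd, isomir_rate, locus.star_ext_dominant
                )
                if locus.star is not None
                else []
            )
            for s in samples:
                emit(s, mat_var, _nbinom(rng, mean))
                if star_var:
                    emit(s, star_var, _nbinom(rng, mean / star_ratio))
        elif locus.locus_class == DECOY_SHUF:
            mat_var = _arm_variants(truth, locus, locus.mature, fluct_sd, isomir_rate, False)
            for s in samples:
                emit(s, mat_var, _nbinom(rng, mean * bg_rate))
        else:  # degradation-style fragments, uniform starts
            contig = truth.genome[locus.chrom]
            k = 15
            starts = rng.integers(locus.start, locus.end - 26, size=k)
            lens = rng.integers(18, 26, size=k)
            variants = [
                (canonical_rna(contig[int(a) : int(a) + int(l)]), 1.0 / k)
                for a, l in zip(starts, lens)
            ]
            for s in samples:
                emit(s, variants, _nbinom(rng, mean * bg_rate))

    return {s: merge_reads(rs) for s, rs in reads_by_sample.items()}


def pooled_reads(reads_by_sample: Dict[str, List[CollapsedRead]]) -> List[CollapsedRead]:
    """Merge per-sample read sets into multi-sample collapsed reads."""
    return merge_reads(r for rs in reads_by_sample.values() for r in rs)


# ---------------------------------------------------------------------------
# reference sets
# ---------------------------------------------------------------------------

def build_reference_sets(truth: SyntheticTruth) -> List[ReferenceSet]:
    """Reference sets matching the planted truth.

    Known planted loci populate the known-miRNA set of the target
    species; homolog-flagged true loci put their mature (and star) in the
    other-species set; ncRNA regions form the exclusion set.
    """
    known = {
        f"{l.name}-mature": l.mature_seq for l in truth.by_class(KNOWN)
    }
    other = {}
    for i, l in enumerate(truth.by_class(TRUE)):
        if l.homolog:
            fam = 9000 + i + 1
            other[f"mmu-miR-{fam}"] = l.mature_seq
            if l.star_seq:
                other[f"mmu-miR-{fam}*"] = l.star_seq
    exclusion = {
        l.name: canonical_rna(truth.genome[l.chrom][l.start : l.end])
        for l in truth.by_class(NCRNA)
    }
    return [
        ReferenceSet("known-rat", "known-rat-mirna", known),
        ReferenceSet("other-species", "other-species-mirna", other),
        ReferenceSet("ncrna-exclusion", "exclusion", exclusion),
        ReferenceSet("genome", "genome", dict(truth.genome)),
    ]


# ---------------------------------------------------------------------------
# intensity simulation
# ---------------------------------------------------------------------------

def simulate_intensities(
    truth: SyntheticTruth,
    n_arrays: int = 6,
    seed: int = 0,
    dropout: float = 0.0,
    group_effect: float = 2.0,
    base_mean: float = 200.0,
    n_background: int = 20,
) -> Tuple[IntensityMatrix, Dict[str, str]]:
    """Matching microarray matrix: 3 control + 3 treated arrays by default.

    Expressed (true and known) loci receive log-normal intensities above
    the expression cutoff with optional ``dropout``; treatment-responsive
    loci are scaled by ``group_effect`` in the treated arrays; background
    probes stay below the cutoff.  Returns the matrix and the probe
    id -> probe sequence map used for sequence-based call linkage.
    """
    rng = np.random.default_rng(seed + 2)
    half = n_arrays // 2
    arrays = [f"aCTL{i + 1}" for i in range(half)] + [
        f"aAA{i + 1}" for i in range(n_arrays - half)
    ]
    groups = {a: ("control" if a.startswith("aCTL") else "treated") for a in arrays}

    probe_seqs: Dict[str, str] = {}
    rows: Dict[str, List[float]] = {}
    for locus in truth.loci:
        if locus.locus_class not in (TRUE, KNOWN):
            continue
        probe_seqs[locus.name] = locus.mature_seq
        vals = []
        for a in arrays:
            if rng.random() < dropout:
                vals.append(float(rng.uniform(0, 20)))
                continue
            v = float(np.exp(rng.normal(np.log(base_mean), 0.4)))
            if locus.aa_responsive and groups[a] == "treated":
                v *= group_effect
            vals.append(round(v, 2))
        rows[locus.name] = vals
    for i in range(n_background):
        pid = f"bg-probe-{i + 1}"
        probe_seqs[pid] = canonical_rna(_random_dna(rng, 22))
        rows[pid] = [round(float(rng.uniform(0, 20)), 2) for _ in arrays]

    df = pd.DataFrame.from_dict(rows, orient="index", columns=arrays)
    return IntensityMatrix(df, groups), probe_seqs


# ---------------------------------------------------------------------------
# scoring and export
# ---------------------------------------------------------------------------

def score_calls(truth: SyntheticTruth, calls: Sequence, which: str = "all") -> Dict[str, object]:
    """Compare pipeline calls against the planted truth by interval overlap.

    ``which`` restricts the recovery denominator to the loci a pass can
    see: ``homolog`` (loci with a known other-species homolog),
    ``specific`` (loci without), or ``all``.
    """
    def wanted(locus: PlantedLocus) -> bool:
        if which == "homolog":
            return locus.homolog
        if which == "specific":
            return not locus.homolog
        return True

    def overlaps(call, locus) -> bool:
        p = call.precursor
        return (
            p.chrom == locus.chrom
            and p.strand == locus.strand
            and p.start < locus.end
            and locus.start < p.end
        )

    recovered = []
    decoy_hits = []
    unmatched = []
    for call in calls:
        hit = next((l for l in truth.loci if overlaps(call, l)), None)
        if hit is None:
            unmatched.append(call.name)
        elif hit.locus_class == TRUE and wanted(hit):
            recovered.append(hit.name)
        elif hit.locus_class in (DECOY_DEG, DECOY_SHUF):
            decoy_hits.append(hit.name)
    true_names = [l.name for l in truth.by_class(TRUE) if wanted(l)]
    return {
        "n_true": len(true_names),
        "recovered": sorted(set(recovered)),
        "recovery": len(set(recovered)) / len(true_names) if true_names else float("nan"),
        "decoys_called": sorted(set(decoy_hits)),
        "false_calls": sorted(set(decoy_hits) | set(unmatched)),
    }


def write_benchmark(
    truth: SyntheticTruth,
    reads_by_sample: Dict[str, List[CollapsedRead]],
    matrix: IntensityMatrix,
    probe_seqs: Dict[str, str],
    outdir,
) -> None:
    """Write genome, per-sample collapsed FASTA, reference sets, intensity
    table and the truth table to ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(truth.genome, outdir / "genome.fa")
    for sample, reads in reads_by_sample.items():
        write_reads(reads, outdir / f"reads_{sample}.fa", sample)
    for rs in build_reference_sets(truth):
        if rs.role != "genome":
            write_fasta(
                {k: v.replace("U", "T") for k, v in rs.sequences.items()},
                outdir / f"ref_{rs.name}.fa",
            )
    write_intensities(matrix, outdir / "intensities.tsv")
    write_fasta({k: v.replace("U", "T") for k, v in probe_seqs.items()}, outdir / "probes.fa")
    rows = [
        {
            "name": l.name,
            "class": l.locus_class,
            "chrom": l.chrom,
            "strand": l.strand,
            "start": l.start,
            "end": l.end,
            "mature_start": l.mature[0] if l.mature else "",
            "mature_end": l.mature[1] if l.mature else "",
            "depth_mean": round(l.depth_mean, 2),
            "homolog": l.homolog,
            "aa_responsive": l.aa_responsive,
        }
        for l in truth.loci
    ]
    pd.DataFrame(rows).to_csv(outdir / "truth.tsv", sep="\t", index=False)
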