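"""Core value types shared across the discovery pipeline.

Coordinates are 0-based half-open throughout; format writers convert at
the boundary (GFF3 1-based inclusive, BED 0-based half-open).  Sequences
are stored canonically as uppercase RNA (``U``, never ``T``).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGUTacgut", "UGCAAugcaa")
_DNA_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def canonical_rna(seq: str) -> str:
    """Uppercase and convert T to U (idempotent)."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving the RNA/DNA convention of the input."""
    if "U" in seq or "u" in seq:
        return seq.translate(_COMPLEMENT)[::-1]
    return seq.translate(_DNA_COMPLEMENT)[::-1]


@dataclass
class CollapsedRead:
    """A unique small-RNA sequence with per-sample read counts."""

    sequence: str
    counts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = canonical_rna(self.sequence)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.sequence)

    def merged(self, other: "CollapsedRead") -> "CollapsedRead":
        if other.sequence != self.sequence:
            raise ValueError("cannot merge reads with different sequences")
        counts = dict(self.counts)
        for k, v in other.counts.items():
            counts[k] = counts.get(k, 0) + v
        return CollapsedRead(self.sequence, counts)


def merge_reads(reads) -> List[CollapsedRead]:
    """Collapse a read iterable on sequence identity, summing per-sample counts."""
    by_seq: Dict[str, CollapsedRead] = {}
    for r in reads:
        if r.sequence in by_seq:
            by_seq[r.sequence] = by_seq[r.sequence].merged(r)
        else:
            by_seq[r.sequence] = CollapsedRead(r.sequence, dict(r.counts))
    return list(by_seq.values())


@dataclass
class IntensityMatrix:
    """Probe x sample matrix of normalized microarray intensities."""

    values: pd.DataFrame  # rows = probes, columns = samples
    groups: Dict[str, str]  # sample id -> group label

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")

    @property
    def probes(self) -> List[str]:
        return list(self.values.index)

    @property
    def samples(self) -> List[str]:
        return list(self.values.columns)

    def row(self, probe: str):
        if probe not in self.values.index:
            raise KeyError(f"unknown probe: {probe}")
        return self.values.loc[probe]


@dataclass
class PreprocessConfig:
    """Read-cleaning bounds: keep [min_len, max_len], truncating longer reads."""

    min_len: int = 17
    max_len: int = 26

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("require 0 < min_len <= max_len")


@dataclass
class Alignment:
    """Placement of a read on a reference, 5'-anchored seed semantics."""

    read: CollapsedRead
    ref_id: str
    start: int  # 0-based offset of the leftmost reference base covered
    strand: str  # '+' or '-'
    mismatches: int

    @property
    def end(self) -> int:
        return self.start + len(self.read.sequence)

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the read's 5' end (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class ReferenceSet:
    """Named collection of reference sequences with a routing role."""

    name: str
    role: str  # known-rat-mirna | other-species-mirna | exclusion | genome
    sequences: Dict[str, str]

    ROLES = ("known-rat-mirna", "other-species-mirna", "exclusion", "genome")

    def __post_init__(self) -> None:
        if self.role not in self.ROLES:
            raise ValueError(f"unknown reference role: {self.role}")


@dataclass
class ReadCluster:
    """A strand-aware stack of overlapping genome alignments (putative mature locus)."""

    chrom: str
    strand: str
    start: int
    end: int
    members: List[Alignment] = field(default_factory=list)

    @property
    def counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for a in self.members:
            for s, c in a.read.counts.items():
                out[s] = out.get(s, 0) + c
        return out

    @property
    def total(self) -> int:
        return sum(a.read.total for a in self.members)


@dataclass
class HairpinStructure:
    """A sequence with its dot-bracket secondary structure.

    ``pairs`` maps each paired 0-based position to its partner
    (symmetric).  ``energy`` is kcal/mol under the thermodynamic model,
    or the (negated) pairing score under the maximum-pairing model.
    """

    sequence: str
    dotbracket: str
    pairs: Dict[int, int]
    energy: float
    model: str = "thermo"

    def __post_init__(self) -> None:
        if len(self.dotbracket) != len(self.sequence):
            raise ValueError("structure/sequence length mismatch")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs) // 2

    def partner(self, i: int) -> Optional[int]:
        return self.pairs.get(i)


@dataclass
class Thresholds:
    """Every numeric filter of the discovery procedure, with its published default."""

    min_total_pairs: int = 19  # base pairs required in the whole hairpin
    min_cluster_pairs: int = 11  # pairs touching the read-cluster (mature) region
    min_precursor_len: int = 65  # nt; extension floor when no bulge is reached
    overhang_range: Tuple[int, int] = (1, 4)  # accepted 3' overhang, nt
    perfect_overhang: int = 2  # canonical Dicer overhang, nt
    max_start_fluct: int = 2  # exclusive: 5' start fluctuation must be < this
    min_samples: int = 4  # of n_samples, for cross-sample consensus
    n_samples: int = 8
    min_reads: int = 10  # NGS read-count cutoff
    array_cutoff: float = 32.0  # microarray expression intensity cutoff


@dataclass
class CandidateWindow:
    """A genome window around a read cluster, folded under one arm hypothesis."""

    cluster: ReadCluster
    chrom: str
    strand: str
    start: int
    end: int
    sequence: str  # strand-corrected RNA
    structure: Optional[HairpinStructure]
    arm: str  # '5p' or '3p': which arm the cluster is hypothesized to be
    clipped: bool = False

    @property
    def cluster_region(self) -> Tuple[int, int]:
        """Cluster interval in window-local (strand-corrected) coordinates."""
        if self.strand == "+":
            return (self.cluster.start - self.start, self.cluster.end - self.start)
        return (self.end - self.cluster.end, self.end - self.cluster.start)

    def local_to_genomic(self, pos: int) -> int:
        if self.strand == "+":
            return self.start + pos
        return self.end - 1 - pos


@dataclass
class ArmProduct:
    """One arm's product: interval local to the precursor, sequence, counts."""

    arm: str  # '5p' | '3p'
    start: int  # local, 0-based
    end: int  # local, half-open
    sequence: str
    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class PrecursorCandidate:
    """A trimmed hairpin precursor with called arms and Dicer-pattern evidence."""

    sequence: str
    structure: HairpinStructure
    chrom: str = ""
    strand: str = "+"
    start: int = 0  # genomic, 0-based half-open
    end: int = 0
    mature: Optional[ArmProduct] = None
    mature_star: Optional[ArmProduct] = None
    overhangs: Optional[Tuple[Optional[int], Optional[int]]] = None
    start_fluct: Optional[int] = None
    isomirs: List[Tuple[str, int, Dict[str, int]]] = field(default_factory=list)
    flags: Dict[str, bool] = field(default_factory=dict)
    clipped: bool = False

    @property
    def sample_counts(self) -> Dict[str, int]:
        return dict(self.mature.counts) if self.mature else {}

    def local_to_genomic(self, pos: int) -> int:
        if self.strand == "+":
            return self.start + pos
        return self.end - 1 - pos

    def genomic_interval_of(self, a: ArmProduct) -> Tuple[int, int]:
        g = sorted((self.local_to_genomic(a.start), self.local_to_genomic(a.end - 1)))
        return (g[0], g[1] + 1)


@dataclass
class NovelMiRNACall:
    """A final novel-miRNA call with naming, class and cross-platform evidence."""

    name: str
    mirna_class: str  # 'homologous' | 'species-specific'
    precursor: PrecursorCandidate
    matures: List[Tuple[str, str, str]] = field(default_factory=list)  # (arm, seq, name)
    n_samples_detected: int = 0
    sample_counts: Dict[str, int] = field(default_factory=dict)
    homolog_ids: List[str] = field(default_factory=list)
    array: Dict[str, object] = field(default_factory=dict)

    @property
    def chrom(self) -> str:
        return self.precursor.chrom

    @property
    def strand(self) -> str:
        return self.precursor.strand
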