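"""Readers and writers for the external formats the pipeline touches.

Reads are collapsed on input: identical sequences are merged and their
counts attributed to the sample being read.  T and U are treated as
equivalent and stored canonically as U.  FASTQ quality strings are
discarded (no step of the procedure uses them).
"""
from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .types import (
    CollapsedRead,
    IntensityMatrix,
    NovelMiRNACall,
    RNA_ALPHABET,
    canonical_rna,
    merge_reads,
    revcomp,
)


class ParseError(ValueError):
    """Malformed input record; the message names the offending location."""


_COLLAPSED_X = re.compile(r"_x(\d+)$")
_COLLAPSED_DASH = re.compile(r"-(\d+)$")


def _seq_records(path: Path, fmt: str) -> Iterable[Tuple[int, str, str]]:
    """Yield (record number, header id, sequence) via Biopython's parsers."""
    from Bio import SeqIO

    recno = 0
    try:
        for rec in SeqIO.parse(str(path), fmt):
            recno += 1
            yield recno, (rec.id or rec.description), str(rec.seq)
    except ValueError as e:
        raise ParseError(f"{path}: near record {recno + 1}: {e}") from e


def read_reads(
    path, format: str, sample_id: str, collapsed_dialect: str = "_x"
) -> List[CollapsedRead]:
    """Read small-RNA reads and collapse identical sequences for one sample.

    ``format`` is one of ``fastq``, ``fasta``, ``collapsed-fasta``.  The
    collapsed-FASTA count dialect is the ``_x<count>`` header suffix by
    default; ``collapsed_dialect="-"`` accepts the ``-<count>`` suffix.
    """
    path = Path(path)
    if format == "fastq":
        records = _seq_records(path, "fastq")
        counter = None
    elif format == "fasta":
        records = _seq_records(path, "fasta")
        counter = None
    elif format == "collapsed-fasta":
        records = _seq_records(path, "fasta")
        counter = _COLLAPSED_X if collapsed_dialect == "_x" else _COLLAPSED_DASH
    else:
        raise ValueError(f"unknown read format: {format!r}")

    reads: List[CollapsedRead] = []
    for recno, header, seq in records:
        if not seq:
            raise ParseError(f"{path}: record {recno} ({header!r}) has no sequence")
        count = 1
        if counter is not None:
            m = counter.search(header)
            if not m:
                raise ParseError(
                    f"{path}: record {recno}: header {header!r} lacks a "
                    f"{'_x<count>' if counter is _COLLAPSED_X else '-<count>'} suffix"
                )
            count = int(m.group(1))
        reads.append(CollapsedRead(seq, {sample_id: count}))
    return merge_reads(reads)


def write_reads(reads: Sequence[CollapsedRead], path, sample_id: str) -> None:
    """Write one sample's reads as collapsed FASTA (``>r<i>_x<count>``)."""
    with open(path, "w") as fh:
        for i, r in enumerate(sorted(reads, key=lambda r: r.sequence), 1):
            c = r.counts.get(sample_id, 0)
            if c > 0:
                fh.write(f">r{i}_x{c}\n{r.sequence}\n")


def read_fasta(path) -> Dict[str, str]:
    """FASTA file as an ordered id -> sequence map (uppercased)."""
    out: Dict[str, str] = {}
    for recno, header, seq in _seq_records(Path(path), "fasta"):
        rid = header.split()[0]
        if rid in out:
            raise ParseError(f"{path}: record {recno}: duplicated record id {rid!r}")
        out[rid] = seq.upper()
    return out


def write_fasta(sequences: Dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in sequences.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# intensity tables
# ---------------------------------------------------------------------------

def read_intensities(path, group_map: Dict[str, str], sep: str = "\t") -> IntensityMatrix:
    """Read a delimited probe x sample intensity table, no transformation.

    First column is the probe id; all remaining columns must be numeric.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].tolist()
        raise ParseError(f"{path}: duplicated probe id(s): {dup}")
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            probe = df.index[converted.isna()][0]
            raise ParseError(f"{path}: non-numeric intensity at probe {probe!r}, sample {col!r}")
        numeric[col] = converted.astype(float)
    return IntensityMatrix(numeric, dict(group_map))


def write_intensities(matrix: IntensityMatrix, path, sep: str = "\t") -> None:
    matrix.values.to_csv(path, sep=sep, index_label="probe")


# ---------------------------------------------------------------------------
# annotation output
# ---------------------------------------------------------------------------

def write_calls(calls: Sequence[NovelMiRNACall], gff_path, fasta_path) -> None:
    """Write calls as GFF3 (1-based inclusive) plus precursor/mature FASTA."""
    seqs: Dict[str, str] = {}
    with open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for call in calls:
            p = call.precursor
            pid = call.name.replace("miR", "mir")
            gff.write(
                "\t".join(
                    [
                        p.chrom,
                        "mirnovel",
                        "miRNA_primary_transcript",
                        str(p.start + 1),
                        str(p.end),
                        ".",
                        p.strand,
                        ".",
                        f"ID={pid};Name={pid};class={call.mirna_class}",
                    ]
                )
                + "\n"
            )
            seqs[pid] = p.sequence
            for arm, seq, name in call.matures:
                prod = p.mature if p.mature and p.mature.arm == arm else p.mature_star
                if prod is None:
                    continue
                g0, g1 = p.genomic_interval_of(prod)
                gff.write(
                    "\t".join(
                        [
                            p.chrom,
                            "mirnovel",
                            "miRNA",
                            str(g0 + 1),
                            str(g1),
                            ".",
                            p.strand,
                            ".",
                            f"ID={name};Name={name};Derives_from={pid}",
                        ]
                    )
                    + "\n"
                )
                seqs[name] = seq
    write_fasta(seqs, fasta_path)


def read_gff3(path) -> List[Dict[str, object]]:
    """Minimal GFF3 reader for round-tripping the pipeline's own output.

    Returns one dict per feature with 0-based half-open ``start``/``end``.
    """
    feats: List[Dict[str, object]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            feats.append(
                {
                    "chrom": parts[0],
                    "type": parts[2],
                    "start": int(parts[3]) - 1,
                    "end": int(parts[4]),
                    "strand": parts[6],
                    "attributes": attrs,
                }
            )
    return feats


def write_clusters_bed(clusters, path) -> None:
    """BED6 export of read clusters (0-based half-open, as BED requires)."""
    with open(path, "w") as fh:
        for i, c in enumerate(clusters, 1):
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\tcluster{i}\t{c.total}\t{c.strand}\n")


def extract_interval(genome: Dict[str, str], chrom: str, start: int, end: int, strand: str) -> str:
    """Strand-corrected RNA slice of a genome contig (0-based half-open)."""
    piece = genome[chrom][start:end]
    if strand == "-":
        piece = revcomp(piece)
    return canonical_rna(piece)


def format_structure_block(structure, pileup: Optional[Sequence] = None) -> str:
    """Sequence line + dot-bracket line (+ energy), with aligned reads below.

    ``pileup`` is an optional iterable of ``(read, offset, counts)``; each
    read is printed indented to its offset with its total count on the
    right, mirroring the conventional precursor-report layout.
    """
    lines = [f"# energy {structure.energy:.2f} ({structure.model})"]
    lines.append(structure.sequence)
    lines.append(structure.dotbracket)
    if pileup:
        for read, offset, counts in pileup:
            total = sum(counts.values())
            lines.append(" " * offset + read + f"  {total}")
    return "\n".join(lines) + "\n"
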