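"""Published reference data for the nine novel rat kidney pre-miRNAs.

These are the printed sequences, genome locations, per-sample sequencing
read counts and microarray intensities of the five homologous and four
rat-specific novel miRNAs discovered in the rat kidney small-RNA study
this pipeline re-implements.  They serve as worked-example inputs for
tests and for the acceptance computations.

Sequencing samples are CTL13-CTL16 (control) and AA19-AA22 (aristolochic
acid treated); array samples are a 3+3 subset (column names carry an
``a`` prefix here to keep the two platforms distinct).
"""
from __future__ import annotations

from importlib import resources
from typing import Dict, List, Tuple

import pandas as pd

from .types import CollapsedRead, IntensityMatrix

NGS_SAMPLES = ["CTL13", "CTL14", "CTL15", "CTL16", "AA19", "AA20", "AA21", "AA22"]
ARRAY_SAMPLES = ["aCTL13", "aCTL14", "aCTL15", "aAA19", "aAA20", "aAA21"]
ARRAY_GROUPS = {s: ("control" if "CTL" in s else "treated") for s in ARRAY_SAMPLES}


def _data_path(name: str):
    return resources.files("mirnovel.data").joinpath(name)


def _read_tsv(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def _read_fasta(name: str) -> Dict[str, str]:
    from .io import read_fasta

    with resources.as_file(_data_path(name)) as p:
        return read_fasta(p)


def homologous_matures() -> pd.DataFrame:
    """Mature/mature* sequences and genome locations of the 5 homologous loci."""
    return _read_tsv("homologous_matures.tsv")


def homologous_precursors() -> Dict[str, str]:
    return _read_fasta("homologous_precursors.fa")


def homolog_matches() -> pd.DataFrame:
    """Known other-species miRNAs matched by each homologous mature."""
    return _read_tsv("homolog_matches.tsv")


def specific_matures() -> pd.DataFrame:
    return _read_tsv("specific_matures.tsv")


def specific_precursors() -> Dict[str, str]:
    return _read_fasta("specific_precursors.fa")


def all_precursors() -> Dict[str, str]:
    """All nine published precursors (five homologous + four specific)."""
    out = homologous_precursors()
    out.update(specific_precursors())
    return out


def _expression(name: str) -> pd.DataFrame:
    df = _read_tsv(name).set_index("name")
    return df.astype(float)


def ngs_counts(which: str = "homolog") -> pd.DataFrame:
    """Per-sample sequencing read counts (rows = miRNAs, cols = 8 samples)."""
    df = _expression(f"{which}_expression.tsv")
    return df[NGS_SAMPLES].astype(int)


def array_intensities(which: str = "homolog") -> IntensityMatrix:
    """Published microarray intensities as an IntensityMatrix (6 arrays)."""
    df = _expression(f"{which}_expression.tsv")
    return IntensityMatrix(df[ARRAY_SAMPLES], dict(ARRAY_GROUPS))


def reads_from_counts(which: str = "homolog") -> List[CollapsedRead]:
    """The printed matures as collapsed reads with their printed counts."""
    seqs = (homologous_matures() if which == "homolog" else specific_matures()).set_index("name")[
        "sequence"
    ]
    counts = ngs_counts(which)
    return [
        CollapsedRead(seqs[name], {s: int(counts.loc[name, s]) for s in NGS_SAMPLES})
        for name in counts.index
    ]
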