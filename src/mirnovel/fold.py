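"""RNA secondary-structure prediction for hairpin candidates.

Two energy models sit behind one interface:

* ``thermo`` — the nearest-neighbor minimum-free-energy model of the
  ViennaRNA package (used when its Python bindings are importable).
* ``maxpair`` — a built-in dynamic-programming maximum-weighted-pairing
  model (GC=3, AU=2, GU=1, hairpin loop >= 3 nt), dependency-free and
  fully deterministic.

All pre-miRNA filters downstream are pair-count and topology thresholds,
so either model can drive them; thermodynamic energies are only reported
by the ``thermo`` model.
"""
from __future__ import annotations

import functools
from typing import Dict, Optional, Tuple

from .types import RNA_ALPHABET, HairpinStructure, canonical_rna

try:  # ViennaRNA bindings, optional at runtime
    import RNA as _vienna
except ImportError:  # pragma: no cover - exercised only without ViennaRNA
    _vienna = None

#: pairing weights of the maximum-pairing model
PAIR_WEIGHT: Dict[frozenset, int] = {
    frozenset("GC"): 3,
    frozenset("AU"): 2,
    frozenset("GU"): 1,
}
MIN_LOOP = 3  # minimal hairpin loop length, nt


def thermo_available() -> bool:
    return _vienna is not None


def pair_table(dotbracket: str) -> Dict[int, int]:
    """Symmetric position->partner map from a dot-bracket string."""
    pairs: Dict[int, int] = {}
    stack = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
        elif c != ".":
            raise ValueError(f"unexpected structure character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pairs


def _pair_weight(a: str, b: str) -> int:
    return PAIR_WEIGHT.get(frozenset((a, b)), 0)


def _maxpair_fold(seq: str) -> Tuple[str, float]:
    """Maximum-weighted-pairing DP (Nussinov-style) with deterministic traceback.

    Ties are broken toward more base pairs, then toward the 5'-most
    pairing partner.
    """
    n = len(seq)
    # score[i][j], npair[i][j] over half-open spans; choice records traceback
    score = [[0] * (n + 1) for _ in range(n + 1)]
    npair = [[0] * (n + 1) for _ in range(n + 1)]
    choice = [[-1] * (n + 1) for _ in range(n + 1)]  # k paired with j-1, or -1
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span  # half-open end; last base index j-1
            best_s, best_p, best_k = score[i][j - 1], npair[i][j - 1], -1
            last = seq[j - 1]
            for k in range(i, j - 1 - MIN_LOOP):
                w = _pair_weight(seq[k], last)
                if w == 0:
                    continue
                s = score[i][k] + score[k + 1][j - 1] + w
                p = npair[i][k] + npair[k + 1][j - 1] + 1
                if s > best_s or (s == best_s and (p > best_p or (p == best_p and best_k == -1))):
                    best_s, best_p, best_k = s, p, k
            score[i][j], npair[i][j], choice[i][j] = best_s, best_p, best_k

    db = ["."] * n
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < 2:
            continue
        k = choice[i][j]
        if k == -1:
            stack.append((i, j - 1))
        else:
            db[k], db[j - 1] = "(", ")"
            stack.append((i, k))
            stack.append((k + 1, j - 1))
    return "".join(db), -float(score[0][n])


def _thermo_fold(seq: str) -> Tuple[str, float]:
    md = _vienna.md()  # default Turner parameters, 37 C
    fc = _vienna.fold_compound(seq, md)
    db, mfe = fc.mfe()
    return db, float(mfe)


def fold(sequence: str, model: str = "auto") -> HairpinStructure:
    """Predict the minimum-energy (or maximum-pairing) structure of ``sequence``.

    Parameters
    ----------
    sequence:
        RNA string, length >= 10; T is accepted and canonicalized to U.
    model:
        ``"thermo"``, ``"maxpair"``, or ``"auto"`` (thermo when the
        ViennaRNA bindings are importable, else maxpair).
    """
    seq = canonical_rna(sequence)
    if len(seq) < 10:
        raise ValueError("sequence shorter than 10 nt cannot form a hairpin")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    if model == "auto":
        model = "thermo" if thermo_available() else "maxpair"
    if model == "thermo":
        if _vienna is None:
            raise RuntimeError("thermodynamic model requested but ViennaRNA is not importable")
        db, energy = _thermo_fold(seq)
    elif model == "maxpair":
        db, energy = _maxpair_fold(seq)
    else:
        raise ValueError(f"unknown folding model: {model}")
    return HairpinStructure(seq, db, pair_table(db), energy, model=model)


def count_pairs(structure: HairpinStructure, region: Optional[Tuple[int, int]] = None) -> int:
    """Number of base pairs with at least one endpoint in ``region`` (half-open).

    With ``region`` omitted, the total pair count of the structure.
    """
    if region is None:
        return structure.n_pairs
    lo, hi = region
    if lo < 0 or hi > len(structure.sequence) or lo > hi:
        raise ValueError(f"region {region} out of bounds for length {len(structure.sequence)}")
    n = 0
    for i, j in structure.pairs.items():
        if i < j and (lo <= i < hi or lo <= j < hi):
            n += 1
    return n


def is_hairpin(structure: HairpinStructure) -> bool:
    """True iff the structure is a single stem-loop (one terminal loop).

    Internal loops and bulges are allowed; a second stem (any ``(``
    occurring after a ``)``) is not.  Pair-free structures are not
    hairpins.
    """
    db = structure.dotbracket
    if "(" not in db:
        return False
    return db.rindex("(") < db.index(")")


def terminal_loop(structure: HairpinStructure) -> Tuple[int, int]:
    """Half-open interval of the terminal loop of a single stem-loop."""
    if not is_hairpin(structure):
        raise ValueError("structure is not a single hairpin")
    db = structure.dotbracket
    return (db.rindex("(") + 1, db.index(")"))


@functools.lru_cache(maxsize=4096)
def _fold_cached(seq: str, model: str) -> HairpinStructure:
    return fold(seq, model)


def fold_cached(sequence: str, model: str = "auto") -> HairpinStructure:
    """Memoized :func:`fold` for pipeline-internal reuse on repeated windows."""
    return _fold_cached(canonical_rna(sequence), model)
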