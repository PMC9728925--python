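"""TCRdist: a similarity-weighted mismatch distance between TCRβ clonotypes.

The distance sums per-position residue mismatch costs over the four
pMHC-contacting loops (CDR1β, CDR2β, CDR2.5β, CDR3β), with the CDR3 loop
weighted 3× and every other loop weighted 1×.  The per-position cost is

    AAdist(a, b) = 0                       if a == b (including '-' == '-')
                 = 4                       if exactly one of a, b is '-'
                 = min(4, 4 - BLOSUM62(a, b))  otherwise

so chemically conservative substitutions cost little and any pair with a
non-positive BLOSUM62 score saturates at the cap of 4.  Germline loops are
fixed-length and compared positionwise; CDR3 loops of unequal length are
aligned by inserting a contiguous gap block in the middle of the shorter
sequence.  The cap makes this a semimetric: symmetry and identity hold,
the triangle inequality need not.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Align import substitution_matrices

from .errors import ValidationError
from .io import AA_ALPHABET, GAP, GermlineCdrTable, Repertoire, TcrBeta

#: loop weight for CDR3β; all germline loops have weight 1
CDR3_WEIGHT = 3
#: cap on the per-position mismatch cost
MISMATCH_CAP = 4

_ALPHABET = AA_ALPHABET + GAP
_GAP_IDX = len(AA_ALPHABET)
_CHAR_TO_IDX = {ch: i for i, ch in enumerate(_ALPHABET)}


def _build_mismatch_table() -> np.ndarray:
    """21×21 AAdist lookup (20 residues + gap), from the NCBI BLOSUM62."""
    blosum = substitution_matrices.load("BLOSUM62")
    n = len(_ALPHABET)
    tab = np.zeros((n, n), dtype=np.float64)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            if a == b:
                continue
            tab[i, j] = min(MISMATCH_CAP, MISMATCH_CAP - blosum[a, b])
    tab[_GAP_IDX, : _GAP_IDX] = MISMATCH_CAP
    tab[: _GAP_IDX, _GAP_IDX] = MISMATCH_CAP
    tab[_GAP_IDX, _GAP_IDX] = 0.0  # '-' == '-' counts as equality
    return tab


MISMATCH_TABLE = _build_mismatch_table()


def aa_mismatch_distance(a1: str, a2: str) -> float:
    """Per-position mismatch cost between two residues or gap characters."""
    try:
        return float(MISMATCH_TABLE[_CHAR_TO_IDX[a1], _CHAR_TO_IDX[a2]])
    except KeyError:
        bad = [c for c in (a1, a2) if c not in _CHAR_TO_IDX]
        raise ValidationError(
            f"characters outside amino-acid alphabet ∪ {{'-'}}: {bad}"
        ) from None


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_CHAR_TO_IDX[c] for c in seq), dtype=np.int8, count=len(seq))
    except KeyError:
        bad = sorted(set(seq) - set(_ALPHABET))
        raise ValidationError(f"invalid sequence characters {bad} in {seq!r}") from None


def gap_sequence(seq: str, length: int) -> str:
    """Pad ``seq`` to ``length`` with a contiguous interior gap block.

    The block is inserted at offset ``ceil(len(seq) / 2)``, i.e. just past
    the middle of the shorter sequence, keeping both termini (which are
    strongly conserved in CDR3s) intact.  Deterministic and independent of
    the partner sequence, so gapping to a common length is symmetric.
    """
    if length < len(seq):
        raise ValidationError("target length shorter than sequence")
    k = length - len(seq)
    if k == 0:
        return seq
    cut = math.ceil(len(seq) / 2)
    return seq[:cut] + GAP * k + seq[cut:]


def trim_cdr3(seq: str, n_term: int = 3, c_term: int = 2) -> str:
    """Trim conserved CDR3 termini (TCRdist-publication convention)."""
    if len(seq) <= n_term + c_term:
        raise ValidationError(f"CDR3 {seq!r} too short to trim {n_term}+{c_term}")
    return seq[n_term : len(seq) - c_term]


def align_cdr3(c1: str, c2: str) -> tuple[str, str]:
    """Gap both CDR3s to the common length max(len(c1), len(c2))."""
    if not c1 or not c2:
        raise ValidationError("CDR3 sequences must be non-empty")
    length = max(len(c1), len(c2))
    return gap_sequence(c1, length), gap_sequence(c2, length)


def _cdr3_distance(c1: str, c2: str) -> float:
    g1, g2 = align_cdr3(c1, c2)
    a, b = _encode(g1), _encode(g2)
    return CDR3_WEIGHT * float(MISMATCH_TABLE[a, b].sum())


def _germline_distance(
    loops1: tuple[str, str, str], loops2: tuple[str, str, str]
) -> float:
    total = 0.0
    for s1, s2 in zip(loops1, loops2):
        total += float(MISMATCH_TABLE[_encode(s1), _encode(s2)].sum())
    return total


def tcrdist_pair(
    t1: TcrBeta,
    t2: TcrBeta,
    table: GermlineCdrTable | None = None,
    trim: bool = False,
) -> float:
    """TCRdist between two clonotypes (symmetric, ≥ 0, 0 on identity).

    With ``trim=True`` the CDR3s lose 3 N-terminal and 2 C-terminal
    residues before alignment, the original TCRdist-publication
    convention; the default compares full CDR3s.
    """
    table = table or GermlineCdrTable.default()
    l1 = table.loops(t1.v_allele)
    l2 = table.loops(t2.v_allele)
    c1, c2 = t1.cdr3, t2.cdr3
    if trim:
        c1, c2 = trim_cdr3(c1), trim_cdr3(c2)
    return _germline_distance(l1, l2) + _cdr3_distance(c1, c2)


def _cdr3_distance_block(seqs1: list[str], seqs2: list[str]) -> np.ndarray:
    """Weighted CDR3 distances for all pairs, vectorized by length group."""
    by_len1: dict[int, list[int]] = {}
    for i, s in enumerate(seqs1):
        by_len1.setdefault(len(s), []).append(i)
    by_len2: dict[int, list[int]] = {}
    for j, s in enumerate(seqs2):
        by_len2.setdefault(len(s), []).append(j)

    out = np.empty((len(seqs1), len(seqs2)), dtype=np.float64)
    for la, idx1 in by_len1.items():
        for lb, idx2 in by_len2.items():
            L = max(la, lb)
            a = np.stack([_encode(gap_sequence(seqs1[i], L)) for i in idx1])
            b = np.stack([_encode(gap_sequence(seqs2[j], L)) for j in idx2])
            block = MISMATCH_TABLE[a[:, None, :], b[None, :, :]].sum(axis=2)
            out[np.ix_(idx1, idx2)] = CDR3_WEIGHT * block
    return out


def distance_matrix(
    r1: Repertoire,
    r2: Repertoire,
    table: GermlineCdrTable | None = None,
    trim: bool = False,
) -> np.ndarray:
    """n×m matrix of TCRdist values between two repertoires.

    Duplicate clonotypes are collapsed internally so each distinct pair is
    evaluated once; germline loop distances are computed once per allele
    pair.
    """
    if len(r1) == 0 or len(r2) == 0:
        raise ValidationError("repertoires must be non-empty")
    table = table or GermlineCdrTable.default()

    def dedupe(rep: Repertoire) -> tuple[list[TcrBeta], np.ndarray]:
        uniq: dict[tuple[str, str], int] = {}
        inverse = np.empty(len(rep), dtype=np.int64)
        reps: list[TcrBeta] = []
        for i, t in enumerate(rep.tcrs):
            k = t.key()
            if k not in uniq:
                uniq[k] = len(reps)
                reps.append(t)
            inverse[i] = uniq[k]
        return reps, inverse

    u1, inv1 = dedupe(r1)
    u2, inv2 = dedupe(r2)

    # germline component via per-allele-pair lookup
    a1 = [table.resolve_allele(t.v_allele) for t in u1]
    a2 = [table.resolve_allele(t.v_allele) for t in u2]
    alleles = sorted(set(a1) | set(a2))
    aidx = {a: i for i, a in enumerate(alleles)}
    G = np.zeros((len(alleles), len(alleles)))
    for i, ai in enumerate(alleles):
        for j, aj in enumerate(alleles):
            if j < i:
                G[i, j] = G[j, i]
            elif j > i:
                G[i, j] = _germline_distance(table.loops(ai), table.loops(aj))
    germ = G[np.ix_([aidx[a] for a in a1], [aidx[a] for a in a2])]

    seqs1 = [t.cdr3 for t in u1]
    seqs2 = [t.cdr3 for t in u2]
    if trim:
        seqs1 = [trim_cdr3(s) for s in seqs1]
        seqs2 = [trim_cdr3(s) for s in seqs2]
    cdr3 = _cdr3_distance_block(seqs1, seqs2)

    D = germ + cdr3
    return D[np.ix_(inv1, inv2)]


def self_distance_matrix(
    rep: Repertoire, table: GermlineCdrTable | None = None, trim: bool = False
) -> np.ndarray:
    """Within-repertoire TCRdist matrix (used for δ-balls and annuli)."""
    return distance_matrix(rep, rep, table, trim=trim)


def write_distance_matrix(D: np.ndarray, r1: Repertoire, r2: Repertoire, path) -> None:
    """Export a labelled distance matrix as TSV."""
    import pandas as pd

    labels1 = [f"{t.v_allele}|{t.cdr3}" for t in r1.tcrs]
    labels2 = [f"{t.v_allele}|{t.cdr3}" for t in r2.tcrs]
    pd.DataFrame(D, index=labels1, columns=labels2).to_csv(path, sep="\t")
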