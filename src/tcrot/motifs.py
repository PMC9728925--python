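"""Cluster motif summaries: alignment, profile statistics, query scoring.

A cluster of CDR3 sequences is summarized by a gapped multiple alignment
built with a deterministic center-star strategy (all sequences aligned
pairwise to the medoid under BLOSUM62, gaps merged), from which a profile
is derived: per match-column amino-acid frequencies, occupancy (the
probability of a non-gap residue), the probability of an insertion after
the column and its expected length, plus the V-gene usage of the cluster.
Match columns are those with occupancy ≥ 0.5, the standard profile-HMM
construction heuristic.

Queries are scored against the profile by a best-path log2-odds ("bit
score") through match/insert/delete states versus an i.i.d. background
model, and "hard" membership is decided by an empirical E-value: the
expected number of background-sampled sequences scoring at least as high.
External aligner/HMM tools are not required; aligned FASTA and Stockholm
exports are provided for interoperability with them.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .errors import ValidationError
from .io import AA_ALPHABET, GAP

PSEUDOCOUNT = 1.0 / 20
DEFAULT_E_CRIT = 0.01
DEFAULT_NULL_SAMPLES = 10_000
GAP_PENALTY = -4.0

_BLOSUM = substitution_matrices.load("BLOSUM62")
_AA_IDX = {a: i for i, a in enumerate(AA_ALPHABET)}


def _nw_align(a: str, b: str) -> tuple[str, str, float]:
    """Global Needleman–Wunsch alignment under BLOSUM62, linear gaps.

    Deterministic tie-break: diagonal, then up (gap in b), then left.
    """
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = np.arange(n + 1) * GAP_PENALTY
    score[0, :] = np.arange(m + 1) * GAP_PENALTY
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1, j - 1] + _BLOSUM[a[i - 1], b[j - 1]]
            up = score[i - 1, j] + GAP_PENALTY
            left = score[i, j - 1] + GAP_PENALTY
            score[i, j] = max(diag, up, left)
    # traceback
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + _BLOSUM[
            a[i - 1], b[j - 1]
        ]:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and score[i, j] == score[i - 1, j] + GAP_PENALTY:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_b.append(b[j - 1])
            out_a.append(GAP)
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score[n, m])


def build_alignment(sequences: list[str]) -> list[str]:
    """Center-star multiple alignment of CDR3 sequences.

    The center is the medoid (maximal summed pairwise alignment score,
    ties to the first); every other sequence is aligned to it and gaps
    are merged into a master column pattern.  Deterministic.
    """
    seqs = list(sequences)
    if len(seqs) < 2:
        raise ValidationError("need at least 2 sequences to align")
    for s in seqs:
        bad = set(s) - set(AA_ALPHABET)
        if not s or bad:
            raise ValidationError(f"invalid CDR3 sequence {s!r}")

    n = len(seqs)
    totals = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            sc = _nw_align(seqs[i], seqs[j])[2]
            totals[i] += sc
            totals[j] += sc
    center = int(np.argmax(totals))

    pairs = []
    for j in range(n):
        if j == center:
            continue
        ca, cb, _ = _nw_align(seqs[center], seqs[j])
        pairs.append((j, ca, cb))

    # merge: master = center with the union of gap insertions
    master = seqs[center]
    aligned = {center: master}
    for j, ca, cb in pairs:
        # reconcile ca with current master (both are gapped center copies)
        merged_master, remap_old, remap_new = _merge_gap_patterns(master, ca)
        if merged_master != master:
            aligned = {
                k: _apply_remap(v, remap_old, len(merged_master))
                for k, v in aligned.items()
            }
            master = merged_master
        aligned[j] = _apply_remap(cb, remap_new, len(master))
    return [aligned[i] for i in range(n)]


def _merge_gap_patterns(m1: str, m2: str) -> tuple[str, list[int], list[int]]:
    """Merge two gapped copies of the same sequence into a common pattern.

    Returns the merged pattern plus, for each input, the mapping from its
    columns to merged columns (as a list of merged positions).
    """
    i = j = 0
    merged = []
    map1, map2 = [], []
    while i < len(m1) or j < len(m2):
        c1 = m1[i] if i < len(m1) else None
        c2 = m2[j] if j < len(m2) else None
        if c1 is not None and c2 is not None and c1 == c2:
            map1.append(len(merged))
            map2.append(len(merged))
            merged.append(c1)
            i += 1
            j += 1
        elif c1 == GAP:
            map1.append(len(merged))
            merged.append(GAP)
            i += 1
        elif c2 == GAP:
            map2.append(len(merged))
            merged.append(GAP)
            j += 1
        else:  # pragma: no cover - both non-gap, must match (same sequence)
            raise AssertionError("inconsistent gapped copies of the center")
    return "".join(merged), map1, map2


def _apply_remap(row: str, colmap: list[int], width: int) -> str:
    out = [GAP] * width
    for pos, col in zip(row, colmap):
        out[col] = pos
    return "".join(out)


@dataclass
class MotifProfile:
    """Alignment-derived motif summary for a cluster of CDR3s."""

    match_columns: list[int]
    frequencies: np.ndarray  # (n_match, 20), rows sum to 1
    occupancy: np.ndarray  # (n_match,)
    insertion_prob: np.ndarray  # (n_match,) prob of insertion after column
    expected_insert_len: np.ndarray  # (n_match,)
    v_usage: dict[str, float] = field(default_factory=dict)
    n_sequences: int = 0

    @property
    def consensus(self) -> str:
        return "".join(
            AA_ALPHABET[int(i)] for i in np.argmax(self.frequencies, axis=1)
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "match_columns": self.match_columns,
            "alphabet": AA_ALPHABET,
            "frequencies": self.frequencies.tolist(),
            "occupancy": self.occupancy.tolist(),
            "insertion_prob": self.insertion_prob.tolist(),
            "expected_insert_len": self.expected_insert_len.tolist(),
            "v_usage": self.v_usage,
            "n_sequences": self.n_sequences,
            "consensus": self.consensus,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def profile_stats(
    alignment: list[str], v_alleles: list[str] | None = None
) -> MotifProfile:
    """Column statistics of a gapped alignment.

    Match columns have occupancy ≥ 0.5; runs of non-match columns between
    (or after) match columns are treated as insert regions attributed to
    the preceding match column (index −1 region, before the first match
    column, is attributed to match column 0's predecessor and ignored in
    the per-column table only if there is no preceding match column).
    """
    rows = [r.upper() for r in alignment]
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValidationError("alignment rows must have equal length")
    n = len(rows)

    occ_all = np.array(
        [sum(1 for r in rows if r[c] != GAP) / n for c in range(width)]
    )
    match_cols = [c for c in range(width) if occ_all[c] >= 0.5]
    if not match_cols:
        raise ValidationError("alignment has no match columns")

    freqs = np.zeros((len(match_cols), 20))
    for k, c in enumerate(match_cols):
        counts = Counter(r[c] for r in rows if r[c] != GAP)
        total = sum(counts.values())
        for aa, cnt in counts.items():
            freqs[k, _AA_IDX[aa]] = cnt / total

    ins_prob = np.zeros(len(match_cols))
    exp_len = np.zeros(len(match_cols))
    for k, c in enumerate(match_cols):
        nxt = match_cols[k + 1] if k + 1 < len(match_cols) else width
        region = range(c + 1, nxt)
        if not len(region):
            continue
        lengths = [
            sum(1 for cc in region if r[cc] != GAP) for r in rows
        ]
        inserting = [L for L in lengths if L > 0]
        if inserting:
            ins_prob[k] = len(inserting) / n
            exp_len[k] = float(np.mean(inserting))

    v_usage: dict[str, float] = {}
    if v_alleles:
        counts = Counter(v_alleles)
        v_usage = {v: c / len(v_alleles) for v, c in sorted(counts.items())}

    return MotifProfile(
        match_columns=match_cols,
        frequencies=freqs,
        occupancy=occ_all[match_cols],
        insertion_prob=ins_prob,
        expected_insert_len=exp_len,
        v_usage=v_usage,
        n_sequences=n,
    )


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20)


def score_sequence(
    profile: MotifProfile,
    query: str,
    background: np.ndarray | None = None,
) -> float:
    """Best-path log2-odds bit score of a query against the profile.

    Dynamic program over match/insert/delete states: match emissions are
    the pseudocounted column frequencies, insert emissions equal the
    background (zero odds), and state transitions use the profile's
    occupancy (deletion probability 1 − occupancy) and insertion
    statistics, pseudocounted away from hard 0/1.  The score is the
    maximal log2 P(path, query | profile) − log2 P(query | background).
    """
    if background is None:
        background = uniform_background()
    background = np.asarray(background, dtype=float)
    if abs(background.sum() - 1.0) > 1e-6:
        raise ValidationError("background frequencies must sum to 1")
    bad = set(query) - set(AA_ALPHABET)
    if not query or bad:
        raise ValidationError(f"invalid query sequence {query!r}")

    K = len(profile.match_columns)
    L = len(query)
    # pseudocounted emission odds per match column
    counts = profile.frequencies * profile.n_sequences
    em = (counts + PSEUDOCOUNT) / (counts.sum(axis=1, keepdims=True) + 20 * PSEUDOCOUNT)
    log_odds = np.log2(em) - np.log2(background[None, :])

    eps = 1e-3  # keeps transitions away from hard 0/1
    p_del = np.clip(1.0 - profile.occupancy, eps, 1 - eps)
    p_ins = np.clip(profile.insertion_prob, eps, 1 - eps)
    # expected insert length E -> geometric continuation prob 1 - 1/E
    with np.errstate(divide="ignore", invalid="ignore"):
        p_ext = np.where(
            profile.expected_insert_len > 1.0,
            1.0 - 1.0 / np.maximum(profile.expected_insert_len, 1.0),
            eps,
        )
    p_ext = np.clip(p_ext, eps, 1 - eps)

    lg = np.log2
    NEG = -np.inf
    # V[k][i]: best score consuming first i query residues, at match state k
    # (k from 1..K), D[k][i] deletion of column k, I[k][i] insert after k.
    M = np.full((K + 1, L + 1), NEG)
    I = np.full((K + 1, L + 1), NEG)
    D = np.full((K + 1, L + 1), NEG)
    M[0, 0] = 0.0  # begin state
    for k in range(0, K + 1):
        for i in range(0, L + 1):
            if k > 0:
                best_prev = max(
                    M[k - 1, i - 1] if i > 0 else NEG,
                    I[k - 1, i - 1] if i > 0 else NEG,
                    D[k - 1, i - 1] if i > 0 else NEG,
                )
                if i > 0 and best_prev > NEG:
                    M[k, i] = (
                        best_prev
                        + lg(1 - p_del[k - 1])
                        + log_odds[k - 1, _AA_IDX[query[i - 1]]]
                    )
                best_del = max(M[k - 1, i], I[k - 1, i], D[k - 1, i])
                if best_del > NEG:
                    D[k, i] = best_del + lg(p_del[k - 1])
            if i > 0:
                open_p = p_ins[k - 1] if k > 0 else eps
                cand_open = max(M[k, i - 1], D[k, i - 1]) + lg(open_p)
                ext_p = p_ext[k - 1] if k > 0 else eps
                cand_ext = I[k, i - 1] + lg(ext_p)
                I[k, i] = max(cand_open, cand_ext)  # insert emits at bg odds 0
    return float(max(M[K, L], I[K, L], D[K, L]))


def sample_background_sequence(
    rng: np.random.Generator, length: int, background: np.ndarray
) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length, p=background))


def empirical_null_scores(
    profile: MotifProfile,
    lengths: list[int],
    background: np.ndarray | None = None,
    n_samples: int = DEFAULT_NULL_SAMPLES,
    seed: int = 0,
) -> np.ndarray:
    """Scores of background-sampled sequences against the profile.

    Lengths are drawn from the supplied length pool (typically the
    cluster's ungapped CDR3 lengths).
    """
    if background is None:
        background = uniform_background()
    rng = np.random.default_rng(seed)
    ls = rng.choice(np.asarray(lengths), size=n_samples, replace=True)
    return np.array(
        [
            score_sequence(
                profile, sample_background_sequence(rng, int(L), background), background
            )
            for L in ls
        ]
    )


def hard_membership(
    profile: MotifProfile,
    query: str,
    e_crit: float = DEFAULT_E_CRIT,
    null_scores: np.ndarray | None = None,
    lengths: list[int] | None = None,
    background: np.ndarray | None = None,
    n_samples: int = DEFAULT_NULL_SAMPLES,
    seed: int = 0,
) -> tuple[bool, float]:
    """E-value-thresholded motif membership.

    E = N × (fraction of N background samples scoring ≥ the query); the
    query is a member when E < e_crit.  Pass precomputed ``null_scores``
    when testing many queries against one profile.
    """
    if e_crit <= 0:
        raise ValidationError("e_crit must be positive")
    if null_scores is None:
        if lengths is None:
            lengths = [len(query)]
        null_scores = empirical_null_scores(
            profile, lengths, background, n_samples=n_samples, seed=seed
        )
    s = score_sequence(profile, query, background)
    e_value = float(np.count_nonzero(null_scores >= s))
    return e_value < e_crit, e_value


def write_aligned_fasta(alignment: list[str], names: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(names, alignment):
            fh.write(f">{name}\n{row}\n")


def write_stockholm(alignment: list[str], names: list[str], path: str | Path) -> None:
    width = max(len(n) for n in names) + 2
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        for name, row in zip(names, alignment):
            fh.write(f"{name.ljust(width)}{row.replace(GAP, '.')}\n")
        fh.write("//\n")
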