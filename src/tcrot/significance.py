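"""Significance machinery: randomization test, replicate z-scores,
cluster prevalence, and hit-rate utilities.

The randomization (relabeling) test builds a per-TCR null: in each trial
all TCR occurrences of both repertoires are pooled and reassigned at
random, preserving the two sample sizes; neighborhood loneliness is then
recomputed for the trial target against the trial source.  Null score
distributions are maintained only for the occurrences originally in the
target repertoire (an occurrence contributes a trial score only when the
shuffle places it in the trial target), then downsampled to a common size.
Empirical p-values use the add-one estimator, p = (1 + #{null ≥ obs}) /
(1 + |null|), so they are never exactly zero.

Replicate z-scores compare the observed loneliness against a background
of biological-replicate repertoires: S(t) collects the TCR's loneliness
versus every other same-type repertoire, and z = (s_obs − mean S) / sd S.
Randomization z-scores are the analogue with the permutation null.  Note
the two nulls answer different questions: the randomization null models
resampling within one pair of samples, not variation between organisms,
so a fixed linear map between the two z-scales (if available from
replicate data) is exposed as an explicit utility rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import GermlineCdrTable, Repertoire, TcrBeta
from .loneliness import DEFAULT_DELTA, score_repertoire_pair
from .metric import distance_matrix, tcrdist_pair
from .transport import DEFAULT_EPSILON, sinkhorn_plan

DEFAULT_TRIALS = 100


@dataclass
class RandomizationResult:
    """Observed scores, per-TCR permutation nulls, z-scores and p-values."""

    repertoire: Repertoire
    observed: np.ndarray
    null_samples: list[np.ndarray]
    z_star: np.ndarray
    p_value: np.ndarray
    trials: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "v_allele": [t.v_allele for t in self.repertoire.tcrs],
                "cdr3": [t.cdr3 for t in self.repertoire.tcrs],
                "s_obs": self.observed,
                "z_star": self.z_star,
                "p_value": self.p_value,
                "n_null": [len(s) for s in self.null_samples],
            }
        )


@dataclass
class ReplicateScores:
    """Background/foreground replicate means and replicate z-scores."""

    repertoire: Repertoire
    bg_score: np.ndarray
    fg_score: np.ndarray
    s_obs: np.ndarray
    z: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "v_allele": [t.v_allele for t in self.repertoire.tcrs],
                "cdr3": [t.cdr3 for t in self.repertoire.tcrs],
                "bg_score": self.bg_score,
                "fg_score": self.fg_score,
                "s_obs": self.s_obs,
                "z": self.z,
            }
        )


def _neighborhood_scores_for_slice(
    D_pool: np.ndarray,
    src_idx: np.ndarray,
    tgt_idx: np.ndarray,
    delta: float,
    epsilon: float,
) -> np.ndarray:
    """Neighborhood loneliness of pool[tgt] vs pool[src] from a pooled
    distance matrix (marginals uniform per occurrence)."""
    D = D_pool[np.ix_(src_idx, tgt_idx)]
    d_max = float(D.max())
    D_norm = D / d_max if d_max > 0 else D
    r = np.full(len(src_idx), 1.0 / len(src_idx))
    c = np.full(len(tgt_idx), 1.0 / len(tgt_idx))
    plan = sinkhorn_plan(r, c, D_norm, epsilon)
    indiv = (plan.P * D).sum(axis=0)
    ball = D_pool[np.ix_(tgt_idx, tgt_idx)] < delta
    return ball @ indiv


def randomization_test(
    r1: Repertoire,
    r2: Repertoire,
    trials: int = DEFAULT_TRIALS,
    seed: int = 0,
    delta: float = DEFAULT_DELTA,
    epsilon: float = DEFAULT_EPSILON,
    table: GermlineCdrTable | None = None,
    min_null_size: int | None = None,
    max_extra_trials: int = 1000,
) -> RandomizationResult:
    """Relabeling test of the neighborhood-loneliness scores of ``r2``.

    Each occurrence is reassigned independently, even duplicates.  With
    ``min_null_size`` set, extra trials run (up to ``max_extra_trials``)
    until every per-TCR null reaches that size before downsampling.
    """
    if trials < 1:
        raise ValidationError("trials must be >= 1")
    table = table or GermlineCdrTable.default()
    rng = np.random.default_rng(seed)

    n1, n2 = len(r1), len(r2)
    pooled = r1.tcrs + r2.tcrs
    pool_rep = Repertoire.from_tcrs(pooled)
    D_pool = distance_matrix(pool_rep, pool_rep, table)

    obs = _neighborhood_scores_for_slice(
        D_pool, np.arange(n1), np.arange(n1, n1 + n2), delta, epsilon
    )

    nulls: list[list[float]] = [[] for _ in range(n2)]
    done = 0
    while True:
        perm = rng.permutation(n1 + n2)
        tgt = perm[n1:]
        scores = _neighborhood_scores_for_slice(D_pool, perm[:n1], tgt, delta, epsilon)
        for pos, pool_i in enumerate(tgt):
            if pool_i >= n1:  # occurrence originally in R2
                nulls[pool_i - n1].append(float(scores[pos]))
        done += 1
        if done >= trials:
            if min_null_size is None:
                break
            if min(len(s) for s in nulls) >= min_null_size:
                break
            if done >= trials + max_extra_trials:
                break

    sizes = [len(s) for s in nulls]
    m = min(sizes)
    samples: list[np.ndarray] = []
    for s in nulls:
        arr = np.asarray(s, dtype=float)
        if len(arr) > m:
            arr = rng.choice(arr, size=m, replace=False)
        samples.append(arr)

    z = np.full(n2, np.nan)
    p = np.full(n2, np.nan)
    for j, arr in enumerate(samples):
        if len(arr) == 0:
            continue
        p[j] = (1.0 + np.count_nonzero(arr >= obs[j])) / (1.0 + len(arr))
        sd = arr.std(ddof=0)
        if sd > 0:
            z[j] = (obs[j] - arr.mean()) / sd

    return RandomizationResult(
        repertoire=r2,
        observed=obs,
        null_samples=samples,
        z_star=z,
        p_value=p,
        trials=done,
        seed=seed,
    )


def replicate_zscores(
    target: Repertoire,
    background_set: Sequence[Repertoire],
    foreground: Repertoire | Sequence[Repertoire],
    delta: float = DEFAULT_DELTA,
    epsilon: float = DEFAULT_EPSILON,
    table: GermlineCdrTable | None = None,
) -> ReplicateScores:
    """Replicate-based background/foreground scores for ``target`` TCRs.

    The background score averages each TCR's neighborhood loneliness
    versus every background repertoire other than the target itself
    (denominator |set| − 1 when the target belongs to the set); the
    foreground score averages over the foreground repertoires.  The
    observed score is taken against the first foreground repertoire and
    the replicate z uses the background sample as null; z is NaN when the
    null is degenerate (zero spread).
    """
    table = table or GermlineCdrTable.default()
    bg = [r for r in background_set if r is not target]
    if len(bg) < 2:
        raise ValidationError("background_set must contain >= 2 other repertoires")
    fg = [foreground] if isinstance(foreground, Repertoire) else list(foreground)
    if not fg:
        raise ValidationError("foreground must contain >= 1 repertoire")

    from .metric import self_distance_matrix

    D22 = self_distance_matrix(target, table)

    def scores_vs(source: Repertoire) -> np.ndarray:
        return score_repertoire_pair(
            source, target, table, epsilon=epsilon, delta=delta, D22=D22
        ).neighborhood

    bg_matrix = np.stack([scores_vs(r) for r in bg])  # (n_bg, n_target)
    fg_matrix = np.stack([scores_vs(r) for r in fg])

    s_obs = fg_matrix[0]
    bg_mean = bg_matrix.mean(axis=0)
    sd = bg_matrix.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (s_obs - bg_mean) / sd, np.nan)

    return ReplicateScores(
        repertoire=target,
        bg_score=bg_mean,
        fg_score=fg_matrix.mean(axis=0),
        s_obs=s_obs,
        z=z,
    )


def ball_membership(
    centroid: TcrBeta, radius: float, table: GermlineCdrTable
) -> Callable[[TcrBeta], bool]:
    """Membership rule: within ``radius`` TCRdist of ``centroid``."""

    def rule(t: TcrBeta) -> bool:
        return tcrdist_pair(centroid, t, table) <= radius

    return rule


def cluster_prevalence(
    repertoire: Repertoire, membership: Callable[[TcrBeta], bool]
) -> float:
    """Fraction of repertoire members satisfying the membership rule."""
    if len(repertoire) == 0:
        return 0.0
    return sum(1 for t in repertoire.tcrs if membership(t)) / len(repertoire)


def hit_rate(
    candidates: Iterable[TcrBeta],
    reference: Iterable[TcrBeta],
    mode: str = "exact",
    clusters: Sequence[Callable[[TcrBeta], bool]] | None = None,
) -> float | None:
    """Fraction of candidate TCRs confirmed by a reference set.

    ``exact`` matches (V allele, CDR3) identity; ``member-of-cluster``
    counts a candidate as a hit when it shares one of the given cluster
    membership rules with some reference TCR.  Returns None (missing) for
    an empty candidate set.
    """
    cand = list(candidates)
    if not cand:
        return None
    ref = list(reference)
    if mode == "exact":
        ref_keys = {t.key() for t in ref}
        hits = sum(1 for t in cand if t.key() in ref_keys)
    elif mode == "member-of-cluster":
        if clusters is None:
            raise ValidationError("member-of-cluster mode requires cluster rules")
        ref_in = [{i for i, rule in enumerate(clusters) if rule(t)} for t in ref]
        occupied = set().union(*ref_in) if ref_in else set()
        hits = sum(
            1
            for t in cand
            if any(rule(t) and i in occupied for i, rule in enumerate(clusters))
        )
    else:
        raise ValidationError(f"unknown hit-rate mode {mode!r}")
    return hits / len(cand)


def map_z_scores(
    z_star: np.ndarray, slope: float, intercept: float = 0.0
) -> np.ndarray:
    """Linear map from randomization z-scores to a replicate z-scale.

    The coefficients must come from the user's own replicate calibration;
    the permutation null is a within-sample null and its z-scale need not
    match between-organism variation.
    """
    return intercept + slope * np.asarray(z_star, dtype=float)
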