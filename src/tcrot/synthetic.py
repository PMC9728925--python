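"""Synthetic repertoires: background diversity plus planted spike-in clusters.

The generator emulates the structure of a spike-in benchmark: a diverse
"naive-like" background of (TRBV, CDR3) clonotypes, and a tight planted
cluster of near-identical variants of an epitope-specific seed clonotype
(the default seed mimics an influenza-M1-specific public β chain).
Background CDR3s start with C and end with F, with interior residues
drawn i.i.d. from a fixed naive-like frequency vector and lengths from a
unimodal distribution over 10–18 residues.  Only the *contrast* between
cluster and background matters for benchmarking; no V(D)J generation
model is implied.

The benchmark plants k spike-ins into a foreground of total size n (the
spike-ins displace background), compares it against a background-only
source repertoire of size n, and measures how well neighborhood
loneliness ranks the spike-ins (AUROC via the rank statistic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .errors import ValidationError
from .io import AA_ALPHABET, GermlineCdrTable, Repertoire, TcrBeta
from .loneliness import DEFAULT_DELTA, score_repertoire_pair
from .transport import DEFAULT_EPSILON

#: naive-like interior residue frequencies (glycine/serine-rich junctions);
#: a fixed modeling choice, not an empirical estimate.
NAIVE_RESIDUE_FREQS = {
    "A": 0.050, "C": 0.005, "D": 0.040, "E": 0.050, "F": 0.040,
    "G": 0.110, "H": 0.020, "I": 0.030, "K": 0.030, "L": 0.070,
    "M": 0.015, "N": 0.040, "P": 0.045, "Q": 0.055, "R": 0.060,
    "S": 0.110, "T": 0.065, "V": 0.050, "W": 0.015, "Y": 0.100,
}

#: default CDR3 length distribution (total length including C...F), 10-18
CDR3_LENGTH_WEIGHTS = {
    10: 0.04, 11: 0.08, 12: 0.14, 13: 0.18, 14: 0.20,
    15: 0.16, 16: 0.10, 17: 0.06, 18: 0.04,
}

DEFAULT_SPIKE_SEED = TcrBeta("TRBV19*01", "CASSIRSSYEQYF")


@dataclass
class SimConfig:
    """Parameters of the synthetic repertoire generator."""

    seed: int = 0
    n_background: int = 500
    n_spikein: int = 0
    spike_seed: TcrBeta = DEFAULT_SPIKE_SEED
    max_substitutions: int = 2
    v_weights: dict[str, float] | None = None  # None -> uniform over table
    length_weights: dict[int, float] = field(
        default_factory=lambda: dict(CDR3_LENGTH_WEIGHTS)
    )
    residue_freqs: dict[str, float] = field(
        default_factory=lambda: dict(NAIVE_RESIDUE_FREQS)
    )

    def __post_init__(self) -> None:
        if self.n_background < 0 or self.n_spikein < 0:
            raise ValidationError("sizes must be non-negative")
        if self.n_background + self.n_spikein == 0:
            raise ValidationError("at least one clonotype must be generated")
        if self.max_substitutions > len(self.spike_seed.cdr3):
            raise ValidationError("substitution cap exceeds seed CDR3 length")


def _residue_sampler(cfg: SimConfig) -> tuple[list[str], np.ndarray]:
    aas = sorted(cfg.residue_freqs)
    p = np.array([cfg.residue_freqs[a] for a in aas], dtype=float)
    return aas, p / p.sum()


def generate_background(
    cfg: SimConfig, table: GermlineCdrTable | None = None
) -> Repertoire:
    """n_background clonotypes of naive-like diversity; pure in (cfg, seed)."""
    table = table or GermlineCdrTable.default()
    rng = np.random.default_rng(cfg.seed)
    alleles = table.alleles
    if cfg.v_weights is not None:
        weights = np.array([cfg.v_weights.get(a, 0.0) for a in alleles], dtype=float)
        if weights.sum() <= 0:
            raise ValidationError("v_weights assign no mass to known alleles")
        weights /= weights.sum()
    else:
        weights = np.full(len(alleles), 1.0 / len(alleles))
    lengths = sorted(cfg.length_weights)
    lw = np.array([cfg.length_weights[l] for l in lengths], dtype=float)
    lw /= lw.sum()
    aas, p = _residue_sampler(cfg)

    tcrs = []
    for _ in range(cfg.n_background):
        v = alleles[int(rng.choice(len(alleles), p=weights))]
        L = int(lengths[int(rng.choice(len(lengths), p=lw))])
        interior = "".join(rng.choice(aas, size=L - 2, p=p))
        tcrs.append(TcrBeta(v, "C" + interior + "F"))
    return Repertoire.from_tcrs(tcrs, label=f"background-seed{cfg.seed}")


def generate_spikein_cluster(
    cfg: SimConfig, table: GermlineCdrTable | None = None
) -> Repertoire:
    """k near-identical variants of the seed clonotype.

    Each variant carries 0…max_substitutions point substitutions at
    uniformly chosen CDR3 positions and shares the seed's V allele, so
    pairwise within-cluster TCRdist is at most 24 × max_substitutions
    (two sequences, ≤ max_substitutions differing positions each, CDR3
    weight 3 × cap 4).
    """
    if cfg.n_spikein < 1:
        raise ValidationError("n_spikein must be >= 1")
    rng = np.random.default_rng(cfg.seed + 1)
    seed_cdr3 = cfg.spike_seed.cdr3
    aas = list(AA_ALPHABET)
    tcrs = []
    for _ in range(cfg.n_spikein):
        n_sub = int(rng.integers(0, cfg.max_substitutions + 1))
        cdr3 = list(seed_cdr3)
        positions = rng.choice(len(cdr3), size=n_sub, replace=False)
        for pos in positions:
            cdr3[pos] = aas[int(rng.integers(len(aas)))]
        tcrs.append(TcrBeta(cfg.spike_seed.v_allele, "".join(cdr3)))
    return Repertoire.from_tcrs(tcrs, label=f"spikein-seed{cfg.seed}")


def make_spikein_pair(
    n: int,
    k: int,
    seed: int,
    table: GermlineCdrTable | None = None,
    cfg: SimConfig | None = None,
) -> tuple[Repertoire, Repertoire, np.ndarray]:
    """Source (background only, size n), target (n − k background + k
    spike-ins), and the boolean spike-in labels of the target."""
    if k >= n:
        raise ValidationError("k must be smaller than n")
    table = table or GermlineCdrTable.default()
    base = cfg or SimConfig()
    src_cfg = SimConfig(
        seed=seed,
        n_background=n,
        spike_seed=base.spike_seed,
        max_substitutions=base.max_substitutions,
        v_weights=base.v_weights,
        length_weights=base.length_weights,
        residue_freqs=base.residue_freqs,
    )
    tgt_cfg = SimConfig(
        seed=seed + 10_007,
        n_background=n - k,
        n_spikein=k,
        spike_seed=base.spike_seed,
        max_substitutions=base.max_substitutions,
        v_weights=base.v_weights,
        length_weights=base.length_weights,
        residue_freqs=base.residue_freqs,
    )
    source = generate_background(src_cfg, table)
    bg = generate_background(tgt_cfg, table)
    spikes = generate_spikein_cluster(tgt_cfg, table) if k else None
    tcrs = bg.tcrs + (spikes.tcrs if spikes else [])
    labels = np.zeros(len(tcrs), dtype=bool)
    labels[len(bg.tcrs):] = True
    target = Repertoire.from_tcrs(tcrs, label=f"mixed-n{n}-k{k}-seed{seed}")
    return source, target, labels


def auroc(labels: np.ndarray, scores: np.ndarray) -> float | None:
    """Mann–Whitney rank AUROC with midrank ties; None if one class."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        return None
    return float(roc_auc_score(labels, scores))


def spikein_benchmark(
    n: int = 500,
    k_grid: tuple[int, ...] = (5, 20, 50),
    replicates: int = 10,
    seed: int = 0,
    delta: float = DEFAULT_DELTA,
    epsilon: float = DEFAULT_EPSILON,
    table: GermlineCdrTable | None = None,
    cfg: SimConfig | None = None,
) -> pd.DataFrame:
    """AUROC of loneliness scores for spike-in recovery.

    For each k and replicate, generates a fresh source/target pair, scores
    the target, and records the AUROC of both neighborhood and individual
    loneliness for spike-in membership.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    table = table or GermlineCdrTable.default()
    rows = []
    for k in k_grid:
        for rep in range(replicates):
            pair_seed = seed + 1009 * rep + 104_729 * k
            source, target, labels = make_spikein_pair(n, k, pair_seed, table, cfg)
            scores = score_repertoire_pair(
                source, target, table, epsilon=epsilon, delta=delta
            )
            rows.append(
                {
                    "k": k,
                    "replicate": rep,
                    "seed": pair_seed,
                    "auroc_neighborhood": auroc(labels, scores.neighborhood),
                    "auroc_individual": auroc(labels, scores.individual),
                }
            )
    return pd.DataFrame(rows)
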