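"""Multi-repertoire analyses and the end-to-end comparison pipeline.

The total Sinkhorn transport cost between two repertoires is a global
dissimilarity usable for repertoire-level clustering: we assemble the
symmetric matrix of pairwise total costs and build an agglomerative
dendrogram (Ward by default).  Ward linkage formally presumes Euclidean
distances; applying it to a transport cost matrix is the usual pragmatic
approximation and is documented as such.

:func:`run_full_comparison` chains metric → transport → loneliness →
clustering → optional significance → motif summaries and writes a report
bundle (scores TSV, clusters JSON, motif profiles JSON, run log).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import __version__
from .errors import ValidationError
from .io import (
    GermlineCdrTable,
    Repertoire,
    load_repertoire,
    write_scores_table,
)
from .loneliness import DEFAULT_DELTA, score_repertoire_pair
from .metric import self_distance_matrix
from .clustering import DEFAULT_R_MAX, DEFAULT_STEP, extract_clusters
from .motifs import build_alignment, profile_stats
from .significance import randomization_test
from .transport import DEFAULT_EPSILON, repertoire_transport


@dataclass
class RepertoireDistanceMatrix:
    """Symmetric matrix of total transport costs with repertoire labels."""

    matrix: np.ndarray
    labels: list[str]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def pairwise_repertoire_distances(
    repertoires: list[Repertoire],
    table: GermlineCdrTable | None = None,
    epsilon: float = DEFAULT_EPSILON,
    zero_diagonal: bool = False,
) -> RepertoireDistanceMatrix:
    """Total Sinkhorn cost between every pair of repertoires.

    Each unordered pair is solved once and mirrored, so the matrix is
    symmetric by construction.  The diagonal is the honest self-transport
    cost (near zero but not exactly zero under entropic smoothing) unless
    ``zero_diagonal`` is set.
    """
    if len(repertoires) < 2:
        raise ValidationError("need at least 2 repertoires")
    table = table or GermlineCdrTable.default()
    n = len(repertoires)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j and zero_diagonal:
                continue
            cost = repertoire_transport(
                repertoires[i], repertoires[j], table, epsilon=epsilon
            ).total_cost
            M[i, j] = M[j, i] = cost
    labels = [r.label or f"repertoire_{i}" for i, r in enumerate(repertoires)]
    return RepertoireDistanceMatrix(matrix=M, labels=labels)


def hierarchical_dendrogram(
    M: RepertoireDistanceMatrix, linkage: str = "ward"
) -> tuple[np.ndarray, str]:
    """Agglomerative tree over a repertoire distance matrix.

    Returns the scipy linkage matrix and a Newick string whose branch
    lengths derive from merge heights.  The off-diagonal matrix must be
    symmetric; the diagonal is ignored (treated as zero for linkage).
    """
    if linkage not in ("ward", "average", "complete"):
        raise ValidationError(f"unsupported linkage {linkage!r}")
    A = np.asarray(M.matrix, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, rtol=1e-6, atol=1e-9):
        raise ValidationError("distance matrix must be square and symmetric")
    B = A.copy()
    np.fill_diagonal(B, 0.0)
    Z = hierarchy.linkage(squareform(B, checks=False), method=linkage)
    return Z, linkage_to_newick(Z, M.labels)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage tree as Newick with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def recurse(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return recurse(tree, tree.dist) + ";"


@dataclass
class ComparisonConfig:
    """All tunables of the end-to-end pipeline (mirrors the CLI flags)."""

    epsilon: float = DEFAULT_EPSILON
    delta: float = DEFAULT_DELTA
    step: float = DEFAULT_STEP
    r_max: float = DEFAULT_R_MAX
    max_clusters: int = 10
    weighting: str = "uniform"
    trials: int = 0  # 0 disables the randomization test
    seed: int = 0
    germline_table: str | None = None


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_full_comparison(
    source_path: str | Path,
    target_path: str | Path,
    outdir: str | Path,
    config: ComparisonConfig | None = None,
) -> dict:
    """Run the full source-vs-target comparison and write a report bundle.

    Writes ``scores.tsv``, ``clusters.json``, ``motifs.json`` and
    ``run_log.json`` into ``outdir``; returns the run log as a dict.
    Deterministic for fixed inputs and seed.
    """
    cfg = config or ComparisonConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = (
        GermlineCdrTable.from_tsv(cfg.germline_table)
        if cfg.germline_table
        else GermlineCdrTable.default()
    )
    source = load_repertoire(source_path, weighting=cfg.weighting, table=table)
    target = load_repertoire(target_path, weighting=cfg.weighting, table=table)

    D22 = self_distance_matrix(target, table)
    scores = score_repertoire_pair(
        source, target, table, epsilon=cfg.epsilon, delta=cfg.delta, D22=D22
    )
    clusters = extract_clusters(
        scores, D22, step=cfg.step, r_max=cfg.r_max, max_clusters=cfg.max_clusters
    )

    frame = scores.to_frame()
    assignment = clusters.assignments(len(target))
    frame["cluster_id"] = [int(a) if a else None for a in assignment]

    if cfg.trials > 0:
        rand = randomization_test(
            source,
            target,
            trials=cfg.trials,
            seed=cfg.seed,
            delta=cfg.delta,
            epsilon=cfg.epsilon,
            table=table,
        )
        frame["p_value"] = rand.p_value

    write_scores_table(frame, outdir / "scores.tsv")

    cluster_payload = []
    motif_payload = []
    for cl in clusters:
        cluster_payload.append(
            {
                "rank": cl.rank,
                "centroid": {"v_allele": cl.centroid.v_allele, "cdr3": cl.centroid.cdr3},
                "breakpoint": cl.breakpoint,
                "members": cl.member_indices,
                "fit": {
                    "status": cl.fit.status,
                    "beta0": cl.fit.beta0,
                    "beta1": cl.fit.beta1,
                    "beta2": cl.fit.beta2,
                    "sse": cl.fit.sse,
                    "sse_line": cl.fit.sse_line,
                },
            }
        )
        member_tcrs = [target.tcrs[i] for i in cl.member_indices]
        if len(member_tcrs) >= 2:
            aln = build_alignment([t.cdr3 for t in member_tcrs])
            profile = profile_stats(aln, [t.v_allele for t in member_tcrs])
            motif_payload.append(
                {
                    "rank": cl.rank,
                    "consensus": profile.consensus,
                    "match_columns": profile.match_columns,
                    "frequencies": profile.frequencies.tolist(),
                    "occupancy": profile.occupancy.tolist(),
                    "insertion_prob": profile.insertion_prob.tolist(),
                    "expected_insert_len": profile.expected_insert_len.tolist(),
                    "v_usage": profile.v_usage,
                }
            )

    (outdir / "clusters.json").write_text(json.dumps(cluster_payload, indent=2))
    (outdir / "motifs.json").write_text(json.dumps(motif_payload, indent=2))

    run_log = {
        "package_version": __version__,
        "config": asdict(cfg),
        "source": {"path": str(source_path), "n": len(source), "sha256": _digest(source_path)},
        "target": {"path": str(target_path), "n": len(target), "sha256": _digest(target_path)},
        "total_transport_cost": scores.total_cost,
        "n_clusters": len(clusters),
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2))
    return run_log
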