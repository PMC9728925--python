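"""Per-TCR enrichment ("loneliness") scores from the effort decomposition.

The effort matrix E = P ⊙ D partitions the total transport cost over
clonotype pairs.  The *individual loneliness* of a target TCR is the sum
of the effort column that indexes it: the work spent moving source mass
onto it.  Because an outlier in both repertoires also accrues effort, the
operative score is the *neighborhood loneliness*: the summed individual
loneliness of all target TCRs strictly within a TCRdist ball of radius δ,
taken within the target repertoire.  A TCR in a dense target-only region
collects many high-effort neighbors; an isolated oddball does not.

Default δ = 48.5 TCRdist units, roughly 0–4 CDR3 mismatches plus a few
germline-loop mismatches, a practical radius for single-chain data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import GermlineCdrTable, Repertoire
from .metric import self_distance_matrix
from .transport import DEFAULT_EPSILON, TransportResult, repertoire_transport

#: default neighborhood radius in TCRdist units
DEFAULT_DELTA = 48.5


@dataclass
class LonelinessTable:
    """Per target-TCR loneliness scores at radius δ."""

    repertoire: Repertoire
    individual: np.ndarray
    neighborhood: np.ndarray
    neighbor_count: np.ndarray
    delta: float
    total_cost: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "v_allele": [t.v_allele for t in self.repertoire.tcrs],
                "cdr3": [t.cdr3 for t in self.repertoire.tcrs],
                "individual_loneliness": self.individual,
                "neighborhood_loneliness": self.neighborhood,
                "neighbor_count": self.neighbor_count,
            }
        )


def paired_effort(result: TransportResult, i: int, j: int) -> float:
    """Effort spent moving mass between source TCR i and target TCR j."""
    return float(result.effort[i, j])


def individual_loneliness(result: TransportResult, j: int) -> float:
    """Column sum of the effort matrix at target index j."""
    return float(result.effort[:, j].sum())


def individual_loneliness_vector(result: TransportResult) -> np.ndarray:
    """All column sums at once; sums to the total transport cost."""
    return result.effort.sum(axis=0)


def neighborhood_loneliness(
    result: TransportResult,
    D22: np.ndarray,
    j: int,
    delta: float = DEFAULT_DELTA,
) -> float:
    """Summed individual loneliness over the δ-ball around target TCR j.

    The ball is taken within the target repertoire with a strict
    inequality, ``TCRdist(t_j, t') < δ``; it always contains t_j itself.
    """
    return float(neighborhood_loneliness_vector(result, D22, delta)[j])


def neighborhood_loneliness_vector(
    result: TransportResult,
    D22: np.ndarray,
    delta: float = DEFAULT_DELTA,
) -> np.ndarray:
    if delta <= 0:
        raise ValidationError("delta must be positive")
    m = result.effort.shape[1]
    if D22.shape != (m, m):
        raise ValidationError(
            f"within-target distance matrix shape {D22.shape} != ({m}, {m})"
        )
    indiv = individual_loneliness_vector(result)
    ball = D22 < delta
    return ball @ indiv


def score_repertoire_pair(
    r1: Repertoire,
    r2: Repertoire,
    table: GermlineCdrTable | None = None,
    epsilon: float = DEFAULT_EPSILON,
    delta: float = DEFAULT_DELTA,
    D: np.ndarray | None = None,
    D22: np.ndarray | None = None,
) -> LonelinessTable:
    """End-to-end scoring of target repertoire ``r2`` against source ``r1``.

    Composes distance matrix → Sinkhorn plan → effort → loneliness.  The
    within-target distance matrix is computed explicitly (precomputed
    matrices may be passed when scoring many pairs).
    """
    result = repertoire_transport(r1, r2, table, epsilon=epsilon, D=D)
    if D22 is None:
        D22 = self_distance_matrix(r2, table)
    indiv = individual_loneliness_vector(result)
    ball = D22 < delta
    return LonelinessTable(
        repertoire=r2,
        individual=indiv,
        neighborhood=ball @ indiv,
        neighbor_count=ball.sum(axis=1),
        delta=delta,
        total_cost=result.total_cost,
    )
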