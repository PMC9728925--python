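"""Lonely-cluster extraction by annulus profiles and segmented regression.

Around the loneliest un-clustered target TCR we step outward in annuli of
width s (default 5 TCRdist units, radii 0, 5, …, up to r_max = 200) and
record the mean neighborhood loneliness of the TCRs falling in each
annulus.  In a genuinely enriched region this profile decays with radius
and then flattens; the flattening radius is estimated by a two-segment
continuous ("broken-stick") regression

    E[M | r] = β0 + β1 r + β2 (r − ρ)_+

whose breakpoint ρ̂ becomes the cluster radius.  Members are the
un-clustered TCRs with TCRdist(t, t_max) ≤ ρ̂; the procedure repeats on
the remainder until a breakpoint cannot be estimated or the cluster cap
is reached.

The breakpoint is accepted only when the elbow is real: at least two
populated annuli on each side, ≥ 10% SSE improvement over a single line,
and a slope change β2 significant at 95% by a t-test from the OLS
covariance.  These rules mirror the practical behavior of segmented
regression packages while staying explicit and testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from .errors import ValidationError
from .io import TcrBeta
from .loneliness import LonelinessTable

DEFAULT_STEP = 5.0
DEFAULT_R_MAX = 200.0
#: minimum populated annuli required on each side of a breakpoint
MIN_SIDE_POINTS = 2
#: required relative SSE improvement over the single-line fit
MIN_SSE_IMPROVEMENT = 0.10


@dataclass
class AnnulusProfile:
    """Mean loneliness per annulus around a centroid TCR.

    ``radii[i]`` is the inner edge of annulus i, covering
    [radii[i], radii[i] + step); the first annulus is the ball [0, step).
    Only populated annuli appear.
    """

    radii: np.ndarray
    means: np.ndarray
    counts: np.ndarray
    step: float
    r_max: float


@dataclass
class SegmentedFit:
    """Two-segment continuous regression of mean loneliness on radius."""

    status: str  # "ok" | "no-breakpoint"
    breakpoint: float | None = None
    beta0: float = math.nan
    beta1: float = math.nan
    beta2: float = math.nan
    sse: float = math.nan
    sse_line: float = math.nan
    t_beta2: float = math.nan


@dataclass
class LonelyCluster:
    rank: int
    centroid_index: int
    centroid: TcrBeta
    breakpoint: float
    member_indices: list[int]
    fit: SegmentedFit


@dataclass
class ClusterSet:
    clusters: list[LonelyCluster] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def assignments(self, n: int) -> np.ndarray:
        """Cluster rank per TCR index (0 = unassigned)."""
        out = np.zeros(n, dtype=np.int64)
        for cl in self.clusters:
            out[cl.member_indices] = cl.rank
        return out


def annulus_profile(
    neighborhood: np.ndarray,
    D22: np.ndarray,
    t_max: int,
    step: float = DEFAULT_STEP,
    r_max: float = DEFAULT_R_MAX,
    active: np.ndarray | None = None,
) -> AnnulusProfile:
    """Mean loneliness in semi-closed annuli [r, r+step) around ``t_max``.

    ``active`` masks the TCRs still in play (un-clustered); means are
    taken over those only.  Empty annuli are skipped, not imputed.
    """
    if step <= 0:
        raise ValidationError("step must be positive")
    neighborhood = np.asarray(neighborhood, dtype=float)
    d = D22[t_max]
    if active is None:
        active = np.ones(len(d), dtype=bool)

    radii, means, counts = [], [], []
    r = 0.0
    while r < r_max - 1e-12:
        in_annulus = active & (d >= r) & (d < r + step)
        k = int(in_annulus.sum())
        if k > 0:
            radii.append(r)
            means.append(float(neighborhood[in_annulus].mean()))
            counts.append(k)
        r += step
    return AnnulusProfile(
        radii=np.asarray(radii),
        means=np.asarray(means),
        counts=np.asarray(counts, dtype=np.int64),
        step=step,
        r_max=r_max,
    )


def _hinge_ols(r: np.ndarray, m: np.ndarray, rho: float) -> tuple[np.ndarray, float]:
    X = np.column_stack([np.ones_like(r), r, np.maximum(r - rho, 0.0)])
    beta, *_ = np.linalg.lstsq(X, m, rcond=None)
    resid = m - X @ beta
    return beta, float(resid @ resid)


def fit_segmented(profile: AnnulusProfile) -> SegmentedFit:
    """Least-squares broken-stick fit with profiled breakpoint search.

    The SSE is minimized over candidate breakpoints at each interior
    populated radius, then refined by bounded scalar minimization between
    the neighboring radii.  Returns status ``no-breakpoint`` when the
    acceptance rules fail (too few annuli, no real elbow, breakpoint at
    the range edge).
    """
    r = profile.radii.astype(float)
    m = profile.means.astype(float)
    k = len(r)
    if k < 5:
        return SegmentedFit(status="no-breakpoint")

    # single-line baseline
    X1 = np.column_stack([np.ones_like(r), r])
    beta_line, *_ = np.linalg.lstsq(X1, m, rcond=None)
    sse_line = float(((m - X1 @ beta_line) ** 2).sum())

    # interior candidates with >= MIN_SIDE_POINTS populated radii each side
    best: tuple[float, float] | None = None  # (sse, rho)
    for i in range(MIN_SIDE_POINTS, k - MIN_SIDE_POINTS):
        rho = r[i]
        _, sse = _hinge_ols(r, m, rho)
        if best is None or sse < best[0]:
            best = (sse, rho)
    if best is None:
        return SegmentedFit(status="no-breakpoint")

    # golden-section refinement between the neighbors of the best grid rho
    i = int(np.searchsorted(r, best[1]))
    lo = r[max(i - 1, MIN_SIDE_POINTS - 1)]
    hi = r[min(i + 1, k - MIN_SIDE_POINTS)]
    if hi > lo:
        res = minimize_scalar(
            lambda rho: _hinge_ols(r, m, rho)[1],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if res.fun <= best[0] + 1e-15:
            best = (float(res.fun), float(res.x))

    sse, rho = best
    beta, sse = _hinge_ols(r, m, rho)

    # acceptance rules
    n_left = int((r < rho).sum())
    n_right = int((r > rho).sum())
    if n_left < MIN_SIDE_POINTS or n_right < MIN_SIDE_POINTS:
        return SegmentedFit(status="no-breakpoint", sse=sse, sse_line=sse_line)
    if rho <= r[0] or rho >= profile.r_max:
        return SegmentedFit(status="no-breakpoint", sse=sse, sse_line=sse_line)
    # a straight line that is already perfect to floating precision leaves
    # nothing for a breakpoint to explain
    sse_floor = k * (np.finfo(float).eps * max(1.0, float(np.abs(m).max()))) ** 2 * 100.0
    if sse_line <= sse_floor or (sse_line - sse) / sse_line < MIN_SSE_IMPROVEMENT:
        return SegmentedFit(status="no-breakpoint", sse=sse, sse_line=sse_line)

    # t-test on the slope change beta2 from the OLS covariance at fixed rho
    df = k - 3
    if df <= 0:
        return SegmentedFit(status="no-breakpoint", sse=sse, sse_line=sse_line)
    X = np.column_stack([np.ones_like(r), r, np.maximum(r - rho, 0.0)])
    xtx_inv = np.linalg.pinv(X.T @ X)
    sigma2 = sse / df
    se_b2 = math.sqrt(max(sigma2 * xtx_inv[2, 2], 0.0))
    if se_b2 == 0.0:
        # exact piecewise data: zero residual with a genuine slope change
        t_b2 = math.inf if abs(beta[2]) > 1e-12 else 0.0
    else:
        t_b2 = beta[2] / se_b2
    t_crit = stats.t.ppf(0.975, df)
    if not abs(t_b2) > t_crit:
        return SegmentedFit(
            status="no-breakpoint", sse=sse, sse_line=sse_line, t_beta2=t_b2
        )

    return SegmentedFit(
        status="ok",
        breakpoint=rho,
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        beta2=float(beta[2]),
        sse=sse,
        sse_line=sse_line,
        t_beta2=float(t_b2),
    )


def extract_clusters(
    scores: LonelinessTable,
    D22: np.ndarray,
    step: float = DEFAULT_STEP,
    r_max: float = DEFAULT_R_MAX,
    max_clusters: int = 10,
) -> ClusterSet:
    """Iteratively extract lonely clusters from the target repertoire.

    Each round: take the loneliest un-clustered TCR (ties broken by input
    order), build its annulus profile over the remaining TCRs, fit the
    breakpoint, and claim the un-clustered TCRs within ρ̂ (inclusive).
    Stops when the breakpoint cannot be estimated or ``max_clusters`` is
    reached.
    """
    if max_clusters < 1:
        raise ValidationError("max_clusters must be >= 1")
    nbhd = np.asarray(scores.neighborhood, dtype=float)
    n = len(nbhd)
    active = np.ones(n, dtype=bool)
    out = ClusterSet()

    while active.any() and len(out) < max_clusters:
        masked = np.where(active, nbhd, -np.inf)
        t_max = int(np.argmax(masked))  # argmax is stable: first max wins
        profile = annulus_profile(nbhd, D22, t_max, step=step, r_max=r_max, active=active)
        fit = fit_segmented(profile)
        if fit.status != "ok":
            break
        members = np.flatnonzero(active & (D22[t_max] <= fit.breakpoint))
        out.clusters.append(
            LonelyCluster(
                rank=len(out) + 1,
                centroid_index=t_max,
                centroid=scores.repertoire.tcrs[t_max],
                breakpoint=float(fit.breakpoint),
                member_indices=[int(i) for i in members],
                fit=fit,
            )
        )
        active[members] = False
    return out
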