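# Methods

This note records the statistical model behind `tcrot`, the default
parameters and why they are what they are, and the numerical choices
that are easy to miss when reading the code.

## Problem setting

A TCRβ clonotype is a pair (TRBV allele, CDR3 amino-acid sequence). A
repertoire is a finite set of clonotypes with abundances, modeled as a
discrete probability distribution: either uniform over clonotypes
(default) or proportional to abundance. Comparing two repertoires R1
(source) and R2 (target) asks: which parts of R2 have no counterpart in
R1?

## TCRdist metric

Distance between clonotypes is a similarity-weighted mismatch distance
over the four CDR loops (CDR1, CDR2, CDR2.5 from the germline V gene;
CDR3 from the sequenced junction):

- Per-position residue distance: 0 for an identical pair (including
  gap–gap), 4 if exactly one position is a gap, otherwise
  `min(4, 4 − BLOSUM62(a, b))`. Any pair with non-positive BLOSUM62
  score therefore saturates at the cap of 4.
- Loop weights: CDR3 counts 3×, the germline loops 1×.
- CDR3 length mismatch is resolved by inserting a single contiguous gap
  block into the shorter sequence at offset `ceil(len(shorter)/2)`,
  i.e. just past the middle, which keeps the conserved flanks aligned.

The germline loops come from a bundled allele table. The shipped table
is a deterministic synthetic stand-in (distinct fixed-length loops per
allele); every algorithm depends only on the table being self-consistent,
and a user-supplied TSV (`v_allele, cdr1, cdr2, cdr2_5`) can replace it
everywhere via `--germline` / `table=`.

## Optimal transport and loneliness

With marginals r (source) and c (target) and distance matrix D, the
transport polytope U(r, c) holds all couplings with those marginals. The
exact earth mover's distance is the LP `min ⟨D, P⟩ over U(r, c)`; we
solve it with `scipy.optimize.linprog` (HiGHS) for oracle-scale
problems (guarded at 10,000 matrix cells).

The workhorse is the entropically regularized Sinkhorn plan:
`min ⟨D, P⟩ − ε·h(P)`, computed by log-domain scaling iterations.
Regularization is applied to the max-normalized distance matrix
(`D / max(D)`), so `ε` has a scale-free meaning; reported costs are on
the original TCRdist scale.

The effort matrix `E = P ⊙ D` partitions the total cost. Per-TCR scores:

- individual loneliness of a target TCR = its column sum of E;
- neighborhood loneliness = sum of individual loneliness over all target
  TCRs strictly within TCRdist δ (the ball always contains the TCR
  itself).

Neighborhood loneliness is the primary statistic: a lone odd sequence is
noisy, but a whole δ-ball absorbing distant mass marks an enriched
cluster. On spike-in simulations the neighborhood AUROC dominates the
individual AUROC, matching this reasoning.

## Cluster extraction

Around the loneliest target TCR we take annuli `[r, r + s)` of width
s and regress mean annulus loneliness on radius with a two-segment
(hinge) model `β0 + β1·r + β2·(r − ρ)+`, scanning breakpoint candidates
on the annulus grid and refining with bounded scalar minimization. A
breakpoint is accepted only when (i) at least 2 annuli lie on each side,
(ii) the segmented fit improves SSE over a straight line by at least
10%, and (iii) β2 is significant at 95% (t-test). Cluster members are
all active TCRs within ρ̂ of the centroid; the procedure repeats on the
remaining TCRs for lower-ranked clusters. Profiles that a straight line
already fits to floating-point precision are declared breakpoint-free
outright (a scale-relative SSE floor guards against 1e-29-level noise
passing the 10% rule).

## Significance

Randomization (relabeling) test: pool the occurrences of both
repertoires, compute the pooled distance matrix once, and for each trial
reassign occurrences at random preserving the two sample sizes; each
trial's slice of the pooled matrix yields trial loneliness scores. A
target TCR accumulates a null sample from the trials that place it in
the trial target; nulls are downsampled to a common size and the add-one
estimator gives `p = (1 + #{null ≥ obs}) / (1 + m)`.

Discreteness note: with m nulls the smallest attainable p is 1/(m+1),
and rejection at α = 0.05 with one exceedance requires m ≥ 39. The
`min_null_size` option runs extra trials until every null reaches the
requested size; m = 40 is the natural choice for calibrated 5%-level
decisions.

Replicate z-scores: when replicate repertoires exist, each target TCR's
observed loneliness is standardized against its scores versus the other
background replicates. The permutation z-scale and the replicate z-scale
answer different questions (within-sample resampling vs between-organism
variation); `map_z_scores` exposes an explicit linear map between them
rather than assuming one.

## Motif summaries

Cluster CDR3s are multiple-aligned center-star style: the medoid under
Needleman–Wunsch/BLOSUM62 (gap −4, deterministic traceback) is the
center, pairwise alignments to it are merged into a master gap pattern.
Match columns are those with occupancy ≥ 0.5; the profile records
per-column residue frequencies, occupancy, insertion probability and
expected insertion length, plus V-allele usage. Queries are scored by a
best-path (Viterbi) log2-odds bit score through match/insert/delete
states with pseudocounted emissions and transitions clipped away from
hard 0/1; hard membership thresholds an empirical E-value from
background-sampled sequences (`E < 0.01` by default). Alignments export
to FASTA and Stockholm for interop with external HMM tools.

## Synthetic data and benchmark

The background generator emits naive-like CDR3s (`C…F`, interior drawn
from a fixed residue frequency table, lengths 10–18 with fixed weights,
uniform V usage by default). A spike-in cluster consists of variants of
a seed clonotype with 0–2 uniform point substitutions, so within-cluster
TCRdist is at most 24 per allowed substitution (two sequences × cap 4 ×
CDR3 weight 3). The benchmark plants k spike-ins into an n-clonotype
target, scores it against a clean source, and reports AUROC of both
loneliness flavors over seeded replicates. This generator is a
structural emulation — it reproduces the shape of the detection problem,
not the biological realism of VDJ recombination; absolute AUROCs should
be read as properties of the method on this generator only.

## Defaults and why

| parameter | default | rationale |
|---|---|---|
| Sinkhorn ε | 0.01 | on the max-normalized D: sharp enough that cost ≈ EMD within a few %, smooth enough to converge at 500×500 in seconds |
| neighborhood δ | 48.5 | half-integer avoids ties at integer TCRdist values; ~4 saturated CDR3 mismatches |
| annulus step s | 5 | resolves breakpoints at the scale of single-residue distance differences |
| r_max | 200 | beyond it, annulus means are dominated by unrelated sequences |
| randomization trials | 100 | null size ≈ 50 per TCR at equal sample sizes |
| motif E-value cutoff | 0.01 | at the default 10,000 null samples, demands a score above all but ~0 of the null |
| benchmark n, k | 500; 5/20/50 | desk-scale study sizes; configurable up to study scale |

## Numerical choices

- Sinkhorn runs in the log domain with hand-rolled row/column
  logsumexp (max + exp + sum), ε-scaling warm starts (halving from
  max(D) down to the target ε), and residual checks every 5 iterations.
- The final iterate is projected onto U(r, c) by marginal rounding (row
  scaling, column scaling, rank-one correction). The rounded plan is
  exactly feasible to float precision, remains non-negative, and its
  cost is by construction an upper bound on the exact EMD — so the
  guarantee "Sinkhorn cost ≥ EMD" survives truncation of the iteration
  (inner residual target 1e-6).
- Zero-mass atoms are dropped before the solve and reinserted as zero
  rows/columns afterwards.
- The exact LP drops one redundant marginal constraint (the polytope's
  constraints sum to the same total on both sides) to keep HiGHS happy.
- `distance_matrix` deduplicates clonotypes, groups CDR3s by length pair
  so the per-position mismatch table is applied to whole blocks, and
  expands back with index arrays; the germline loop contribution is a
  per-allele-pair matrix computed once.

## Limitations

- The bundled germline table is synthetic; real analyses should supply
  an IMGT-derived table.
- Ward linkage formally presumes Euclidean structure; using it on
  transport costs is a pragmatic, documented approximation (average and
  complete linkage are offered).
- The randomization null models within-sample resampling, not
  between-organism variation; its z-scores are not directly comparable
  to replicate z-scores without an explicit calibration map.
- Entropic smoothing biases total cost upward, most visibly for a
  repertoire against itself (near-zero, not zero); `exact_emd` exists
  for small instances when exactness matters.
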