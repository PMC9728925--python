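# tcrot — comparing TCR repertoires with optimal transport

`tcrot` compares T-cell receptor β-chain repertoires nonparametrically:
it moves one repertoire's probability mass onto the other with an
entropically regularized optimal-transport (Sinkhorn) plan over the
TCRdist sequence metric, and asks where that transport had to work hard.
Target TCRs that absorb mass over long distances — "lonely" TCRs — have
no counterpart in the source repertoire; contiguous balls of lonely TCRs
are clusters of differential enrichment, e.g. clonal expansions after an
immune challenge.

What you get per comparison:

- **Loneliness scores** for every target TCR (individual = its column of
  the effort matrix `P ⊙ D`; neighborhood = summed over a TCRdist
  δ-ball, the primary statistic).
- **Lonely clusters**: balls around loneliness peaks whose radii are
  estimated by segmented regression of mean annulus loneliness vs
  radius (breakpoint = cluster edge).
- **Significance**: a pooled relabeling (randomization) test with
  per-TCR empirical p-values, plus replicate-based z-scores when
  biological replicates exist.
- **Motif summaries** of each cluster: center-star CDR3 alignment,
  per-column frequencies/occupancy/insertion statistics, log-odds
  scoring of new sequences with empirical E-values.
- **Repertoire-level comparison**: pairwise total-transport distance
  matrices with Ward dendrograms (Newick export).
- **Synthetic spike-in benchmark**: plant k near-duplicate clonotypes in
  a background of n and measure recovery by AUROC.

## Worked example

```python
from tcrot import make_spikein_pair, score_repertoire_pair

# a 200-clonotype pair in which 20 target TCRs form a planted cluster
source, target, is_spikein = make_spikein_pair(n=200, k=20, seed=42)
scores = score_repertoire_pair(source, target)
frame = scores.to_frame()
```

Running `python examples/01_score_repertoires.py` (the same computation
with reporting) prints:

```text
total transport cost: 145.74 TCRdist units
neighborhood radius delta = 48.5

10 loneliest target TCRs (spike-ins should dominate):
 v_allele          cdr3  neighborhood_loneliness  spikein
TRBV19*01 CASSIRSSLEQHF                 17.46733     True
TRBV19*01 CASSIRSSYEQYF                 17.46733     True
TRBV19*01 CASSIRSSVEQDF                 17.46733     True
TRBV19*01 CASSIRSSYEQYF                 17.46733     True
TRBV19*01 CASSERSKYEQYF                 17.46733     True
TRBV19*01 CASSIRSSYEQYF                 17.46733     True
TRBV19*01 CASSISSSYEQYF                 17.46733     True
TRBV19*01 CASSINSHYEQYF                 17.46733     True
TRBV19*01 CASSIRSSYIQYF                 17.46733     True
TRBV19*01 CASSIRSSYEQYF                 17.46733     True

median neighborhood loneliness: spike-ins 17.47 vs background 0.71
```

The spiked-in TRBV19 clonotypes dominate the loneliness ranking, which
is the core claim of the method: transport effort localizes exactly
where the target repertoire differs from the source.

More narrative walkthroughs live in `examples/`:

| script | shows |
|---|---|
| `01_score_repertoires.py` | transport + loneliness scores |
| `02_find_lonely_clusters.py` | segmented-regression cluster extraction |
| `03_significance_testing.py` | randomization-test p-values |
| `04_motif_summary.py` | cluster alignment, motif profile, membership |
| `05_repertoire_dendrogram.py` | many-repertoire distance matrix + tree |
| `06_spikein_benchmark.py` | AUROC benchmark across spike-in counts |

## Command line

The same stages are exposed as a thin CLI:

```sh
tcrot simulate --out bg.tsv --n 200 --seed 1
tcrot simulate --out mix.tsv --n 200 --spikeins 20 --seed 2
tcrot compare --source bg.tsv --target mix.tsv --out scores.tsv
tcrot cluster --source bg.tsv --target mix.tsv --outdir report/
tcrot significance --source bg.tsv --target mix.tsv --out pvals.tsv --trials 100 --seed 0
tcrot matrix a.tsv b.tsv c.tsv --out dist.tsv --newick tree.nwk
tcrot benchmark --out auroc.tsv --seed 0
```

Input tables are TSV/CSV with columns for the TRBV gene/allele, the
CDR3 amino-acid sequence, and optionally a count (column names are
matched case-insensitively; see `tcrot.io`). `tcrot cluster` writes a
full report bundle (`scores.tsv`, `clusters.json`, `motifs.json`,
`run_log.json`).

## Model in one paragraph

Clonotypes are (TRBV allele, CDR3) pairs; a repertoire is a discrete
distribution over them (uniform or abundance-weighted). TCRdist sums
capped BLOSUM62 mismatch costs over the four CDR loops with CDR3
weighted 3×; CDR3 length mismatches get a single mid-sequence gap block.
The Sinkhorn plan minimizes `⟨D, P⟩ − ε·h(P)` over couplings of the two
distributions (log-domain iterations, ε = 0.01 on the max-normalized
distance matrix, final plan rounded onto the exact marginal polytope).
The effort matrix `E = P ⊙ D` decomposes the total cost; loneliness
aggregates its columns. Defaults: δ = 48.5, annulus step 5, breakpoint
acceptance requires ≥ 10% SSE improvement and a 95% t-test on the slope
change. Full details, parameter rationale, and limitations are in
[docs/methods.md](docs/methods.md).

The bundled germline CDR-loop table is a deterministic synthetic
stand-in; supply your own IMGT-derived table (`--germline`, or
`GermlineCdrTable.from_tsv`) for real analyses.

## Reproduction

`scripts/acceptance.py` recomputes the package's exact acceptance
targets (residue-level metric definitions) at runtime and writes them as
JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The binding end-to-end checks — metric definitions, shipped defaults,
transport correctness against independent oracles (Hungarian,
permutation enumeration, min-cost flow), conservation identities,
breakpoint recovery, randomization-test calibration, spike-in AUROC, and
end-to-end cluster recovery — run as `tests/test_acceptance.py` within
the normal suite.
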