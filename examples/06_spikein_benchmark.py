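"""Benchmark spike-in recovery with AUROC.

For each spike-in count k, we repeatedly plant k near-duplicate
clonotypes into a fresh background, score the target repertoire, and ask
how well loneliness ranks spike-ins above background (AUROC). Detection
should get easier as k grows, and neighborhood loneliness should beat
individual loneliness.

Note: this is a scaled-down run (n = 120, 3 replicates) so it finishes in
about a minute; raise n/replicates for a study-scale benchmark.
"""

from tcrot import spikein_benchmark

df = spikein_benchmark(n=120, k_grid=(5, 15, 40), replicates=3, seed=0)

print(df.to_string(index=False))
print("\nmean AUROC by k:")
summary = df.groupby("k")[["auroc_neighborhood", "auroc_individual"]].mean()
print(summary.round(3).to_string())
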