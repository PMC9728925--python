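"""Compare many repertoires at once with a transport-distance dendrogram.

The total Sinkhorn cost between two repertoires is a global
dissimilarity; assembling it for every pair gives a distance matrix we
can feed to hierarchical clustering. Here, two planted families (pure
background vs spike-in dominated) should split into two clean clades.
"""

from scipy.cluster.hierarchy import fcluster

from tcrot import (
    Repertoire,
    SimConfig,
    generate_background,
    generate_spikein_cluster,
    hierarchical_dendrogram,
    pairwise_repertoire_distances,
)

repertoires = []
for seed in (1, 2, 3):
    rep = generate_background(SimConfig(seed=seed, n_background=30))
    repertoires.append(Repertoire.from_tcrs(rep.tcrs, label=f"background-{seed}"))
for seed in (4, 5, 6):
    bg = generate_background(SimConfig(seed=seed, n_background=10))
    spike = generate_spikein_cluster(SimConfig(seed=seed, n_background=0, n_spikein=20))
    repertoires.append(
        Repertoire.from_tcrs(bg.tcrs + spike.tcrs, label=f"spiked-{seed}")
    )

M = pairwise_repertoire_distances(repertoires)
print("pairwise total-transport distances:")
print(M.to_frame().round(1).to_string())

Z, newick = hierarchical_dendrogram(M, linkage="ward")
labels = fcluster(Z, t=2, criterion="maxclust")
print("\ntwo-way cut:", dict(zip(M.labels, labels)))
print("\nNewick tree:")
print(newick)
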