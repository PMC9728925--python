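"""Summarize a TCR cluster as a CDR3 motif profile.

Cluster members are multiple-aligned with a center-star strategy, the
alignment is reduced to match-column frequencies plus insertion
statistics, and new sequences can be scored (log2-odds bits) against the
profile with an empirical E-value for hard membership calls.
"""

from tcrot import (
    SimConfig,
    build_alignment,
    empirical_null_scores,
    generate_spikein_cluster,
    hard_membership,
    profile_stats,
    score_sequence,
)

cluster = generate_spikein_cluster(SimConfig(seed=11, n_background=0, n_spikein=12))
cdr3s = [t.cdr3 for t in cluster.tcrs]

alignment = build_alignment(cdr3s)
print("cluster alignment:")
for row in alignment:
    print(f"  {row}")

profile = profile_stats(alignment, [t.v_allele for t in cluster.tcrs])
print(f"\nconsensus: {profile.consensus}")
print(f"match columns: {profile.match_columns}")
print(f"V usage: {profile.v_usage}")

# score the consensus and a random-looking sequence against the profile
null = empirical_null_scores(profile, lengths=[len(c) for c in cdr3s],
                             n_samples=2000, seed=0)
for query in (profile.consensus, "CGWYDRAWYTEQF"):
    bits = score_sequence(profile, query)
    member, e_value = hard_membership(profile, query, null_scores=null)
    print(f"\nquery {query}: {bits:.1f} bits, E = {e_value:g}, "
          f"member = {member}")
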