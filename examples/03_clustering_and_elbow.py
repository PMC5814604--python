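"""Cluster raw MET vectors with Lloyd k-means and pick k by the elbow rule.

25 random restarts per k guard against bad local optima; the elbow stops at
the first k whose next cluster cuts within-group SS by less than 10%.
"""

from acticlust import (
    default_trial_config, generate_cohort, filter_valid_participants,
    raw_feature_matrix, elbow_scan, name_clusters, smooth_cluster_curves,
)

cohort, planted = generate_cohort(default_trial_config(), seed=42)
cohort, _ = filter_valid_participants(cohort)
features = raw_feature_matrix(cohort)

scan = elbow_scan(features, k_max=4, restarts=25, seed=42)
print("WSS by k:", [round(w) for w in scan.wss_by_k])
reductions = [
    round(float((a - b) / a), 3) for a, b in zip(scan.wss_by_k, scan.wss_by_k[1:])
]
print("relative reductions:", reductions)  # big cuts to k=3, then < 10%
print("elbow chooses k =", scan.chosen_k)

result = scan.results[scan.chosen_k - 1]
print("cluster sizes:", result.cluster_sizes().tolist())
print(f"variance explained: {result.variance_explained:.1%}")

curves = smooth_cluster_curves(features, result.labels)
names = name_clusters(result, curves, features.kind)
print("cluster names:", names)
# the lowest-activity cluster is "unengaged"; the others are named by
# whether their smoothed diel curve peaks before or after noon
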