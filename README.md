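# acticlust

Diel physical-activity pattern analysis for minute-level accelerometry.

`acticlust` is for researchers who have minute-epoch accelerometer exports —
one MET (metabolic equivalent of task) value per worn minute, seven
consecutive days per participant — and want to answer: *when* during the day
are participants active, do participants fall into distinct temporal activity
types, and how do those types differ on sociodemographic and clinical
covariates? It implements the full analysis chain as a tested library with a
thin CLI, plus a synthetic-cohort generator so every stage can be exercised
and validated without any participant data.

## The analysis

1. **Wear validity.** A day is valid when it has ≥ 8 h of recorded wear;
   participants need all 7 days valid. A minute is "worn" iff a MET value was
   recorded for it.
2. **Features.** Two representations of participant *i*'s record
   d<sub>i,t</sub> (t = 1..10,080 minutes):
   - *raw*: the 10,080-vector of minute METs, missing minutes imputed to 1
     (the stationary MET level);
   - *normalized MVPA*: binarize b<sub>i,t</sub> = 1{d<sub>i,t</sub> ≥ 3},
     average the 7 days minute-of-day-wise into a 1440-length MVPA frequency
     profile, and scale it to unit Euclidean norm — removing activity volume
     so clustering responds to timing alone.
3. **Clustering.** Lloyd k-means (squared Euclidean, centroids = means),
   25 random restarts, best WSS wins; k chosen by the elbow rule (smallest k
   whose next cluster cuts WSS by < 10%). Accuracy is reported as variance
   explained, 1 − WSS/TSS.
4. **MVPA bouts.** Weekly MVPA minutes under 1-, 5- and 10-minute criteria
   (the 10-minute rule bridges interruptions of ≤ 2 minutes), plus mean
   daily steps.
5. **Curves.** Per-cluster mean diel curves, loess-smoothed (span 0.1,
   tricube-weighted local linear fits), used to attach interpretable names
   ("morning", "afternoon", "unengaged"; "noon_peak", "evening_peak",
   "morning_and_evening_peak").
6. **Comparison.** One-way ANOVA (continuous) or Pearson chi-square
   (categorical) across clusters, with unadjusted pairwise Welch t-tests /
   2-group chi-squares only when the omnibus test is significant.

## Worked example

```python
from acticlust import (
    default_trial_config, generate_cohort, filter_valid_participants,
    raw_feature_matrix, elbow_scan, name_clusters, smooth_cluster_curves,
)

cohort, planted = generate_cohort(default_trial_config(), seed=42)
cohort, _ = filter_valid_participants(cohort)
features = raw_feature_matrix(cohort)           # 215 x 10080
scan = elbow_scan(features, k_max=4, restarts=25, seed=42)
print("WSS by k:", [round(w) for w in scan.wss_by_k])
print("elbow chooses k =", scan.chosen_k)
result = scan.results[scan.chosen_k - 1]
print("cluster sizes:", result.cluster_sizes().tolist())
curves = smooth_cluster_curves(features, result.labels)
print(name_clusters(result, curves, "raw"))
```

prints

```
WSS by k: [529099, 449227, 397297, 392072]
elbow chooses k = 3
cluster sizes: [48, 102, 65]
{0: 'morning', 1: 'unengaged', 2: 'afternoon'}
```

The WSS sequence drops by 15% and 12% up to k = 3 and then by only 1.3%, so
the elbow stops at three clusters; they recover the three planted archetypes
exactly (48 morning-engaged, 65 afternoon-engaged, 102 unengaged
participants), and the names come from each cluster's smoothed diel curve —
the lowest-activity curve is "unengaged", the others are labelled by whether
they peak before or after noon. The `examples/` directory has one short
script per capability (simulation, features, clustering, bouts, curves,
comparison); each prints its numbers with a note on what they mean.

A CLI wraps the same stages:

```sh
acticlust all --simulate --seed 42 --k 3 --out run/
acticlust simulate --seed 1 --out cohort.csv
acticlust cluster --features features.csv --k 3 --seed 1 --out labels.csv
```

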