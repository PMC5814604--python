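"""Build the two feature representations used for clustering.

Raw features: each participant's imputed week of minute METs (10,080 values).
Normalized MVPA features: minutes >= 3 METs, averaged over the 7 days into a
1440-minute typical-day frequency profile, scaled to unit Euclidean norm so
only the *timing* of activity distinguishes participants.
"""

import numpy as np

from acticlust import (
    default_trial_config, generate_cohort, filter_valid_participants,
    raw_feature_matrix, normalized_feature_matrix,
)

cohort, _ = generate_cohort(default_trial_config(), seed=42)
cohort, _ = filter_valid_participants(cohort)

raw = raw_feature_matrix(cohort)
print(f"raw feature matrix: {raw.n} x {raw.p}")          # 215 x 10080
print("minimum raw MET value:", raw.values.min())        # >= 0, no NaN after imputation

norm, degenerate = normalized_feature_matrix(cohort)
print(f"normalized MVPA matrix: {norm.n} x {norm.p}")    # 215 x 1440
norms = np.linalg.norm(norm.values, axis=1)
print("row norms all 1:", np.allclose(norms, 1.0, atol=1e-12))
print("participants with zero MVPA (excluded):", degenerate)
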