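# Methods

This note records the models, conventions and numerical choices behind
`acticlust`, and what the synthetic cohorts do and do not establish.

## Data model and wear convention

A participant's record is a 7 × 1440 grid of minute-level MET values.
Internal time is 0-based with minute 0 at local midnight; the day boundary is
midnight because minute-epoch devices of this class reset their daily buffer
there. A minute counts as *worn* exactly when a MET value was recorded for
it: no inference-based non-wear algorithm (Choi, Troiano) is applied, since
the measurement regime being modelled records only while the device is worn.
Consequences: the validity filter (every one of 7 days with ≥ 480 recorded
minutes; boundary inclusive) operates on recorded minutes only, and step
counts never affect validity.

Missing minutes are imputed to 1.0 MET — the stationary reading — only where
a complete vector is required (the raw feature matrix). The MVPA binarization
maps missing minutes to 0 directly; because 1.0 < 3.0 this is identical to
imputing first, and the code asserts that equivalence in tests.

## Feature constructions

*Raw*: rows are the imputed 10,080-minute MET vectors, ordered by sorted
participant id. No standardization is applied before clustering; all
coordinates are already METs on a common scale, and centring or z-scoring
would distort the overnight-imputation structure that distinguishes
day-active from night-active patterns.

*Normalized MVPA*: threshold at 3 METs (inclusive — moderate activity starts
at 3), average the 7 days minute-of-day-wise (entries in {0, 1/7, …, 1}),
then scale each profile to unit Euclidean norm. The normalization makes the
representation scale-free in activity volume: two participants active at the
same times of day but on different numbers of days map to the same unit
vector. A participant with no MVPA at all has a zero profile, which has no
direction; such rows are *degenerate* and are excluded with a report by
default (`keep_zero` retains them as zero rows). Excluding is the default
because a zero row would otherwise sit at an arbitrary centroid and its
cluster assignment would be meaningless.

## Bout criteria

Weekly MVPA is totalled three ways, always within days (bouts never span
midnight, matching the device's daily reset):

- **1-minute**: every MVPA minute counts.
- **5-minute**: minutes inside maximal runs of ≥ 5 consecutive MVPA minutes.
- **10-minute with interruption allowance**: maximal runs of ≤ 2 sub-threshold
  minutes lying strictly between MVPA minutes are bridged; each maximal
  bridged segment spanning ≥ 10 minutes is a bout, contributing its MVPA
  minutes only (bridged gap minutes are not counted).

This bridged-gap reading is the simplest formalization of "a 1 or 2 minute
interruption is allowed"; a sliding-window alternative (≥ 8 active of any 10)
is provided as `sliding_window_mvpa_minutes` but is not the default. Two
deliberate consequences: edge gaps are never bridged (an interruption must be
*between* activity), and the 10-minute total is not bounded by the 5-minute
total — a 4-minute fragment, a 2-minute gap and a 7-minute fragment form one
13-minute bout with 11 counted minutes, while the 5-minute criterion counts
only 7. Both criteria are verified against an independent regex/string oracle
exhaustively over all 2^16 short days and on random day-length strings.

Mean daily steps divides the weekly step total by exactly 7 (not by observed
days): retained participants have 7 valid days, and unworn minutes contribute
zero steps by construction.

## Clustering

Plain Lloyd k-means under squared Euclidean distance: initial centroids are k
distinct data rows sampled uniformly (k-means++ is available but not the
default, which deliberately matches the classical algorithm), then
assign/recompute-means iterations to an assignment fixed point (default
`tol=0`; a relative-WSS early exit is available). Empty clusters are repaired
by seizing the point farthest from its current centroid from a cluster that
keeps at least one member. The algorithm is restarted 25 times from
independent substreams of one seed (`numpy.random.SeedSequence.spawn`), the
restart with minimal within-group sum of squares wins, and ties break toward
the lowest restart index, making results reproducible bit-for-bit. Per-
iteration WSS history of the winning restart is kept so the Lloyd
monotonicity property can be asserted. Fit quality is summarized as variance
explained, 1 − WSS/TSS. Correctness is checked three ways: exhaustive
partition enumeration on small datasets, agreement of best WSS with
scikit-learn's `KMeans` on separated blobs, and parameter recovery on
synthetic cohorts.

The cluster count comes from the elbow rule: scan k = 1..k_max with the same
restart budget and choose the smallest k for which the relative WSS reduction
(WSS_k − WSS_{k+1})/WSS_k falls below a threshold. The threshold quantifies
"no longer reduces WSS meaningfully"; 0.10 is the default, and the full scan
is always returned so the decision is auditable. Note the rule is a
*relative* one: on very low-dimensional data, splitting even an isotropic
Gaussian cluster removes a large WSS fraction (≈ 64%/d in d dimensions), so
the rule is most informative in the high-dimensional regimes this package
targets (p = 1440 or 10,080), where splitting noise buys only ~1–2%.

Cluster naming is post hoc and purely descriptive, computed from the
loess-smoothed diel curves: for raw features the lowest-mean curve is
"unengaged" and the rest are "morning"/"afternoon" by peak position relative
to noon; for normalized features a curve with two prominent local maxima
(≥ 10% relative prominence, via `scipy.signal.find_peaks`) at least 6 h apart
is "morning_and_evening_peak", otherwise the global peak's position decides
"morning_peak" (< 10:00), "noon_peak" (10:00–14:00) or "evening_peak"
(≥ 14:00). The "morning_peak" label is an extension for single early peaks,
which the three canonical names do not cover; duplicate names get a
deterministic numeric suffix.

## Smoothing

Per-cluster curves are the member means on the 1440-minute day; raw-feature
rows are folded over the 7 day-blocks *before* smoothing so both feature
kinds share the same axis (day-fold-then-smooth, one smoothing pass on 1440
points). Loess is the classical first-order variant: at each minute a
weighted linear regression over the nearest ⌈span·n⌉ neighbours with tricube
weights, evaluated at that minute; no robustness iterations; the day is
non-circular (no midnight wraparound). The implementation is
`statsmodels`' lowess with `it=0`, with the fraction adjusted so its window
equals the ceiling convention. Degree-1 exactness (constants and lines
reproduced to 1e-9 everywhere, including boundaries) and shift equivariance
are asserted in tests. Default span 0.1 ≙ a 144-minute local window.

## Group comparison

Continuous covariates: one-way ANOVA F-test across clusters. Categorical:
Pearson chi-square on the cluster × level table, without continuity
correction by default (Yates available, and applied only to 2×2 when
enabled); all-zero levels are dropped with a warning. Pairwise contrasts are
computed only when the omnibus p < α (default 0.05): Welch t-tests for
continuous variables — chosen over pooled t for robustness to unequal
cluster sizes and variances, with pooled available via `t_variant` — and
2-group chi-squares for categorical ones. Pairwise p-values are unadjusted by
default (a Holm option exists) because the summary-table convention being
reproduced reports raw pairwise p-values. Degenerate inputs are flagged, not
raised: zero within-group variance yields p = NA with an empty pairwise list.
Type-I calibration of the omnibus tests (rejection at 5% ± 2% under the
null) is verified by simulation in the test suite.

## Synthetic cohorts

The generator plants temporal archetypes: per participant, a personal
baseline ~ N(baseline_mean, baseline_sd) truncated at 0.5 METs; per day, each
archetype window adds a Gaussian bump (peak minute, SD width, peak METs) with
the peak jittered by N(0, day_jitter_sd) and clipped into the wear window;
per minute, N(0, noise_sd) noise, truncation at 0; minutes outside
[wake, bed) stored missing. Steps are Poisson with rate proportional to METs
above 1. Covariates (age, BMI, CES-D depression score, education) are drawn
from plausible marginal distributions with per-archetype mean/probability
shifts taken from config — by default the unengaged archetype gets a +4
CES-D shift so comparison tests have real signal to find. Archetype
membership uses exact largest-remainder allocation of the configured
proportions followed by a seeded shuffle, so planted group sizes are
deterministic.

`default_trial_config()` is the reference condition: n = 215, wake 07:00 /
bed 23:00 (960 observed minutes per day, comfortably past the 8-hour rule),
noise SD 0.30, and three archetypes at 65/48/102 — afternoon-engaged (bumps
near 14:30–15:50), morning-engaged (bumps near 08:50–10:10), and unengaged,
whose two small windows carry a 220-minute peak-time jitter so its modest
activity lands somewhere different every day and its average profile is
flat. Window amplitudes were calibrated once so mean weekly
1-minute-criterion MVPA per archetype lands near 372 / 401 / 206 minutes,
the magnitudes characteristic of engaged-vs-unengaged midlife cohorts; the
noise and jitter defaults were likewise fixed once so the archetypes are
well separated in the raw feature space (elbow reductions ≈ 15% and 11%
into k = 3, then ≈ 1%). `mvpa_trial_config()` provides the timing-archetype
counterpart (morning+evening / noon / evening peaks at 46/61/108) for the
normalized pathway, where clusters differ in when MVPA happens rather than
how much.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: daytime non-wear and irregular wake/bed
times; within-bout autocorrelation of intensity (real MVPA is burstier, so
real 5/10-minute bout totals are far below the 1-minute total, while
synthetic bouts are contiguous and retain most minutes); weekday/weekend
structure; device quantization and step-count biomechanics. Recovery results
(ARI ≥ 0.9, elbow choosing k = 3) demonstrate correctness of the pipeline
under planted structure, not that real cohorts contain three clusters.

## Problem sizes and reproducibility

Every stochastic component takes an explicit seed, and all internal streams
derive from it deterministically; identical config + seed reproduces
byte-identical pipeline artifacts (asserted in tests, including a
manifest-replay round trip). The verification suites use: exhaustive
enumeration for bout criteria up to length-16 days plus 500 random
day-length strings; 100 small datasets for the k-means global-optimality
check; 10 generator seeds for clustering recovery and 20 for elbow
selection; 1000 simulations for normalization fuzz and for type-I
calibration. These sizes give the properties sharp operating
characteristics while keeping the full suite to a few minutes on one core.

## Known limitations

- The elbow threshold (10%) is a quantification the method's verbal
  definition leaves open; different thresholds can change the chosen k on
  weakly separated data. The scan is always emitted for inspection.
- Loess is O(n·w) per curve via statsmodels; for the 1440-point day this is
  instant, but the package never smooths the unfolded 10,080-point week.
- The 10-minute bout rule's treatment of interruptions differs across
  vendors' software; only the bridged-gap and sliding-window readings are
  implemented.
- `cluster_summary_table` formats to one decimal place, which is a
  reporting convention, not a precision claim.
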