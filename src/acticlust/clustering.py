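"""Lloyd k-means with random restarts, elbow selection, and cluster naming.

The clustering follows the classical Lloyd iteration: initialize centroids by
sampling k distinct data rows uniformly at random, then alternate
assign-to-nearest (squared Euclidean) and recompute-means until the assignment
reaches a fixed point. The algorithm is restarted (default 25 times) from
independent random initializations and the restart with the smallest
within-group sum of squares (WSS) wins; accuracy is reported as the fraction
of total variance explained, 1 - WSS/TSS.

The number of clusters is chosen by the elbow rule: the smallest k for which
adding one more cluster no longer reduces WSS by at least a threshold fraction
(default 10%). The full scan is always returned so the choice is auditable.

Features enter the distance as-is (no standardization): raw MET vectors and
unit-norm MVPA profiles are already on a common scale across coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import RAW, FeatureMatrix


def _values(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.values
    return np.asarray(features, dtype=float)


@dataclass
class ClusteringResult:
    labels: np.ndarray                 # (n,) cluster index in [0, k)
    centroids: np.ndarray              # (k, p)
    wss: float                         # within-group sum of squares (best restart)
    tss: float                         # total SS about the grand mean
    restarts: int
    seed: int | None
    per_restart_wss: np.ndarray        # (restarts,)
    best_restart: int
    n_iter: int
    wss_history: list = field(default_factory=list)  # per-iteration WSS, best restart

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def variance_explained(self) -> float:
        """Fraction of total variance explained by the centroids, 1 - WSS/TSS."""
        if self.tss == 0:
            return 1.0
        return 1.0 - self.wss / self.tss

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass
class ElbowScan:
    k_values: np.ndarray
    wss_by_k: np.ndarray
    chosen_k: int
    threshold: float
    results: list[ClusteringResult] = field(default_factory=list)


def _sq_dists(x: np.ndarray, c: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, (n, k); clipped at 0 against fp cancellation."""
    d = x2[:, None] - 2.0 * (x @ c.T) + (c * c).sum(axis=1)[None, :]
    return np.maximum(d, 0.0)


def _wss_of(x: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    diff = x - centroids[labels]
    return float((diff * diff).sum())


def _single_lloyd(
    x: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    init: str,
) -> tuple[np.ndarray, np.ndarray, float, int, list]:
    n = x.shape[0]
    x2 = (x * x).sum(axis=1)
    if init == "uniform":
        centroids = x[rng.choice(n, size=k, replace=False)].copy()
    elif init == "k-means++":
        centroids = _kmeanspp_init(x, k, rng, x2)
    else:
        raise ValueError(f"unknown init {init!r}")
    labels = np.full(n, -1)
    history: list[float] = []
    prev_wss = np.inf
    for it in range(1, max_iter + 1):
        d = _sq_dists(x, centroids, x2)
        new_labels = d.argmin(axis=1)
        # repair empty clusters: seize the point currently farthest from its centroid
        counts = np.bincount(new_labels, minlength=k)
        for c in np.flatnonzero(counts == 0):
            assigned_d = d[np.arange(n), new_labels]
            # only steal from clusters that keep at least one member
            stealable = counts[new_labels] > 1
            cand = np.flatnonzero(stealable)
            far = cand[assigned_d[cand].argmax()]
            counts[new_labels[far]] -= 1
            new_labels[far] = c
            counts[c] += 1
        for c in range(k):
            centroids[c] = x[new_labels == c].mean(axis=0)
        wss = _wss_of(x, new_labels, centroids)
        history.append(wss)
        converged = np.array_equal(new_labels, labels)
        labels = new_labels
        if converged:
            break
        if np.isfinite(prev_wss) and prev_wss > 0 and (prev_wss - wss) / prev_wss < tol:
            break
        prev_wss = wss
    return labels, centroids, wss, it, history


def _kmeanspp_init(
    x: np.ndarray, k: int, rng: np.random.Generator, x2: np.ndarray
) -> np.ndarray:
    n = x.shape[0]
    centroids = np.empty((k, x.shape[1]))
    centroids[0] = x[rng.integers(n)]
    closest = _sq_dists(x, centroids[:1], x2)[:, 0]
    for j in range(1, k):
        probs = closest / closest.sum() if closest.sum() > 0 else np.full(n, 1.0 / n)
        centroids[j] = x[rng.choice(n, p=probs)]
        closest = np.minimum(closest, _sq_dists(x, centroids[j:j + 1], x2)[:, 0])
    return centroids


def lloyd_kmeans(
    features,
    k: int,
    restarts: int = 25,
    seed: int | None = None,
    max_iter: int = 300,
    tol: float = 0.0,
    init: str = "uniform",
) -> ClusteringResult:
    """Best-of-``restarts`` Lloyd k-means under squared Euclidean distance.

    Each restart draws k distinct rows as initial centroids from its own
    deterministic substream of ``seed``; ties between restarts break toward
    the lowest restart index. ``tol`` > 0 allows early exit when the relative
    WSS improvement falls below it (0 runs to the assignment fixed point).
    """
    x = _values(features)
    n = x.shape[0]
    if k <= 0:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of observations n={n}")
    if np.isnan(x).any():
        raise ValueError("features contain missing values")
    streams = np.random.SeedSequence(seed).spawn(restarts)
    best = None
    per_restart = np.empty(restarts)
    for r in range(restarts):
        rng = np.random.default_rng(streams[r])
        labels, centroids, wss, n_iter, history = _single_lloyd(
            x, k, rng, max_iter, tol, init
        )
        per_restart[r] = wss
        if best is None or wss < best[2]:
            best = (labels, centroids, wss, r, n_iter, history)
    labels, centroids, wss, r, n_iter, history = best
    grand = x.mean(axis=0)
    tss = float(((x - grand) ** 2).sum())
    return ClusteringResult(
        labels=labels,
        centroids=centroids,
        wss=wss,
        tss=tss,
        restarts=restarts,
        seed=seed,
        per_restart_wss=per_restart,
        best_restart=r,
        n_iter=n_iter,
        wss_history=history,
    )


def elbow_scan(
    features,
    k_max: int,
    restarts: int = 25,
    seed: int | None = None,
    threshold: float = 0.10,
    **kmeans_kwargs,
) -> ElbowScan:
    """Run k-means for k = 1..k_max and pick k by relative WSS reduction.

    ``chosen_k`` is the smallest k with (WSS_k - WSS_{k+1}) / WSS_k below
    ``threshold`` — i.e. the first k after which one more cluster no longer
    buys a meaningful reduction — or k_max if every step keeps paying off.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    results = [
        lloyd_kmeans(features, k, restarts=restarts, seed=seed, **kmeans_kwargs)
        for k in range(1, k_max + 1)
    ]
    wss_by_k = np.array([r.wss for r in results])
    chosen = choose_elbow_k(wss_by_k, threshold)
    return ElbowScan(
        k_values=np.arange(1, k_max + 1),
        wss_by_k=wss_by_k,
        chosen_k=chosen,
        threshold=threshold,
        results=results,
    )


def choose_elbow_k(wss_by_k, threshold: float = 0.10) -> int:
    """Smallest k whose next cluster cuts WSS by less than ``threshold``.

    ``wss_by_k[i]`` is the WSS at k = i + 1. Returns the largest scanned k
    when every step still reduces WSS by at least the threshold fraction.
    """
    wss_by_k = np.asarray(wss_by_k, dtype=float)
    k_max = len(wss_by_k)
    for k in range(1, k_max):
        w_k, w_next = wss_by_k[k - 1], wss_by_k[k]
        if w_k <= 0 or (w_k - w_next) / w_k < threshold:
            return k
    return k_max


NOON_MINUTE = 720


def _local_maxima(curve: np.ndarray, rel_prominence: float = 0.1) -> np.ndarray:
    """Indices of meaningful local maxima, most prominent first."""
    from scipy.signal import find_peaks

    span = float(curve.max() - curve.min())
    if span == 0:
        return np.array([], dtype=int)
    peaks, props = find_peaks(curve, prominence=rel_prominence * span)
    order = np.argsort(props["prominences"])[::-1]
    return peaks[order]


def name_clusters(result: ClusteringResult, curves, kind: str) -> dict[int, str]:
    """Attach interpretable names to clusters from their smoothed diel curves.

    raw kind: the cluster with the lowest time-averaged smoothed METs is
    "unengaged"; the rest are "morning"/"afternoon" by whether the smoothed
    curve peaks before or after noon (minute 720).

    normalized kind: a curve with two prominent local maxima >= 6 h apart is
    "morning_and_evening_peak"; otherwise it is named by its global peak —
    "morning_peak" (< minute 600), "noon_peak" ([600, 840)), or
    "evening_peak" (>= 840). Ties and duplicates resolve by cluster index
    (duplicate names get a numeric suffix).
    """
    names: dict[int, str] = {}
    cluster_ids = sorted(curves.curves)
    if kind == RAW:
        means = {c: float(curves.curves[c].mean()) for c in cluster_ids}
        unengaged = min(cluster_ids, key=lambda c: (means[c], c))
        for c in cluster_ids:
            if c == unengaged:
                names[c] = "unengaged"
            else:
                peak = int(np.argmax(curves.curves[c]))
                names[c] = "morning" if peak < NOON_MINUTE else "afternoon"
    else:
        for c in cluster_ids:
            curve = curves.curves[c]
            maxima = _local_maxima(curve)
            if len(maxima) >= 2 and abs(int(maxima[0]) - int(maxima[1])) >= 360:
                names[c] = "morning_and_evening_peak"
                continue
            peak = int(np.argmax(curve))
            if peak < 600:
                names[c] = "morning_peak"
            elif peak < 840:
                names[c] = "noon_peak"
            else:
                names[c] = "evening_peak"
    seen: dict[str, int] = {}
    for c in cluster_ids:
        base = names[c]
        seen[base] = seen.get(base, 0) + 1
        if seen[base] > 1:
            names[c] = f"{base}_{seen[base]}"
    return names
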