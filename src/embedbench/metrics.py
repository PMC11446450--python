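"""Embedding-quality metrics: distance preservation vs class/neighborhood preservation.

Two families of metrics are implemented from first principles:

* distance preservation — ``interclass_corr`` (correlation of pairwise
  class-centroid distances between the high-dimensional space and the 2D
  embedding) and ``intraclass_corr`` (correlation of per-class variances);
* neighborhood / class preservation — leave-one-out ``knn_accuracy``,
  ``knn_recall`` (overlap of kNN sets between the two spaces),
  ``silhouette``, and ``ami_max_hdbscan`` (maximum adjusted mutual
  information between ground-truth classes and HDBSCAN clusterings of the
  2D coordinates over a hyperparameter grid).

Nearest neighbors are exact (brute-force Euclidean); distance ties are
broken by ascending point index. Adjusted mutual information uses the
exact expected mutual information under the fixed-marginals permutation
model (hypergeometric sum over each contingency cell).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import pearsonr, spearmanr

logger = logging.getLogger(__name__)

METRIC_NAMES = (
    "interclass_corr",
    "intraclass_corr",
    "knn_accuracy",
    "knn_recall",
    "silhouette",
    "ami_max",
)

#: HDBSCAN hyperparameter sweep used by default for ``ami_max_hdbscan``.
DEFAULT_HDBSCAN_GRID = tuple(
    {"min_cluster_size": mcs, "min_samples": ms}
    for mcs in (5, 10, 25, 50, 100, 250)
    for ms in (5, 10)
)


class MetricError(ValueError):
    pass


@dataclass
class NeighborGraph:
    """Exact k-nearest-neighbor lists, ordered by non-decreasing distance."""

    k: int
    indices: np.ndarray  # (n, k) int
    space_tag: str = "2D"

    @property
    def n(self) -> int:
        return self.indices.shape[0]


@dataclass
class MetricValue:
    metric: str
    value: float
    method: str = ""
    run_index: int = 0
    baseline_hd: float | None = None
    details: dict = field(default_factory=dict)


def _as_matrix(points) -> np.ndarray:
    coords = getattr(points, "coords", None)
    if coords is not None:
        points = coords
    values = getattr(points, "values", None)
    if values is not None and not isinstance(points, np.ndarray):
        points = values
    x = np.asarray(points, dtype=float)
    if x.ndim != 2:
        raise MetricError("points must be a 2D array (n x d)")
    return x


def _labels_array(labels) -> np.ndarray:
    return np.asarray(labels)


def _sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances.

    Small problems use the numerically exact difference formulation; large
    high-dimensional blocks fall back to the BLAS Gram-matrix identity for
    speed (precision loss there is far below any metric's resolution).
    """
    if a.shape[0] * b.shape[0] * a.shape[1] <= 5 * 10**7:
        from scipy.spatial.distance import cdist

        return cdist(a, b, metric="sqeuclidean")
    aa = (a**2).sum(1)[:, None]
    bb = (b**2).sum(1)[None, :]
    d2 = aa + bb - 2.0 * (a @ b.T)
    np.maximum(d2, 0.0, out=d2)
    return d2


def knn_graph(points, k: int, space_tag: str = "2D", block: int = 2048) -> NeighborGraph:
    """Exact Euclidean k-nearest neighbors of every point among the others.

    Distance ties are broken by ascending point index (stable sort on exact
    distances); a point is never its own neighbor, but duplicate points at
    distance zero are valid neighbors.
    """
    x = _as_matrix(points)
    n = x.shape[0]
    if not 1 <= k < n:
        raise MetricError(f"need n > k >= 1 (n={n}, k={k})")
    out = np.empty((n, k), dtype=np.int64)
    for start in range(0, n, block):
        stop = min(start + block, n)
        d2 = _sq_dists(x[start:stop], x)
        d2[np.arange(stop - start), np.arange(start, stop)] = np.inf
        # stable argsort => equal distances keep ascending-index order
        order = np.argsort(d2, axis=1, kind="stable")
        out[start:stop] = order[:, :k]
    return NeighborGraph(k=k, indices=out, space_tag=space_tag)


def knn_accuracy(points, labels, k: int = 10, *, graph: NeighborGraph | None = None,
                 mode: str = "majority") -> MetricValue:
    """Leave-one-out kNN classification accuracy in the given space.

    Each point is assigned the majority label among its k nearest
    neighbors (vote ties resolved by the single nearest neighbor's label);
    the value is the fraction of points whose assigned label matches their
    own. ``mode="fraction"`` instead returns the mean fraction of
    same-label neighbors.
    """
    x = _as_matrix(points)
    y = _labels_array(labels)
    if len(y) != x.shape[0]:
        raise MetricError("labels length must match number of points")
    classes, y_codes = np.unique(y, return_inverse=True)
    if len(classes) == 1:
        logger.warning("knn_accuracy: single class, value trivially 1")
        return MetricValue(metric="knn_accuracy", value=1.0)
    counts = np.bincount(y_codes)
    if counts.min() < 2:
        raise MetricError("every class needs >= 2 members")
    g = graph if graph is not None else knn_graph(x, k)
    neigh_codes = y_codes[g.indices]
    if mode == "fraction":
        value = float((neigh_codes == y_codes[:, None]).mean())
        return MetricValue(metric="knn_accuracy", value=value, details={"mode": mode, "k": k})
    if mode != "majority":
        raise MetricError(f"unknown mode {mode!r}")
    n = x.shape[0]
    votes = np.zeros((n, len(classes)), dtype=np.int64)
    for j in range(g.k):
        np.add.at(votes, (np.arange(n), neigh_codes[:, j]), 1)
    top = votes.max(axis=1)
    predicted = votes.argmax(axis=1)
    tied = (votes == top[:, None]).sum(axis=1) > 1
    predicted[tied] = neigh_codes[tied, 0]  # nearest neighbor breaks vote ties
    value = float((predicted == y_codes).mean())
    return MetricValue(metric="knn_accuracy", value=value, details={"mode": mode, "k": k})


def knn_recall(hd, emb, k: int = 10, *, hd_graph: NeighborGraph | None = None,
               emb_graph: NeighborGraph | None = None) -> MetricValue:
    """Mean fraction of high-dimensional kNN retained among the 2D kNN."""
    a = _as_matrix(hd)
    b = _as_matrix(emb)
    if a.shape[0] != b.shape[0]:
        raise MetricError(f"row-count mismatch: hd has {a.shape[0]}, emb has {b.shape[0]}")
    ga = hd_graph if hd_graph is not None else knn_graph(a, k, space_tag="HD")
    gb = emb_graph if emb_graph is not None else knn_graph(b, k, space_tag="2D")
    if ga.k != gb.k:
        raise MetricError("graphs must use the same k")
    n, k = ga.indices.shape
    overlap = np.empty(n)
    for i in range(n):
        overlap[i] = len(np.intersect1d(ga.indices[i], gb.indices[i], assume_unique=True))
    return MetricValue(metric="knn_recall", value=float(overlap.mean() / k), details={"k": k})


def silhouette(points, labels) -> MetricValue:
    """Mean silhouette coefficient of the labeled points.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean distance to
    the other members of i's class and b(i) the smallest mean distance to
    any other class. Points in singleton classes get s = 0.
    """
    x = _as_matrix(points)
    y = _labels_array(labels)
    if len(y) != x.shape[0]:
        raise MetricError("labels length must match number of points")
    classes, y_codes = np.unique(y, return_inverse=True)
    c = len(classes)
    if c < 2:
        raise MetricError("silhouette undefined for a single class")
    counts = np.bincount(y_codes, minlength=c)
    n = x.shape[0]
    # per-point sum of distances to each class, blockwise
    class_sums = np.empty((n, c))
    for start in range(0, n, 2048):
        stop = min(start + 2048, n)
        d = np.sqrt(_sq_dists(x[start:stop], x))
        for j in range(c):
            class_sums[start:stop, j] = d[:, y_codes == j].sum(axis=1)
    own = y_codes
    s = np.zeros(n)
    nontrivial = counts[own] > 1
    a = np.where(nontrivial, class_sums[np.arange(n), own] / np.maximum(counts[own] - 1, 1), 0.0)
    mean_other = class_sums / counts[None, :]
    mean_other[np.arange(n), own] = np.inf
    b = mean_other.min(axis=1)
    denom = np.maximum(a, b)
    valid = nontrivial & (denom > 0)
    s[valid] = (b[valid] - a[valid]) / denom[valid]
    return MetricValue(metric="silhouette", value=float(s.mean()))


# ---------------------------------------------------------------------------
# Adjusted mutual information
# ---------------------------------------------------------------------------


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    _, ca = np.unique(a, return_inverse=True)
    _, cb = np.unique(b, return_inverse=True)
    table = np.zeros((ca.max() + 1, cb.max() + 1), dtype=np.int64)
    np.add.at(table, (ca, cb), 1)
    return table


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _mutual_information(table: np.ndarray) -> float:
    n = table.sum()
    ai = table.sum(axis=1)
    bj = table.sum(axis=0)
    nz = table > 0
    nij = table[nz].astype(float)
    outer = np.outer(ai, bj)[nz].astype(float)
    return float((nij / n * (np.log(nij * n) - np.log(outer))).sum())


def expected_mutual_information(table: np.ndarray) -> float:
    """Exact E[MI] under the fixed-marginals permutation model.

    For each cell (i, j) the count n_ij follows a hypergeometric
    distribution with parameters (n, a_i, b_j); the expectation sums
    (n_ij/n) log(n n_ij / (a_i b_j)) weighted by that distribution over all
    feasible n_ij.
    """
    ai = table.sum(axis=1).astype(np.int64)
    bj = table.sum(axis=0).astype(np.int64)
    n = int(table.sum())
    lg = gammaln(np.arange(n + 2))  # lg[x] = log((x-1)!)
    emi = 0.0
    for a in ai:
        for b in bj:
            lo = max(1, a + b - n)
            hi = min(a, b)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1)
            log_p = (
                lg[a + 1] + lg[b + 1] + lg[n - a + 1] + lg[n - b + 1]
                - lg[n + 1] - lg[nij + 1] - lg[a - nij + 1] - lg[b - nij + 1]
                - lg[n - a - b + nij + 1]
            )
            term = nij / n * (np.log(n * nij.astype(float)) - np.log(float(a) * b))
            emi += float((np.exp(log_p) * term).sum())
    return emi


def ami(labels_a, labels_b) -> float:
    """Adjusted mutual information between two partitions.

    AMI = (MI - E[MI]) / (mean(H_a, H_b) - E[MI]) with the exact
    permutation-model E[MI]. Identical partitions give 1; a zero
    denominator (e.g. one partition is a single cluster) gives 0.
    """
    a = _labels_array(labels_a)
    b = _labels_array(labels_b)
    if len(a) != len(b):
        raise MetricError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise MetricError("need n >= 2")
    table = _contingency(a, b)
    h_a = _entropy(table.sum(axis=1))
    h_b = _entropy(table.sum(axis=0))
    mi = _mutual_information(table)
    emi = expected_mutual_information(table)
    denom = 0.5 * (h_a + h_b) - emi
    if abs(denom) < 1e-15:
        return 0.0
    return float((mi - emi) / denom)


def ami_max_hdbscan(emb, labels, grid=None, *, noise_mode: str = "extra_cluster") -> MetricValue:
    """Maximum AMI between classes and HDBSCAN clusterings of the 2D coords.

    Runs HDBSCAN (scikit-learn implementation) for every hyperparameter
    setting in ``grid`` and returns the best AMI against the ground-truth
    labels. Noise points either form one dedicated extra cluster
    (``"extra_cluster"``, the default, penalizing embeddings HDBSCAN cannot
    cluster) or are excluded from both partitions (``"exclude"``).
    Per-entry values and the chosen entry are retained in ``details``.
    """
    from sklearn.cluster import HDBSCAN

    x = _as_matrix(emb)
    y = _labels_array(labels)
    grid = list(grid) if grid is not None else [dict(g) for g in DEFAULT_HDBSCAN_GRID]
    if not grid:
        raise MetricError("hyperparameter grid must be non-empty")
    per_entry = []
    for params in grid:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.filterwarnings("ignore", category=FutureWarning)
            clusters = HDBSCAN(**params).fit_predict(x)
        is_noise = clusters == -1
        if np.all(is_noise):
            logger.info("ami_max_hdbscan: all points noise for %s, AMI 0", params)
            per_entry.append({"params": params, "ami": 0.0, "n_clusters": 0})
            continue
        if noise_mode == "exclude":
            keep = ~is_noise
            value = ami(clusters[keep], y[keep]) if keep.sum() >= 2 else 0.0
        elif noise_mode == "extra_cluster":
            value = ami(clusters, y)  # noise label -1 acts as one extra cluster
        else:
            raise MetricError(f"unknown noise_mode {noise_mode!r}")
        per_entry.append(
            {
                "params": params,
                "ami": value,
                "n_clusters": int(len(np.unique(clusters[~is_noise]))),
            }
        )
    best = max(per_entry, key=lambda e: e["ami"])
    return MetricValue(
        metric="ami_max",
        value=float(best["ami"]),
        details={"per_entry": per_entry, "chosen": best["params"], "noise_mode": noise_mode},
    )


# ---------------------------------------------------------------------------
# Distance-preservation metrics
# ---------------------------------------------------------------------------


def _corr(u: np.ndarray, v: np.ndarray, flavor: str) -> float:
    if np.std(u) == 0 or np.std(v) == 0:
        return float("nan")  # undefined: zero variance in a distance vector
    if flavor == "pearson":
        return float(pearsonr(u, v)[0])
    if flavor == "spearman":
        return float(spearmanr(u, v)[0])
    raise MetricError(f"unknown correlation flavor {flavor!r}")


def _centroids_and_variances(x: np.ndarray, codes: np.ndarray, c: int):
    d = x.shape[1]
    centroids = np.zeros((c, d))
    variances = np.zeros(c)
    for j in range(c):
        member = x[codes == j]
        centroids[j] = member.mean(axis=0)
        variances[j] = ((member - centroids[j]) ** 2).sum(axis=1).mean()
    return centroids, variances


def interclass_corr(hd, emb, labels, flavor: str = "pearson") -> MetricValue:
    """Correlation of pairwise class-centroid distances between HD and 2D."""
    a = _as_matrix(hd)
    b = _as_matrix(emb)
    y = _labels_array(labels)
    classes, codes = np.unique(y, return_inverse=True)
    c = len(classes)
    if c < 3:
        raise MetricError("need >= 3 classes for a meaningful correlation")
    cen_a, _ = _centroids_and_variances(a, codes, c)
    cen_b, _ = _centroids_and_variances(b, codes, c)
    iu = np.triu_indices(c, k=1)
    dist_a = np.sqrt(_sq_dists(cen_a, cen_a))[iu]
    dist_b = np.sqrt(_sq_dists(cen_b, cen_b))[iu]
    return MetricValue(
        metric="interclass_corr", value=_corr(dist_a, dist_b, flavor), details={"flavor": flavor}
    )


def intraclass_corr(hd, emb, labels, flavor: str = "pearson") -> MetricValue:
    """Correlation of per-class variances between HD and 2D.

    A class's variance is the mean squared Euclidean distance of its
    members to the class centroid.
    """
    a = _as_matrix(hd)
    b = _as_matrix(emb)
    y = _labels_array(labels)
    classes, codes = np.unique(y, return_inverse=True)
    c = len(classes)
    if c < 3:
        raise MetricError("need >= 3 classes for a meaningful correlation")
    if np.bincount(codes).min() < 2:
        raise MetricError("every class needs >= 2 members")
    _, var_a = _centroids_and_variances(a, codes, c)
    _, var_b = _centroids_and_variances(b, codes, c)
    return MetricValue(
        metric="intraclass_corr", value=_corr(var_a, var_b, flavor), details={"flavor": flavor}
    )


def hd_baselines(hd, labels, k: int = 10, *, graph: NeighborGraph | None = None):
    """kNN accuracy and silhouette evaluated directly in the HD space."""
    acc = knn_accuracy(hd, labels, k=k, graph=graph)
    sil = silhouette(hd, labels)
    return acc.value, sil.value
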