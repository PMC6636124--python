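"""Resampling consensus clustering with CDF/delta-area model selection.

For each candidate cluster number k, repeatedly subsample 80% of the
samples, run k-means (squared-Euclidean, k-means++ with 10 restarts) on
the subsample, and record how often each sample pair lands in the same
cluster among the iterations where both were drawn.  The per-k consensus
matrix feeds three diagnostics: the empirical CDF of consensus values,
its area A(k), and the relative area change Δ(k); the chosen K is the
largest k whose every cluster holds at least 90% within-cluster
consensus and beyond which the CDF area no longer grows appreciably.

Final labels come from average-linkage hierarchical clustering of the
chosen consensus matrix (dissimilarity 1 - M), relabeled 1..K by
decreasing cluster size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

CDF_GRID = np.linspace(0.0, 1.0, 101)


def _child_seed(master: int, *key: int) -> int:
    """Stable per-(k, iteration) integer seed below 2**31."""
    ss = np.random.SeedSequence(master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def kmeans(data, k: int, seed: int = 0) -> np.ndarray:
    """Lloyd k-means, squared-Euclidean objective, k-means++ init with 10
    restarts (best objective kept), at most 300 iterations."""
    data = np.asarray(data, dtype=float)
    if k > len(np.unique(data, axis=0)):
        raise ValueError("k exceeds the number of distinct rows")
    model = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300,
                   random_state=seed)
    return model.fit_predict(data)


def consensus_matrices(data, k_range, n_iter: int = 100,
                       subsample_frac: float = 0.8,
                       seed: int = 0) -> dict[int, np.ndarray]:
    """Per-k consensus matrices M_k[i, j] = (# co-clustered) / (# co-sampled).

    `data` is samples x features.  Subsampling draws
    floor(subsample_frac * n) samples without replacement per iteration.
    Entries never co-sampled stay 0 (with a warning); the diagonal is 1.
    Child RNG streams are keyed by (k, iteration), so enlarging k_range
    leaves the other runs untouched.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if not 0.0 < subsample_frac <= 1.0:
        raise ValueError("subsample_frac must be in (0, 1]")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    n_sub = int(np.floor(subsample_frac * n))
    out: dict[int, np.ndarray] = {}
    for k in k_range:
        I = np.zeros((n, n))
        S = np.zeros((n, n))
        for it in range(n_iter):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(k, it)))
            idx = np.sort(rng.choice(n, size=n_sub, replace=False))
            labels = kmeans(data[idx], k, seed=_child_seed(seed, k, it, 1))
            co = (labels[:, None] == labels[None, :]).astype(float)
            S[np.ix_(idx, idx)] += 1.0
            I[np.ix_(idx, idx)] += co
        with np.errstate(invalid="ignore"):
            M = np.where(S > 0, I / np.where(S > 0, S, 1.0), 0.0)
        never = (S == 0) & ~np.eye(n, dtype=bool)
        if never.any():
            logger.warning("k=%d: %d sample pairs never co-sampled",
                           k, int(never.sum() // 2))
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2.0
        _check_consensus_matrix(M)
        out[int(k)] = M
    return out


def _check_consensus_matrix(M: np.ndarray) -> None:
    assert np.allclose(M, M.T), "consensus matrix not symmetric"
    assert np.allclose(np.diag(M), 1.0), "consensus diagonal not 1"
    assert M.min() >= 0.0 and M.max() <= 1.0 + 1e-12, "consensus outside [0,1]"


def consensus_cdf(M: np.ndarray, grid: np.ndarray = CDF_GRID) -> np.ndarray:
    """Empirical CDF of the upper-triangle consensus values on the grid."""
    vals = np.sort(M[np.triu_indices_from(M, k=1)])
    return np.searchsorted(vals, grid, side="right") / vals.size


def cdf_area(cdf: np.ndarray, grid: np.ndarray = CDF_GRID) -> float:
    """Histogram-formulation area under the CDF:
    A = sum_i (x_i - x_{i-1}) * CDF(x_i)."""
    return float(np.sum(np.diff(grid) * cdf[1:]))


def consensus_cdf_area(matrices: dict[int, np.ndarray],
                       grid: np.ndarray = CDF_GRID):
    """CDF per k, areas A(k), and relative area changes Δ(k).

    Δ(k_min) = A(k_min); Δ(k) = (A(k) - A(k-1)) / A(k-1) for larger k.
    Requires a contiguous k range.
    """
    ks = sorted(matrices)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("k range must be contiguous")
    cdfs = {k: consensus_cdf(matrices[k], grid) for k in ks}
    areas = {k: cdf_area(cdfs[k], grid) for k in ks}
    deltas = {}
    for i, k in enumerate(ks):
        if i == 0:
            deltas[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            deltas[k] = (areas[k] - prev) / prev if prev > 0 else np.inf
    return cdfs, areas, deltas


def cluster_consensus(M: np.ndarray, labels) -> dict[int, float]:
    """Mean within-cluster consensus over unordered sample pairs; a
    singleton cluster scores 1 by convention."""
    labels = np.asarray(labels)
    scores: dict[int, float] = {}
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            scores[int(c)] = 1.0
            continue
        sub = M[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        scores[int(c)] = float(sub[iu].mean())
    return scores


def final_assignments(M: np.ndarray, K: int) -> np.ndarray:
    """Cut the average-linkage tree of (1 - M) into K clusters; labels
    are 1..K by decreasing cluster size (ties to the smallest member
    index)."""
    if K < 2:
        raise ValueError("K must be >= 2")
    D = 1.0 - M
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=K, criterion="maxclust")
    sizes = {c: (raw == c).sum() for c in np.unique(raw)}
    first = {c: int(np.flatnonzero(raw == c)[0]) for c in np.unique(raw)}
    ordered = sorted(sizes, key=lambda c: (-sizes[c], first[c]))
    remap = {c: i + 1 for i, c in enumerate(ordered)}
    return np.array([remap[c] for c in raw])


def select_k(deltas: dict[int, float],
             cluster_scores: dict[int, dict[int, float]],
             min_consensus: float = 0.90,
             delta_tol: float = 0.05) -> tuple[int, dict]:
    """Choose K: among k whose every cluster consensus >= min_consensus,
    take the largest k such that Δ(k') < delta_tol for every larger k' in
    range (the CDF area has stopped growing beyond k).

    Fallbacks, recorded in the decision trace: no Δ-stable eligible k ->
    largest eligible k; no eligible k at all -> argmax of mean cluster
    consensus.  Ties break toward smaller k.
    """
    ks = sorted(cluster_scores)
    eligible = [k for k in ks
                if min(cluster_scores[k].values()) >= min_consensus]
    trace = {
        "k_range": ks,
        "deltas": {k: float(deltas[k]) for k in ks},
        "min_cluster_consensus": {
            k: float(min(cluster_scores[k].values())) for k in ks},
        "eligible": eligible,
        "min_consensus": min_consensus,
        "delta_tol": delta_tol,
        "warning": None,
    }
    if not eligible:
        means = {k: float(np.mean(list(cluster_scores[k].values())))
                 for k in ks}
        chosen = min(k for k in ks if means[k] == max(means.values()))
        trace["warning"] = "no k met the cluster-consensus threshold"
        trace["chosen_k"] = chosen
        logger.warning(trace["warning"])
        return chosen, trace
    stable = [k for k in eligible
              if all(deltas[k2] < delta_tol for k2 in ks if k2 > k)]
    trace["delta_stable_eligible"] = stable
    if stable:
        chosen = max(stable)
    else:
        chosen = max(eligible)
        trace["warning"] = ("no eligible k with stabilized CDF area; "
                            "using largest eligible k")
        logger.warning(trace["warning"])
    trace["chosen_k"] = chosen
    return chosen, trace


@dataclass
class ConsensusResult:
    """Everything produced by one consensus-clustering run."""

    k_range: list[int]
    matrices: dict[int, np.ndarray]
    cdfs: dict[int, np.ndarray]
    areas: dict[int, float]
    deltas: dict[int, float]
    cluster_scores: dict[int, dict[int, float]]
    chosen_k: int
    labels: np.ndarray                  # final labels, 1..K
    labels_per_k: dict[int, np.ndarray]
    trace: dict = field(default_factory=dict)
    sample_ids: list[str] | None = None

    def labels_series(self) -> pd.Series:
        index = self.sample_ids if self.sample_ids is not None else None
        return pd.Series(self.labels, index=index, name="cluster")


def run_consensus(data, k_range=range(2, 21), n_iter: int = 100,
                  subsample_frac: float = 0.8, min_consensus: float = 0.90,
                  delta_tol: float = 0.05, seed: int = 0,
                  sample_ids=None) -> ConsensusResult:
    """Full procedure: consensus matrices over k_range, CDF/area/Δ curves,
    per-k hierarchical labels and cluster-consensus scores, K selection,
    final labels.  Deterministic given the master seed."""
    k_range = list(k_range)
    matrices = consensus_matrices(data, k_range, n_iter=n_iter,
                                  subsample_frac=subsample_frac, seed=seed)
    cdfs, areas, deltas = consensus_cdf_area(matrices)
    labels_per_k = {k: final_assignments(matrices[k], k) for k in k_range}
    cluster_scores = {k: cluster_consensus(matrices[k], labels_per_k[k])
                      for k in k_range}
    chosen, trace = select_k(deltas, cluster_scores,
                             min_consensus=min_consensus, delta_tol=delta_tol)
    return ConsensusResult(k_range, matrices, cdfs, areas, deltas,
                           cluster_scores, chosen, labels_per_k[chosen],
                           labels_per_k, trace,
                           list(sample_ids) if sample_ids is not None else None)
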