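"""Entropy-based calling of cluster-specific hyper/hypomethylated CpGs.

A CpG whose mean methylation is flat across clusters carries maximal
Shannon entropy (log2 K bits) over the normalized cluster-mean profile;
a CpG methylated in essentially one cluster carries low entropy.  Since
entropy of the raw profile is only sensitive to cluster-specific
HYPERmethylation, the profile is also reflected (1 - mean) to catch
specific HYPOmethylation, and a probe's score is the smaller of the two
orientations.  The calling threshold is the lower ``q`` quantile
(default 0.001) of scores simulated under a null in which all K cluster
means share a common baseline perturbed by Normal(0, sd) noise with
sd = 0.04.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PROMOTER_FEATURES

logger = logging.getLogger(__name__)


def cluster_mean_matrix(m: pd.DataFrame, labels) -> pd.DataFrame:
    """Clusters x probes matrix of mean beta values.

    `m` is probes x samples; `labels` assigns each sample (column) to a
    cluster.  Raises on an empty cluster.
    """
    labels = pd.Series(np.asarray(labels), index=m.columns)
    groups = m.T.groupby(labels).mean()  # clusters x probes
    if (labels.value_counts() < 1).any():
        raise ValueError("empty cluster")
    groups.index.name = "cluster"
    return groups


def _entropy_bits(profile: np.ndarray) -> np.ndarray:
    """Shannon entropy (bits) of each row after normalizing to sum 1;
    all-zero rows get the maximum log2 K by convention (a flat profile)."""
    prof = np.atleast_2d(np.asarray(profile, dtype=float))
    K = prof.shape[1]
    total = prof.sum(axis=1, keepdims=True)
    zero = total[:, 0] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, prof / np.where(total > 0, total, 1.0), 0.0)
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    H = -plogp.sum(axis=1)
    H[zero] = np.log2(K)
    return H


def methylation_entropy(means) -> tuple[np.ndarray, np.ndarray]:
    """(H_raw, H_reflected) in bits for one or many cluster-mean profiles.

    H_raw is the entropy of the normalized means m_c / sum(m); the
    reflected entropy uses (1 - m_c) and is low for a profile that is
    UNmethylated in one cluster only.  Both lie in [0, log2 K].
    """
    means = np.atleast_2d(np.asarray(means, dtype=float))
    if means.min() < 0 or means.max() > 1:
        raise ValueError("cluster means must lie in [0, 1]")
    h_raw = _entropy_bits(means)
    h_ref = _entropy_bits(1.0 - means)
    if means.shape[0] == 1:
        return float(h_raw[0]), float(h_ref[0])
    return h_raw, h_ref


def null_entropy_threshold(mean_matrix: pd.DataFrame, sd: float = 0.04,
                           n_null: int = 10000, q: float = 0.001,
                           seed: int = 0) -> float:
    """Simulated-null calling threshold in bits.

    Each null probe takes a common baseline drawn from the empirical
    distribution of observed per-probe grand means, perturbed per cluster
    by independent Normal(0, sd) noise and clipped to [0.01, 0.99]; its
    score is min(H_raw, H_reflected).  The threshold is the q-th quantile
    of the null scores (default q = 0.001).  Deterministic given seed.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if n_null < 1000:
        raise ValueError("n_null must be >= 1000")
    K = mean_matrix.shape[0]
    grand = mean_matrix.mean(axis=0).to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    base = rng.choice(grand, size=n_null, replace=True)
    null_means = np.clip(base[:, None] + rng.normal(0.0, sd, size=(n_null, K)),
                         0.01, 0.99)
    h_raw, h_ref = methylation_entropy(null_means)
    scores = np.minimum(h_raw, h_ref)
    return float(np.quantile(scores, q))


def call_specific(mean_matrix: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Call cluster-specific probes: specific iff min(H_raw, H_reflected)
    is below the threshold.

    Direction is read off the profile's largest deviation from the
    cross-cluster median: 'hyper' when the maximal mean sticks out
    further above the median than the minimal mean drops below it
    (ties toward hyper), and the called cluster is then the argmax
    (hyper) or argmin (hypo) mean.  The winning (lower-entropy)
    orientation is reported alongside.  Returns a frame indexed by
    probe with columns entropy, cluster, direction, orientation,
    restricted to called probes.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    means = mean_matrix.to_numpy(dtype=float).T   # probes x clusters
    h_raw, h_ref = methylation_entropy(means)
    h_raw, h_ref = np.atleast_1d(h_raw), np.atleast_1d(h_ref)
    score = np.minimum(h_raw, h_ref)
    use_raw = h_raw <= h_ref
    med = np.median(means, axis=1)
    hyper = (means.max(axis=1) - med) >= (med - means.min(axis=1))
    cluster_ids = mean_matrix.index.to_numpy()
    arg_hyper = cluster_ids[np.argmax(means, axis=1)]
    arg_hypo = cluster_ids[np.argmin(means, axis=1)]
    called = score < threshold
    out = pd.DataFrame(
        {
            "entropy": score[called],
            "cluster": np.where(hyper, arg_hyper, arg_hypo)[called],
            "direction": np.where(hyper, "hyper", "hypo")[called],
            "orientation": np.where(use_raw, "raw", "reflected")[called],
        },
        index=pd.Index(mean_matrix.columns[called], name="probe"),
    )
    return out


@dataclass
class GeneAnnotation:
    genes: list[str]
    promoter_genes: list[str]
    n_probes_without_genes: int


def annotate_genes(calls: pd.DataFrame, manifest: pd.DataFrame) -> GeneAnnotation:
    """Union of manifest gene symbols over called probes, plus the subset
    annotated by promoter-class probes (TSS1500/TSS200/5'UTR/1stExon).

    A probe may contribute several genes, so genes can outnumber probes;
    probes with empty annotation contribute nothing and are counted.
    """
    absent = calls.index.difference(manifest.index)
    if len(absent) > 0:
        raise KeyError(f"called probe {absent[0]!r} absent from manifest")
    genes: set[str] = set()
    promoter: set[str] = set()
    n_empty = 0
    for probe in calls.index:
        cell = manifest.loc[probe, "genes"]
        symbols = [g for g in str(cell).split(";") if g] if cell else []
        if not symbols:
            n_empty += 1
            continue
        genes.update(symbols)
        if manifest.loc[probe, "feature"] in PROMOTER_FEATURES:
            promoter.update(symbols)
    return GeneAnnotation(sorted(genes), sorted(promoter), n_empty)


def find_specific_cpgs(m: pd.DataFrame, labels, sd: float = 0.04,
                       n_null: int = 10000, q: float = 0.001,
                       seed: int = 0):
    """Convenience wrapper: cluster means -> null threshold -> calls.
    Returns (calls, threshold, cluster_mean_matrix)."""
    means = cluster_mean_matrix(m, labels)
    threshold = null_entropy_threshold(means, sd=sd, n_null=n_null, q=q,
                                       seed=seed)
    calls = call_specific(means, threshold)
    return calls, threshold, means
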