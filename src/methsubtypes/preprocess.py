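"""Probe/sample filtering, KNN imputation, and the balanced cohort split.

Filtering follows the standard 450K hygiene rules: drop probes missing in
more than a fraction of samples (default 0.70, strict inequality), probes
flagged cross-reactive, probes on the sex chromosomes, and probes
overlapping SNPs.  Samples require strictly more than a minimum follow-up
(default 30 days).  Missing beta values are imputed by k-nearest-neighbor
averaging in probe space; the train/test split is re-randomized until the
two halves are balanced on survival and clinical covariates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics.pairwise import nan_euclidean_distances

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Per-reason probe removal counts plus the removed probe list."""

    removed: pd.DataFrame   # columns: probe, reason
    n_input: int
    n_kept: int

    @property
    def counts(self) -> dict[str, int]:
        if self.removed.empty:
            return {}
        return self.removed["reason"].value_counts().to_dict()


def filter_probes(m: pd.DataFrame, manifest: pd.DataFrame,
                  max_missing_frac: float = 0.70
                  ) -> tuple[pd.DataFrame, FilterReport]:
    """Remove high-missingness, cross-reactive, sex-chromosome and
    SNP-overlap probes; probe order is otherwise preserved.

    A removed probe is reported once, under the first rule it violates
    (missingness, cross-reactive, sex chromosome, SNP).
    """
    absent = m.index.difference(manifest.index)
    if len(absent) > 0:
        raise KeyError(f"probe {absent[0]!r} absent from manifest")
    man = manifest.loc[m.index]
    missing_frac = m.isna().mean(axis=1)
    chrom = man["chromosome"].astype(str).str.replace("^chr", "", regex=True)

    reasons = pd.Series("", index=m.index, dtype=object)
    rules = [
        ("missingness", missing_frac > max_missing_frac),
        ("cross_reactive", man["cross_reactive"].astype(bool)),
        ("sex_chromosome", chrom.isin(["X", "Y"])),
        ("snp_overlap", man["snp_overlap"].astype(bool)),
    ]
    for name, mask in rules:
        hit = mask & (reasons == "")
        reasons[hit] = name
    keep = reasons == ""
    removed = pd.DataFrame({"probe": m.index[~keep],
                            "reason": reasons[~keep].to_numpy()})
    report = FilterReport(removed.reset_index(drop=True), len(m),
                          int(keep.sum()))
    return m.loc[keep], report


def filter_samples(clinical: pd.DataFrame,
                   min_followup_days: float = 30.0) -> list[str]:
    """Samples with strictly more than `min_followup_days` of follow-up."""
    if clinical["followup_days"].isna().any():
        raise ValueError("followup_days missing for some samples")
    keep = clinical["followup_days"] > min_followup_days
    return list(clinical.index[keep])


def knn_impute(m: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Impute missing beta values from the k nearest probes.

    For a missing value (probe g, sample s) the imputed value is the
    unweighted mean, in sample s, of the k probes nearest to g by
    Euclidean distance over mutually observed samples, scaled by the
    fraction of shared samples (nan-Euclidean distance).  Falls back to
    the probe-wise mean when fewer than k donor probes carry a value in
    sample s.  Observed entries pass through bit-exactly.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = m.to_numpy(dtype=float, copy=True)
    isna = np.isnan(values)
    if not isna.any():
        return m.copy()
    if isna.all(axis=1).any():
        bad = m.index[isna.all(axis=1)][0]
        raise ValueError(f"probe {bad!r} has no observed values")

    dist = nan_euclidean_distances(values)
    np.fill_diagonal(dist, np.inf)
    probe_means = np.nanmean(values, axis=1)

    out = values.copy()
    for gi in np.flatnonzero(isna.any(axis=1)):
        order = np.argsort(dist[gi], kind="stable")
        for si in np.flatnonzero(isna[gi]):
            donors = order[~isna[order, si]][:k]
            donors = donors[np.isfinite(dist[gi, donors])]
            if len(donors) < k:
                logger.warning(
                    "probe %s sample %s: only %d donor probes (< k=%d); "
                    "falling back to probe mean",
                    m.index[gi], m.columns[si], len(donors), k)
                out[gi, si] = probe_means[gi]
            else:
                out[gi, si] = values[donors, si].mean()
    return pd.DataFrame(np.clip(out, 0.0, 1.0), index=m.index,
                        columns=m.columns)


@dataclass
class SplitReport:
    """Balance diagnostics of the accepted train/test split."""

    pvalues: dict[str, float]
    attempts: int
    passed: bool
    warnings: list[str] = field(default_factory=list)


_CATEGORICAL_BALANCE = {"event", "stage", "T", "N", "M", "grade", "sex"}


def _balance_pvalues(clinical: pd.DataFrame, train_ids, test_ids,
                     balance_vars) -> dict[str, float]:
    pvals: dict[str, float] = {}
    for var in balance_vars:
        a = clinical.loc[train_ids, var].dropna()
        b = clinical.loc[test_ids, var].dropna()
        if var in _CATEGORICAL_BALANCE:
            table = pd.crosstab(
                pd.concat([a, b]),
                np.concatenate([np.zeros(len(a)), np.ones(len(b))]))
            table = table.loc[(table.sum(axis=1) > 0), (table.sum(axis=0) > 0)]
            if table.shape[0] < 2 or table.shape[1] < 2:
                pvals[var] = 1.0
            else:
                pvals[var] = float(
                    stats.chi2_contingency(table.to_numpy(),
                                           correction=False)[1])
        else:
            pvals[var] = float(stats.ks_2samp(a, b).pvalue)
    return pvals


def stratified_split(clinical: pd.DataFrame, train_frac: float = 0.5,
                     balance_vars: tuple[str, ...] = ("age_years", "stage",
                                                      "followup_days", "event"),
                     seed: int = 0, max_attempts: int = 200,
                     p_threshold: float = 0.05
                     ) -> tuple[list[str], list[str], SplitReport]:
    """Random disjoint/exhaustive split, re-randomized until the two
    halves are balanced (chi-square p > 0.05 for categorical variables,
    two-sample Kolmogorov-Smirnov p > 0.05 for continuous ones).

    Returns the first passing split; if none passes within the attempt
    budget, the best-scoring split (largest minimum balance p) with a
    warning flag.  Deterministic given (inputs, seed).
    """
    unknown = [v for v in balance_vars if v not in clinical.columns]
    if unknown:
        raise KeyError(f"balance variables not in clinical table: {unknown}")
    ids = np.asarray(clinical.index)
    n_train = math.floor(train_frac * len(ids))
    rng = np.random.default_rng(seed)

    best = None  # (min p, train, test, pvals)
    for attempt in range(1, max_attempts + 1):
        perm = rng.permutation(len(ids))
        train_ids = list(ids[perm[:n_train]])
        test_ids = list(ids[perm[n_train:]])
        pvals = _balance_pvalues(clinical, train_ids, test_ids, balance_vars)
        score = min(pvals.values())
        if best is None or score > best[0]:
            best = (score, train_ids, test_ids, pvals)
        if score > p_threshold:
            return train_ids, test_ids, SplitReport(pvals, attempt, True)
    score, train_ids, test_ids, pvals = best
    msg = (f"no balanced split in {max_attempts} attempts; returning best "
           f"(min balance p = {score:.4g})")
    logger.warning(msg)
    return train_ids, test_ids, SplitReport(pvals, max_attempts, False, [msg])
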