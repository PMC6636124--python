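"""Gaussian naive Bayes subtype classifier over the specific CpGs.

The classifier models each cluster as a product of independent Gaussians
over the specific-CpG beta values (class priors = training frequencies,
per-class/per-feature means and variances with a hard variance floor).
It is evaluated by stratified tenfold cross-validation (pooled accuracy)
and the Hand-Till multiclass AUC (macro-average of all pairwise
conditional AUCs), then used to assign test-set samples to subtypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .survival import LogrankResult, characterize_clusters, logrank_test

logger = logging.getLogger(__name__)


@dataclass
class NBModel:
    """Per-class priors and per-feature Gaussian parameters."""

    classes: np.ndarray          # sorted class labels
    priors: np.ndarray           # class priors, sum to 1
    means: np.ndarray            # classes x features
    variances: np.ndarray        # classes x features, >= var_floor
    features: list[str]
    var_floor: float = 1e-6

    def to_dict(self) -> dict:
        return {
            "classes": self.classes.tolist(),
            "priors": self.priors.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "features": list(self.features),
            "var_floor": self.var_floor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NBModel":
        return cls(np.asarray(d["classes"]), np.asarray(d["priors"]),
                   np.asarray(d["means"]), np.asarray(d["variances"]),
                   list(d["features"]), float(d["var_floor"]))


def fit_nb(features: pd.DataFrame, labels, var_floor: float = 1e-6) -> NBModel:
    """Fit the Gaussian NB model.

    `features` is samples x specific-CpGs.  Priors are class
    frequencies; means/variances are per-class sample moments (ML, i.e.
    denominator n) with variances floored at `var_floor`.  Every class
    needs at least 2 samples.
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if (counts < 2).any():
        small = classes[counts < 2][0]
        raise ValueError(f"class {small!r} has fewer than 2 samples")
    priors = counts / counts.sum()
    means = np.vstack([X[y == c].mean(axis=0) for c in classes])
    variances = np.vstack([X[y == c].var(axis=0, ddof=0) for c in classes])
    variances = np.maximum(variances, var_floor)
    return NBModel(classes, priors, means, variances,
                   list(features.columns), var_floor)


def predict_nb(model: NBModel, features: pd.DataFrame
               ) -> tuple[np.ndarray, pd.DataFrame]:
    """Posterior class probabilities and argmax labels.

    log-posterior = log pi_c + sum_f log N(x_f; mu_cf, var_cf),
    normalized per sample by log-sum-exp; argmax ties go to the smaller
    class index.  Feature columns must match the model's feature list.
    """
    missing = [f for f in model.features if f not in features.columns]
    if missing:
        raise KeyError(f"missing features: {missing[:5]}"
                       + ("..." if len(missing) > 5 else ""))
    X = features[model.features].to_numpy(dtype=float)   # n x f
    mu = model.means[None, :, :]                         # 1 x c x f
    var = model.variances[None, :, :]
    x = X[:, None, :]
    log_like = -0.5 * (np.log(2.0 * np.pi * var) + (x - mu) ** 2 / var)
    log_post = np.log(model.priors)[None, :] + log_like.sum(axis=2)
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    post = np.exp(log_post)
    labels = model.classes[np.argmax(post, axis=1)]
    posterior = pd.DataFrame(post, index=features.index,
                             columns=list(model.classes))
    return labels, posterior


@dataclass
class CVResult:
    accuracy: float              # pooled over held-out folds
    fold_accuracy: list[float]   # per-fold accuracies
    folds: np.ndarray            # fold index per sample
    predictions: np.ndarray      # held-out prediction per sample
    posteriors: pd.DataFrame     # held-out posterior per sample


def stratified_folds(labels, n_folds: int = 10, seed: int = 0) -> np.ndarray:
    """Per-sample fold index, stratified by class.

    Each class's samples are shuffled and dealt round-robin across the
    folds, so a class smaller than n_folds is spread as evenly as
    possible (with a warning).  Deterministic given seed.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if (counts < n_folds).any():
        logger.warning(
            "classes %s smaller than n_folds=%d; folds will not contain "
            "every class", classes[counts < n_folds].tolist(), n_folds)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    for offset, c in enumerate(classes):
        idx = rng.permutation(np.flatnonzero(y == c))
        # stagger the starting fold per class so folds stay size-balanced
        folds[idx] = (np.arange(len(idx)) + offset) % n_folds
    return folds


def cross_validate(features: pd.DataFrame, labels, n_folds: int = 10,
                   seed: int = 0, var_floor: float = 1e-6) -> CVResult:
    """Stratified k-fold cross-validation (default tenfold): fit on k-1
    folds, predict the held-out fold, pool accuracy = correct / total.
    Training-fold classes left with fewer than 2 samples are dropped
    from that fold's fit with a warning.  Deterministic given seed.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    folds = stratified_folds(y, n_folds=n_folds, seed=seed)
    preds = np.empty(len(y), dtype=y.dtype)
    post = pd.DataFrame(0.0, index=features.index, columns=list(classes))
    fold_acc = []
    for i in range(n_folds):
        te = np.flatnonzero(folds == i)
        tr = np.flatnonzero(folds != i)
        if len(te) == 0:
            continue
        y_tr = y[tr]
        cls, cnt = np.unique(y_tr, return_counts=True)
        if (cnt < 2).any():
            logger.warning("fold %d: dropping training classes %s with < 2 "
                           "samples", i, cls[cnt < 2].tolist())
            keep = np.isin(y_tr, cls[cnt >= 2])
            tr = tr[keep]
            y_tr = y[tr]
        model = fit_nb(features.iloc[tr], y_tr, var_floor=var_floor)
        lab, pp = predict_nb(model, features.iloc[te])
        preds[te] = lab
        post.iloc[te, [post.columns.get_loc(c) for c in pp.columns]] = \
            pp.to_numpy()
        fold_acc.append(float((lab == y[te]).mean()))
    accuracy = float((preds == y).mean())
    return CVResult(accuracy, fold_acc, folds, preds, post)


def multiclass_auc(posteriors: pd.DataFrame, labels) -> float:
    """Hand-Till multiclass AUC.

    For every unordered class pair (i, j), the conditional AUC A(i|j) is
    the probability that the posterior for class i ranks a class-i
    sample above a class-j sample (ties count 0.5); the pair score is
    (A(i|j) + A(j|i)) / 2 and the overall AUC is the mean over pairs.
    Classes absent from the labels are skipped with a warning.
    """
    y = np.asarray(labels)
    present = [c for c in posteriors.columns if (y == c).any()]
    absent = [c for c in posteriors.columns if c not in present]
    if absent:
        logger.warning("classes %s absent from labels; pairs skipped", absent)
    if len(present) < 2:
        raise ValueError("need at least 2 classes present")
    pair_scores = []
    for a_i, ci in enumerate(present):
        for cj in present[a_i + 1:]:
            mask_i, mask_j = y == ci, y == cj
            a_ij = _pairwise_auc(posteriors[ci].to_numpy()[mask_i],
                                 posteriors[ci].to_numpy()[mask_j])
            a_ji = _pairwise_auc(posteriors[cj].to_numpy()[mask_j],
                                 posteriors[cj].to_numpy()[mask_i])
            pair_scores.append(0.5 * (a_ij + a_ji))
    return float(np.mean(pair_scores))


def _pairwise_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """P(score_pos > score_neg) with ties at 0.5 (Mann-Whitney)."""
    from scipy.stats import rankdata
    combined = np.concatenate([pos_scores, neg_scores])
    ranks = rankdata(combined)
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class TestAssignment:
    """Test-set subtype assignment and its survival consistency checks."""

    labels: pd.Series
    posteriors: pd.DataFrame
    test_logrank: LogrankResult
    test_curves: dict
    test_associations: pd.DataFrame
    cross_set_logrank: dict[int, LogrankResult] = field(default_factory=dict)
    skipped_clusters: list[int] = field(default_factory=list)


def assign_test_set(model: NBModel, test_features: pd.DataFrame,
                    test_clinical: pd.DataFrame,
                    train_clinical: pd.DataFrame | None = None,
                    train_labels=None) -> TestAssignment:
    """Assign test samples to subtypes and check prognostic consistency.

    Runs the survival characterization on the predicted test clusters
    (per-cluster KM, across-cluster log-rank, clinical associations) and,
    when the training cohort is supplied, a two-group train-vs-test
    log-rank within every cluster label present in both sets (clusters
    missing from one side are skipped with a note).
    """
    labels_arr, post = predict_nb(model, test_features)
    labels = pd.Series(labels_arr, index=test_features.index, name="cluster")
    clinical = test_clinical.loc[test_features.index]
    curves, lr, assoc = characterize_clusters(labels, clinical)

    cross: dict[int, LogrankResult] = {}
    skipped: list[int] = []
    if train_clinical is not None and train_labels is not None:
        train_labels = pd.Series(np.asarray(train_labels),
                                 index=train_clinical.index)
        for c in sorted(set(model.classes)):
            tr = train_clinical[train_labels == c]
            te = clinical[labels == c]
            if len(tr) == 0 or len(te) == 0:
                skipped.append(int(c))
                logger.info("cluster %s absent from one set; skipped", c)
                continue
            time = np.concatenate([tr["followup_days"], te["followup_days"]])
            event = np.concatenate([tr["event"], te["event"]])
            grp = np.concatenate([np.zeros(len(tr)), np.ones(len(te))])
            if event.sum() < 1:
                skipped.append(int(c))
                continue
            cross[int(c)] = logrank_test(time, event, grp)
    return TestAssignment(labels, post, lr, curves, assoc, cross, skipped)
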