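"""Survival curves and cluster-clinical association tests.

Kaplan-Meier product-limit curves per cluster, the K-sample log-rank
test across clusters, and Pearson chi-square association between cluster
labels and each clinical attribute (Table-1 style), with age
dichotomized at 60 years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class SurvivalCurve:
    """A Kaplan-Meier step function with its risk table."""

    times: np.ndarray       # distinct event times
    at_risk: np.ndarray     # n_i just before each event time
    events: np.ndarray      # d_i events at each time
    survival: np.ndarray    # S(t) just after each event time
    label: str = ""

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "at_risk": self.at_risk,
                             "events": self.events, "survival": self.survival})


def km_curve(time, event, label: str = "") -> SurvivalCurve:
    """Kaplan-Meier estimate S(t) = prod_{t_i <= t} (1 - d_i/n_i) over
    distinct event times; with no events, S is identically 1."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if (time < 0).any():
        raise ValueError("negative follow-up time")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[times, "KM_estimate"].to_numpy() \
        if len(times) else np.array([])
    return SurvivalCurve(times, ev["at_risk"].to_numpy(dtype=int),
                         ev["observed"].to_numpy(dtype=int), surv, label)


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p: float


def logrank_test(time, event, groups) -> LogrankResult:
    """K-sample log-rank test: chi-square statistic on K-1 degrees of
    freedom from the observed-minus-expected event counts per group."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if event.sum() < 1:
        raise ValueError("need at least one event")
    res = multivariate_logrank_test(time, groups, event)
    return LogrankResult(float(res.test_statistic), len(levels) - 1,
                         float(res.p_value))


@dataclass
class AssociationTest:
    attribute: str
    table: pd.DataFrame
    statistic: float
    df: int
    p: float


def chisq_association(labels, values, attribute: str = "") -> AssociationTest:
    """Pearson chi-square (no continuity correction) on the cluster x
    attribute contingency table; all-zero rows/columns are dropped with a
    warning before testing."""
    labels = pd.Series(np.asarray(labels), name="cluster")
    values = pd.Series(np.asarray(values), name=attribute or "attribute")
    keep = labels.notna() & values.notna()
    table = pd.crosstab(labels[keep], values[keep])
    nz = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if nz.shape != table.shape:
        logger.warning("%s: dropped all-zero rows/columns before chi-square",
                       attribute)
    if nz.shape[0] < 2 or nz.shape[1] < 2:
        raise ValueError(f"{attribute}: contingency table degenerate")
    stat, p, df, _ = stats.chi2_contingency(nz.to_numpy(), correction=False)
    return AssociationTest(attribute, nz, float(stat), int(df), float(p))


def dichotomize_age(age_years) -> np.ndarray:
    """Table-1 age split: 'young' strictly below 60, else 'old'
    (age exactly 60 is assigned to 'old')."""
    age = np.asarray(age_years, dtype=float)
    out = np.where(age < 60, "young", "old").astype(object)
    out[np.isnan(age)] = None
    return out


CLINICAL_ATTRIBUTES = ("T", "N", "M", "stage", "grade", "age_group", "sex")


def clinical_association_table(labels, clinical: pd.DataFrame) -> pd.DataFrame:
    """Chi-square association of cluster labels with every clinical
    attribute (T, N, M, stage, grade, dichotomized age, sex)."""
    rows = []
    for attr in CLINICAL_ATTRIBUTES:
        values = (dichotomize_age(clinical["age_years"])
                  if attr == "age_group" else clinical[attr].to_numpy())
        try:
            res = chisq_association(labels, values, attribute=attr)
            rows.append((attr, res.statistic, res.df, res.p))
        except ValueError as exc:
            logger.warning("skipping %s: %s", attr, exc)
            rows.append((attr, np.nan, 0, np.nan))
    return pd.DataFrame(rows, columns=["attribute", "statistic", "df", "p"]
                        ).set_index("attribute")


def characterize_clusters(labels, clinical: pd.DataFrame):
    """Per-cluster KM curves, the across-cluster log-rank test, and the
    cluster-clinical association table."""
    labels = pd.Series(np.asarray(labels), index=clinical.index,
                       name="cluster")
    curves = {}
    for c in sorted(labels.unique()):
        sub = clinical[labels == c]
        curves[int(c)] = km_curve(sub["followup_days"], sub["event"],
                                  label=f"cluster{c}")
    lr = logrank_test(clinical["followup_days"], clinical["event"], labels)
    assoc = clinical_association_table(labels, clinical)
    return curves, lr, assoc
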