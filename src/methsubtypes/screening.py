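"""Prognostic CpG screening with Cox proportional-hazards regression.

Two stages: a univariate Cox fit per CpG keeps probes whose methylation
term is significant at ``alpha`` (default 0.05); the survivors are
re-fitted with T, N, M, grade and stage as covariates (ordinals coded as
integer scores, one degree of freedom each) and the methylation-term
p-values are Benjamini-Hochberg adjusted, keeping q < ``q_cutoff``.

The partial likelihood is maximized by Newton-Raphson with step-halving
(so the log partial likelihood never decreases) and Efron's tie
correction; convergence when the largest Newton step falls below 1e-8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MULTIVARIATE_COVARIATES = ("T", "N", "M", "grade", "stage")


class ConvergenceError(RuntimeError):
    pass


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    pvalues: np.ndarray
    loglik: float
    converged: bool
    n: int
    n_events: int
    ties: str = "efron"

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "hazard_ratio": np.exp(self.coef),
             "se": self.se, "z": self.z, "p": self.pvalues},
            index=self.names)


def _loglik_grad_hess(beta, t, d_idx, event_groups, X, ties):
    """Log partial likelihood, score and (positive) information.

    `event_groups` is a list of (i0, D) pairs: D = sorted positions of
    the events tied at one event time, i0 = first position of the risk
    set (all subjects with time >= that event time).
    """
    n, p = X.shape
    xb = X @ beta
    xb = np.clip(xb, -500, 500)
    w = np.exp(xb)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    U = np.zeros(p)
    H = np.zeros((p, p))
    for i0, D in event_groups:
        d = len(D)
        S0R, S1R, S2R = S0[i0], S1[i0], S2[i0]
        if d == 1 or ties == "breslow":
            phi = np.zeros(d if ties == "breslow" else 1)
        else:
            phi = np.arange(d) / d
        if d == 1:
            phi = np.zeros(1)
        S0D = w[D].sum()
        S1D = wx[D].sum(axis=0)
        S2D = wxx[D].sum(axis=0)
        denom = S0R - phi * S0D
        ll += xb[D].sum() - np.log(denom).sum()
        m1 = (S1R[None, :] - phi[:, None] * S1D[None, :]) / denom[:, None]
        U += X[D].sum(axis=0) - m1.sum(axis=0)
        m2 = (S2R[None] - phi[:, None, None] * S2D[None]) / denom[:, None, None]
        H += (m2 - m1[:, :, None] * m1[:, None, :]).sum(axis=0)
    return ll, U, H


def _loglik_only(beta, t, d_idx, event_groups, X, ties):
    xb = np.clip(X @ beta, -500, 500)
    w = np.exp(xb)
    S0 = np.cumsum(w[::-1])[::-1]
    ll = 0.0
    for i0, D in event_groups:
        d = len(D)
        phi = np.arange(d) / d if (d > 1 and ties == "efron") else np.zeros(d)
        S0D = w[D].sum() if d > 1 else 0.0
        ll += xb[D].sum() - np.log(S0[i0] - phi * S0D).sum()
    return ll


def fit_cox(time, event, covariates, names=None, ties: str = "efron",
            tol: float = 1e-8, max_iter: int = 50) -> CoxFit:
    """Fit a Cox model by Newton-Raphson on the partial likelihood.

    Parameters
    ----------
    time, event : arrays of follow-up durations and 0/1 event flags.
    covariates : (n, p) design matrix (a 1-D array is treated as one
        column).
    ties : "efron" (default) or "breslow" tie handling; they coincide
        when all event times are distinct.

    Monotone-likelihood fits (perfect separation) are returned with
    ``converged=False``; constant covariate columns raise ``ValueError``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if event.sum() < 1:
        raise ValueError("need at least one event")
    if np.any(np.ptp(X, axis=0) == 0):
        j = int(np.flatnonzero(np.ptp(X, axis=0) == 0)[0])
        raise ValueError(f"constant covariate column {names[j]!r}")

    order = np.argsort(time, kind="stable")
    t, d, X = time[order], event[order], X[order]
    # center columns for numerical stability (does not change coef/ll shape)
    center = X.mean(axis=0)
    Xc = X - center

    d_idx = np.flatnonzero(d == 1)
    event_groups = []
    for tt in np.unique(t[d_idx]):
        D = d_idx[t[d_idx] == tt]
        i0 = int(np.searchsorted(t, tt, side="left"))
        event_groups.append((i0, D))

    beta = np.zeros(p)
    ll, U, H = _loglik_grad_hess(beta, t, d_idx, event_groups, Xc, ties)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(H, U)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, U, rcond=None)[0]
        # step-halving keeps the log partial likelihood non-decreasing
        scale = 1.0
        for _half in range(30):
            cand = beta + scale * step
            ll_new = _loglik_only(cand, t, d_idx, event_groups, Xc, ties)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll, U, H = _loglik_grad_hess(beta, t, d_idx, event_groups, Xc, ties)
        if np.max(np.abs(scale * step)) < tol:
            converged = True
            break
    if np.max(np.abs(beta)) > 50:
        converged = False  # monotone likelihood / separation

    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvalues = 2.0 * stats.norm.sf(np.abs(z))
    return CoxFit(list(names), beta, se, z, pvalues, float(ll), converged,
                  n, int(d.sum()), ties)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_i = min over j with p_(j) >= p_(i) of p_(j) * m / rank(j), clipped
    at 1; output order matches input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def _aligned(m: pd.DataFrame, clinical: pd.DataFrame):
    if not m.columns.equals(pd.Index(clinical.index)):
        common = [s for s in m.columns if s in clinical.index]
        if len(common) != m.shape[1]:
            raise ValueError("methylation and clinical samples not aligned")
        clinical = clinical.loc[common]
    return m, clinical


def univariate_screen(m: pd.DataFrame, clinical: pd.DataFrame,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Univariate Cox fit per probe; keeps probes with Wald p < alpha.

    Returns a frame indexed by probe with columns coef, p_uni,
    selected_uni, converged.  Probes must be imputed first (missing beta
    values violate the pipeline ordering and raise).
    """
    m, clinical = _aligned(m, clinical)
    if m.isna().any().any():
        raise ValueError("methylation matrix has missing values; impute first")
    time = clinical["followup_days"].to_numpy(float)
    event = clinical["event"].to_numpy(int)
    rows = []
    for probe, values in m.iterrows():
        x = values.to_numpy(float)
        try:
            fit = fit_cox(time, event, x, names=["methylation"])
            p = fit.pvalues[0] if fit.converged else np.nan
            rows.append((probe, fit.coef[0], p, fit.converged))
        except ValueError:
            rows.append((probe, np.nan, np.nan, False))
    out = pd.DataFrame(rows, columns=["probe", "coef", "p_uni", "converged"])
    out = out.set_index("probe")
    out["selected_uni"] = out["p_uni"] < alpha
    return out


def multivariate_screen(candidates, m: pd.DataFrame, clinical: pd.DataFrame,
                        q_cutoff: float = 0.05) -> pd.DataFrame:
    """Covariate-adjusted Cox fit per candidate probe with T, N, M, grade
    and stage as one-df ordinal covariates; BH-adjusts the methylation
    term across candidates and keeps q < q_cutoff.

    Samples with missing clinical covariates are dropped per fit and the
    n actually used is recorded.
    """
    candidates = list(candidates)
    missing = [c for c in candidates if c not in m.index]
    if missing:
        raise KeyError(f"candidate probe {missing[0]!r} not in matrix")
    m, clinical = _aligned(m, clinical)
    cov = clinical[list(MULTIVARIATE_COVARIATES)].apply(pd.to_numeric)
    ok = cov.notna().all(axis=1) & clinical["followup_days"].notna() \
        & clinical["event"].notna()
    if not ok.all():
        logger.warning("dropping %d samples with missing clinical covariates",
                       int((~ok).sum()))
    cov = cov[ok]
    time = clinical.loc[ok, "followup_days"].to_numpy(float)
    event = clinical.loc[ok, "event"].to_numpy(int)
    covmat = cov.to_numpy(float)
    names = ["methylation", *MULTIVARIATE_COVARIATES]

    rows = []
    for probe in candidates:
        x = m.loc[probe, cov.index].to_numpy(float)
        design = np.column_stack([x, covmat])
        try:
            fit = fit_cox(time, event, design, names=names)
            p = fit.pvalues[0] if fit.converged else np.nan
            rows.append((probe, fit.coef[0], p, fit.converged, fit.n))
        except ValueError:
            rows.append((probe, np.nan, np.nan, False, int(ok.sum())))
    out = pd.DataFrame(
        rows, columns=["probe", "coef_multi", "p_multi", "converged", "n_used"]
    ).set_index("probe")
    finite = out["p_multi"].notna()
    q = np.full(len(out), np.nan)
    if finite.any():
        q[finite.to_numpy()] = bh_fdr(out.loc[finite, "p_multi"].to_numpy())
    out["q"] = q
    out["selected"] = out["q"] < q_cutoff
    return out


def screen(m: pd.DataFrame, clinical: pd.DataFrame, alpha: float = 0.05,
           q_cutoff: float = 0.05) -> pd.DataFrame:
    """Full two-stage screen; returns one row per probe with columns
    p_uni, p_multi, q, selected (NaN p_multi/q for stage-1 rejects)."""
    uni = univariate_screen(m, clinical, alpha=alpha)
    cands = list(uni.index[uni["selected_uni"].fillna(False)])
    result = uni.copy()
    result["p_multi"] = np.nan
    result["q"] = np.nan
    result["selected"] = False
    if cands:
        multi = multivariate_screen(cands, m, clinical, q_cutoff=q_cutoff)
        result.loc[multi.index, ["p_multi", "q", "selected"]] = \
            multi[["p_multi", "q", "selected"]].to_numpy()
    result["selected"] = result["selected"].astype(bool)
    return result
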