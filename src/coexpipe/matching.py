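"""Propensity-score matching of controls to cases.

Logistic propensity model fitted by iteratively reweighted least squares,
then 1:1 greedy nearest-neighbor matching without replacement on the logit
scale within a caliper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["MatchResult", "propensity_scores", "nn_match", "standardized_mean_differences"]


@dataclass
class MatchResult:
    pairs: pd.DataFrame  # case, control, case_score, control_score, distance
    scores: pd.Series
    caliper: float
    unmatched_cases: list
    smd_before: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    smd_after: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def _irls_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                   max_iter: int = 100) -> tuple[np.ndarray, bool]:
    """IRLS fit of a logistic regression; returns (coefficients, separation flag)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = mu * (1.0 - mu)
        if w.max() < 1e-10:
            break
        wx = X * w[:, None]
        h = X.T @ wx + 1e-10 * np.eye(p)
        g = X.T @ (y - mu)
        step = np.linalg.solve(h, g)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    # separation: every fitted probability saturated on the correct side
    mu = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -30, 30)))
    separated = bool((mu[y == 1] > 1 - 1e-3).all() and (mu[y == 0] < 1e-3).all())
    return beta, separated


def propensity_scores(covariates: pd.DataFrame, labels) -> pd.Series:
    """Fitted case probabilities from a logistic model of case status.

    Covariates must be complete; missing values raise with the offending
    sample IDs.  Perfect separation is warned about, scores still returned.
    """
    y = np.asarray(labels).astype(float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be 0/1 (control/case)")
    miss = covariates.index[covariates.isna().any(axis=1)].tolist()
    if miss:
        raise ValueError(f"missing covariates for samples: {miss[:10]}")
    X = np.column_stack([np.ones(len(covariates)), covariates.to_numpy(dtype=float)])
    beta, separated = _irls_logistic(X, y)
    if separated:
        warnings.warn("propensity_scores: perfect separation suspected; "
                      "scores may be degenerate")
    eta = X @ beta
    scores = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    return pd.Series(scores, index=covariates.index, name="propensity")


def standardized_mean_differences(
    covariates: pd.DataFrame, case_ids, control_ids
) -> pd.Series:
    """Absolute SMD per covariate between two sample groups."""
    a = covariates.loc[list(case_ids)]
    b = covariates.loc[list(control_ids)]
    out = {}
    for col in covariates.columns:
        va, vb = a[col].var(ddof=1), b[col].var(ddof=1)
        pooled = np.sqrt((va + vb) / 2.0)
        diff = a[col].mean() - b[col].mean()
        out[col] = abs(diff) / pooled if pooled > 0 else 0.0
    return pd.Series(out, name="smd")


def nn_match(
    scores: pd.Series,
    labels,
    caliper: Optional[float] = None,
    covariates: Optional[pd.DataFrame] = None,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbor matching without replacement.

    Cases are processed in descending propensity order; each takes the
    nearest unused control on the logit scale within the caliper (default
    0.2 × sd of logit scores).  Unmatched cases are counted, not raised.
    """
    lab = pd.Series(np.asarray(labels), index=scores.index)
    case_ids = scores.index[lab == 1]
    ctrl_ids = scores.index[lab == 0]
    if len(ctrl_ids) == 0:
        raise ValueError("no controls available")
    eps = 1e-12
    logit = np.log((scores + eps) / (1.0 - scores + eps))
    if caliper is None:
        caliper = 0.2 * float(logit.std(ddof=1))

    order = scores.loc[case_ids].sort_values(ascending=False, kind="stable").index
    available = dict(logit.loc[ctrl_ids])
    pairs, unmatched = [], []
    for case in order:
        if not available:
            unmatched.append(case)
            continue
        target = logit.loc[case]
        best = min(available, key=lambda c: (abs(available[c] - target), str(c)))
        dist = abs(available[best] - target)
        if dist <= caliper:
            pairs.append({"case": case, "control": best,
                          "case_score": float(scores.loc[case]),
                          "control_score": float(scores.loc[best]),
                          "distance": float(dist)})
            del available[best]
        else:
            unmatched.append(case)
    pairs_df = pd.DataFrame(pairs, columns=["case", "control", "case_score",
                                            "control_score", "distance"])
    result = MatchResult(pairs=pairs_df, scores=scores, caliper=float(caliper),
                         unmatched_cases=unmatched)
    if covariates is not None and len(pairs_df):
        result.smd_before = standardized_mean_differences(covariates, case_ids, ctrl_ids)
        result.smd_after = standardized_mean_differences(
            covariates, pairs_df["case"], pairs_df["control"]
        )
    return result
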