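"""Tercile-coded Cox proportional-hazards prognosis for community eigengenes.

The partial likelihood is maximized by Newton iteration with Breslow
handling of tied event times; standard errors come from the observed
information.  Both an ordinal (0/1/2) trend coding and a high-vs-low binary
coding (middle tercile excluded) are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .community import EigengeneSet, anova_groups

__all__ = [
    "TercileCoding",
    "SurvivalFit",
    "tercile_split",
    "cox_fit",
    "cox_loglik",
    "prognosis_scan",
    "deathclass_anova",
    "km_curve",
]


@dataclass
class TercileCoding:
    labels: np.ndarray  # 0 = low, 1 = mid, 2 = high
    cutpoints: tuple[float, float]
    has_ties: bool


@dataclass
class SurvivalFit:
    coefficient: float
    se: float
    hazard_ratio: float
    wald_z: float
    p: float
    n: int
    events: int
    coding: str
    converged: bool
    n_iter: int
    warnings: list[str] = field(default_factory=list)


def tercile_split(values) -> TercileCoding:
    """Rank-based thirds: cuts at ranks ceil(n/3) and ceil(2n/3).

    Ties are broken by stable input order and flagged.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 6:
        raise ValueError("tercile_split needs at least 6 values")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    order = np.argsort(x, kind="stable")
    n1 = int(np.ceil(n / 3))
    n2 = int(np.ceil(2 * n / 3))
    labels = np.empty(n, dtype=int)
    labels[order[:n1]] = 0
    labels[order[n1:n2]] = 1
    labels[order[n2:]] = 2
    cut_lo = float(x[order[n1 - 1]])
    cut_hi = float(x[order[n2 - 1]])
    has_ties = bool(len(np.unique(x)) < n)
    return TercileCoding(labels=labels, cutpoints=(cut_lo, cut_hi), has_ties=has_ties)


def cox_loglik(beta: float, time, event, x) -> float:
    """Breslow partial log-likelihood of a single-covariate Cox model."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(bool)
    xv = np.asarray(x, dtype=float)
    ll = 0.0
    for ti in np.unique(t[e]):
        deaths = e & (t == ti)
        risk = t >= ti
        ll += beta * xv[deaths].sum() - deaths.sum() * np.log(
            np.exp(beta * xv[risk]).sum()
        )
    return float(ll)


def _cox_derivatives(beta: float, t, e, xv):
    """(loglik, gradient, information) under Breslow ties, vectorized.

    Samples sorted by descending time so risk-set sums are cumulative.
    """
    order = np.argsort(-t, kind="stable")
    ts, es, xs = t[order], e[order], xv[order]
    w = np.exp(beta * xs)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * xs)
    s2 = np.cumsum(w * xs * xs)
    # risk set for time ti = all with t >= ti = prefix ending at last tied index
    last_idx = np.searchsorted(-ts, -ts, side="right") - 1
    ll = grad = info = 0.0
    death_times = np.unique(ts[es])
    for ti in death_times:
        mask = es & (ts == ti)
        d = mask.sum()
        j = last_idx[np.flatnonzero(mask)[0]]
        denom = s0[j]
        mean = s1[j] / denom
        var = s2[j] / denom - mean**2
        ll += beta * xs[mask].sum() - d * np.log(denom)
        grad += xs[mask].sum() - d * mean
        info += d * var
    return float(ll), float(grad), float(info)


def cox_fit(time, event, covariate, coding: str = "continuous",
            max_iter: int = 50, tol: float = 1e-9) -> SurvivalFit:
    """Newton maximization of the Breslow partial likelihood.

    Monotone likelihood (perfect separation) is flagged as non-convergence;
    the last coefficient is still reported with a warning.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(bool)
    xv = np.asarray(covariate, dtype=float)
    if not (np.isfinite(t).all() and np.isfinite(xv).all()):
        raise ValueError("times and covariate must be finite")
    if (t < 0).any():
        raise ValueError("times must be >= 0")
    n_events = int(e.sum())
    if n_events == 0:
        raise ValueError("no events")
    if np.std(xv[e]) == 0 and np.std(xv) == 0:
        raise ValueError("covariate is constant")

    msgs: list[str] = []
    beta = 0.0
    ll_old, _, _ = _cox_derivatives(beta, t, e, xv)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, grad, info = _cox_derivatives(beta, t, e, xv)
        if info <= 0:
            msgs.append("non-positive information; stopping")
            break
        step = grad / info
        # step-halving to keep the likelihood non-decreasing
        new_beta = beta + step
        ll_new, _, _ = _cox_derivatives(new_beta, t, e, xv)
        halvings = 0
        while ll_new < ll and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            ll_new, _, _ = _cox_derivatives(new_beta, t, e, xv)
            halvings += 1
        beta = new_beta
        if abs(ll_new - ll) <= tol * (abs(ll) + 1e-12):
            converged = True
            break
        if abs(beta) > 20:
            msgs.append("monotone likelihood suspected (|coef| > 20)")
            warnings.warn("cox_fit: possible perfect separation; coefficient unreliable")
            break
    _, _, info = _cox_derivatives(beta, t, e, xv)
    se = float(1.0 / np.sqrt(info)) if info > 0 else np.inf
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return SurvivalFit(
        coefficient=float(beta), se=se, hazard_ratio=float(np.exp(beta)),
        wald_z=float(z), p=p, n=int(t.size), events=n_events, coding=coding,
        converged=converged, n_iter=it, warnings=msgs,
    )


def prognosis_scan(eigengenes: EigengeneSet, survival: pd.DataFrame) -> pd.DataFrame:
    """Tercile Cox fits for every community, both codings.

    ``survival`` needs columns ``time`` and ``event`` indexed by sample.
    Per-community failures are recorded, not raised.
    """
    samples = eigengenes.eigengenes.columns
    surv = survival.loc[samples]
    t = surv["time"].to_numpy(dtype=float)
    e = surv["event"].to_numpy()
    rows = []
    for c in eigengenes.communities:
        eig = eigengenes.get(c).to_numpy()
        try:
            coding = tercile_split(eig)
        except ValueError as err:
            rows.append({"community": c, "coding": "ordinal", "error": str(err)})
            continue
        for scheme in ("ordinal", "high_vs_low"):
            if scheme == "ordinal":
                mask = np.ones(len(eig), dtype=bool)
                x = coding.labels.astype(float)
            else:
                mask = coding.labels != 1
                x = (coding.labels[mask] == 2).astype(float)
            try:
                fit = cox_fit(t[mask], e[mask], x, coding=scheme)
                rows.append(
                    {
                        "community": c, "coding": scheme,
                        "coefficient": fit.coefficient, "se": fit.se,
                        "hazard_ratio": fit.hazard_ratio, "wald_z": fit.wald_z,
                        "p": fit.p, "n": fit.n, "events": fit.events,
                        "converged": fit.converged, "tie_flag": coding.has_ties,
                    }
                )
            except ValueError as err:
                rows.append({"community": c, "coding": scheme, "error": str(err)})
    return pd.DataFrame(rows)


def deathclass_anova(eigengenes: EigengeneSet, death_class) -> pd.DataFrame:
    """One-way ANOVA of each eigengene across ordinal death classes (1–4)."""
    dc = np.asarray(death_class)
    ok = pd.notna(dc)
    classes = np.unique(dc[ok])
    if len(classes) < 2:
        raise ValueError("need at least 2 death classes")
    rows = []
    for c in eigengenes.communities:
        eig = eigengenes.get(c).to_numpy()[ok]
        f, p = anova_groups(eig, dc[ok])
        rows.append({"community": c, "F": f, "p": p, "n_classes": len(classes)})
    return pd.DataFrame(rows).set_index("community")


def km_curve(time, event) -> pd.DataFrame:
    """Kaplan–Meier survival coordinates (product-limit estimate)."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(bool)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    rows = [{"time": 0.0, "survival": 1.0, "at_risk": int(t.size)}]
    s = 1.0
    for ti in np.unique(t[e]):
        at_risk = int((t >= ti).sum())
        d = int((e & (t == ti)).sum())
        s *= 1.0 - d / at_risk
        rows.append({"time": float(ti), "survival": s, "at_risk": at_risk})
    return pd.DataFrame(rows)
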