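"""Community eigengenes and their association with traits and groups."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EigengeneSet",
    "WelchResult",
    "compute_eigengene",
    "eigengene_set",
    "trait_correlation",
    "group_difference",
    "anova_groups",
    "association_table",
]


@dataclass
class EigengeneSet:
    """Community × sample eigengene matrix with per-community variance explained.

    Each eigengene has unit norm over samples; the sign is chosen so its
    correlation with the community's mean standardized expression is >= 0.
    """

    eigengenes: pd.DataFrame
    variance_explained: pd.Series

    @property
    def communities(self) -> list:
        return list(self.eigengenes.index)

    def get(self, community) -> pd.Series:
        return self.eigengenes.loc[community]


@dataclass
class WelchResult:
    t: float
    p: float
    df: float
    mean_a: float
    mean_b: float
    smd: float
    ratio_of_means: float


def _standardize_rows(mat: np.ndarray, index) -> np.ndarray:
    sd = mat.std(axis=1, ddof=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"constant gene(s) in community: {list(index[zero[:5]])}")
    return (mat - mat.mean(axis=1, keepdims=True)) / sd[:, None]


def compute_eigengene(expr, genes) -> tuple[pd.Series, float]:
    """First principal component over samples of a gene community.

    Genes are standardized (mean 0, sd 1) before the SVD.  Returns the
    unit-norm eigengene (one value per sample) and the fraction of variance
    explained.  The sign is aligned to the community's mean standardized
    expression.
    """
    values = expr.values if hasattr(expr, "values") and not isinstance(expr, pd.DataFrame) else expr
    sub = values.loc[list(genes)]
    if sub.shape[0] < 2:
        raise ValueError("community needs at least 2 genes")
    if sub.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    z = _standardize_rows(sub.to_numpy(dtype=float), sub.index)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    ve = float(s[0] ** 2 / np.sum(s**2))
    mean_profile = z.mean(axis=0)
    align = float(np.dot(eig, mean_profile))
    if align < 0:
        eig = -eig
    return pd.Series(eig, index=sub.columns, name="eigengene"), ve


def eigengene_set(expr, partition) -> EigengeneSet:
    """Eigengenes for every non-background community of a partition."""
    rows, ve = {}, {}
    for c in partition.communities:
        genes = partition.community_genes(c)
        e, v = compute_eigengene(expr, genes)
        rows[c] = e
        ve[c] = v
    samples = (expr.values if hasattr(expr, "unit") else expr).columns
    eg = pd.DataFrame(rows).T if rows else pd.DataFrame(columns=samples)
    return EigengeneSet(eigengenes=eg, variance_explained=pd.Series(ve, dtype=float))


def trait_correlation(eigengene, trait) -> tuple[float, float]:
    """Pearson r and two-sided p (t transform, n − 2 df), pairwise-complete."""
    x = np.asarray(eigengene, dtype=float)
    y = np.asarray(trait, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"trait_correlation: dropped {n_dropped} incomplete pairs")
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired finite observations")
    if np.std(y) == 0:
        raise ValueError("zero-variance trait")
    if np.std(x) == 0:
        raise ValueError("zero-variance eigengene")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p


def group_difference(eigengene, groups) -> WelchResult:
    """Welch's t-test between two groups with effect sizes.

    Reports the Satterthwaite-df statistic, group means, standardized mean
    difference (pooled-sd denominator), and ratio of means.
    """
    x = np.asarray(eigengene, dtype=float)
    g = np.asarray(groups)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    a, b = x[g == levels[0]], x[g == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        t, p, df = 0.0, 1.0, float(na + nb - 2)
    else:
        t = (a.mean() - b.mean()) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = float(2.0 * stats.t.sf(abs(t), df=df))
    pooled_sd = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    smd = float((a.mean() - b.mean()) / pooled_sd) if pooled_sd > 0 else 0.0
    rom = float(a.mean() / b.mean()) if b.mean() != 0 else np.nan
    return WelchResult(t=float(t), p=float(p), df=float(df), mean_a=float(a.mean()),
                       mean_b=float(b.mean()), smd=smd, ratio_of_means=rom)


def anova_groups(values, groups) -> tuple[float, float]:
    """One-way ANOVA F and p with (k − 1, n − k) degrees of freedom."""
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels = [lev for lev in pd.unique(g)]
    k = len(levels)
    n = x.size
    if k < 2:
        raise ValueError("need at least 2 groups")
    if n <= k:
        raise ValueError("need total n > number of groups")
    grand = x.mean()
    ss_between = sum(len(x[g == lev]) * (x[g == lev].mean() - grand) ** 2 for lev in levels)
    ss_within = sum(((x[g == lev] - x[g == lev].mean()) ** 2).sum() for lev in levels)
    if ss_within == 0:
        if ss_between == 0:
            warnings.warn("anova_groups: no variance at all; F = 0, p = 1")
            return 0.0, 1.0
        return np.inf, 0.0
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    p = float(stats.f.sf(f, k - 1, n - k))
    return float(f), p


def association_table(
    eigengenes: EigengeneSet,
    annotations: pd.DataFrame,
    traits: list[str],
    group_col: str = "group",
    trait_scope=None,
) -> pd.DataFrame:
    """Per community: trait correlations plus patient/control Welch contrast.

    ``trait_scope`` optionally restricts trait correlations to a boolean
    sample mask (e.g. patients only); the group contrast always spans both
    groups.
    """
    samples = eigengenes.eigengenes.columns
    ann = annotations.loc[samples]
    scope = np.ones(len(samples), dtype=bool) if trait_scope is None else np.asarray(trait_scope)
    rows = []
    for c in eigengenes.communities:
        e = eigengenes.get(c).to_numpy()
        row: dict = {"community": c}
        for tr in traits:
            if tr not in ann.columns:
                continue
            try:
                r, p = trait_correlation(e[scope], ann[tr].to_numpy()[scope])
            except ValueError:
                r, p = np.nan, np.nan
            row[f"{tr}_r"] = r
            row[f"{tr}_p"] = p
        if group_col in ann.columns and ann[group_col].nunique() == 2:
            w = group_difference(e, ann[group_col].to_numpy())
            row.update(welch_t=w.t, welch_p=w.p, mean_a=w.mean_a, mean_b=w.mean_b,
                       smd=w.smd, ratio_of_means=w.ratio_of_means)
        rows.append(row)
    return pd.DataFrame(rows).set_index("community")
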