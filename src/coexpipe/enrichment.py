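"""Fisher exact tests, community over-representation analysis, and BH FDR."""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

import pandas as pd

__all__ = [
    "GeneSetCollection",
    "fisher_exact_2x2",
    "ora_community",
    "enrichment_table",
    "bh_fdr",
    "harmonize_ids",
]

# relative slack on the "point probability <= observed" comparison in the
# two-sided test, guarding against float noise on ties (same convention as R)
_TWO_SIDED_REL_TOL = 1e-7

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def harmonize_ids(ids) -> list[str]:
    """Uppercase and strip trailing version suffixes (e.g. ENSG...\\.12)."""
    return [_VERSION_SUFFIX.sub("", str(g)).upper() for g in ids]


@dataclass
class GeneSetCollection:
    """Named gene sets with a source label."""

    sets: dict[str, set[str]]
    source: str = ""

    def __post_init__(self) -> None:
        empty = [k for k, v in self.sets.items() if not v]
        if empty:
            raise ValueError(f"empty gene sets: {empty}")

    def harmonized(self) -> "GeneSetCollection":
        return GeneSetCollection(
            sets={k: set(harmonize_ids(v)) for k, v in self.sets.items()},
            source=self.source,
        )


def fisher_exact_2x2(table, sided: str = "two") -> float:
    """Exact hypergeometric p-value for a 2×2 contingency table.

    ``sided="two"`` sums probabilities of all tables with the same margins
    whose point probability is <= the observed one (with a small relative
    tolerance); ``sided="greater"`` is the upper tail of the first cell.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n_total = a + b + c + d
    if n_total == 0:
        raise ValueError("table total must be > 0")
    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - n_total)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n_total, col1, row1)
    p_obs = pmf[a - lo]
    if sided == "greater":
        p = float(pmf[support >= a].sum())
    elif sided == "two":
        p = float(pmf[pmf <= p_obs * (1.0 + _TWO_SIDED_REL_TOL)].sum())
    else:
        raise ValueError(f"unknown sided {sided!r}")
    return min(p, 1.0)


def ora_community(
    community_genes,
    gene_set,
    universe,
    sided: str = "greater",
    set_name: str = "",
) -> dict:
    """Over-representation of one gene set in one community.

    The universe is the network gene background; the set is intersected with
    the universe first.  Fold enrichment is observed overlap over its
    expectation under random draw.
    """
    community = set(community_genes)
    univ = set(universe)
    if not community <= univ:
        raise ValueError("community must be a subset of the universe")
    s = set(gene_set) & univ
    m, k, n_univ = len(community), len(s), len(univ)
    if k == 0:
        warnings.warn(f"gene set {set_name!r} empty after universe intersection")
        return {
            "set": set_name, "overlap": 0, "expected": np.nan, "odds_ratio": np.nan,
            "fold_enrichment": np.nan, "p": np.nan,
            "community_size": m, "set_size": 0, "universe_size": n_univ,
        }
    overlap = len(community & s)
    expected = m * k / n_univ
    a = overlap
    b = m - overlap
    c = k - overlap
    d = n_univ - m - c
    p = fisher_exact_2x2([[a, b], [c, d]], sided=sided)
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return {
        "set": set_name,
        "overlap": overlap,
        "expected": expected,
        "odds_ratio": odds,
        "fold_enrichment": overlap / expected if expected > 0 else np.nan,
        "p": p,
        "community_size": m,
        "set_size": k,
        "universe_size": n_univ,
    }


def enrichment_table(
    partition,
    collection: GeneSetCollection,
    universe=None,
    sided: str = "greater",
    fdr: bool = True,
) -> pd.DataFrame:
    """ORA of every community against every set, BH-corrected across all rows."""
    labels = partition.labels
    univ = set(universe) if universe is not None else set(labels.index[labels != 0])
    rows = []
    for c in partition.communities:
        genes = set(partition.community_genes(c)) & univ
        for name, s in collection.sets.items():
            row = ora_community(genes, s, univ, sided=sided, set_name=name)
            row["community"] = c
            rows.append(row)
    df = pd.DataFrame(rows)
    if len(df) and fdr:
        ok = df["p"].notna()
        q = np.full(len(df), np.nan)
        if ok.any():
            q[ok.to_numpy()] = bh_fdr(df.loc[ok, "p"].to_numpy())
        df["q"] = q
    return df


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
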