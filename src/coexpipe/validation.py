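"""Cross-cohort edge revalidation and community preservation statistics."""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import CoexpressionNetwork, ModulePartition, NetworkConfig, build_adjacency

__all__ = [
    "EdgeValidationReport",
    "PreservationReport",
    "revalidate_edges",
    "preservation_z",
    "retain_modules",
]


@dataclass
class EdgeValidationReport:
    """Per-edge cross-cohort confirmation status.

    ``confirmed`` is a boolean gene × gene matrix (an edge is confirmed when
    some cohort replicates its correlation with the same sign at p < alpha);
    ``cohort_overlap`` counts genes shared with each cohort;
    ``community_rates`` summarizes the confirmed fraction of within-community
    edges.
    """

    genes: pd.Index
    confirmed: np.ndarray
    alpha: float
    cohort_overlap: dict[str, int]
    community_rates: pd.Series
    overall_rate: float
    per_cohort: dict[str, dict] = field(default_factory=dict)

    def to_frame(self, network: CoexpressionNetwork, min_tom: float = 0.0) -> pd.DataFrame:
        """Long-format edge table (upper triangle), optionally TOM-floored."""
        iu, ju = np.triu_indices(len(self.genes), k=1)
        keep = network.tom[iu, ju] >= min_tom
        iu, ju = iu[keep], ju[keep]
        df = pd.DataFrame(
            {
                "gene_a": self.genes[iu],
                "gene_b": self.genes[ju],
                "correlation": network.corr[iu, ju],
                "adjacency": network.adjacency[iu, ju],
                "tom": network.tom[iu, ju],
                "confirmed": self.confirmed[iu, ju],
            }
        )
        for name, d in self.per_cohort.items():
            df[f"r_{name}"] = d["corr"][iu, ju]
            df[f"p_{name}"] = d["p"][iu, ju]
        return df


@dataclass
class PreservationReport:
    """Per-community preservation Z statistics in one test cohort."""

    cohort: str
    table: pd.DataFrame  # indexed by community
    n_permutations: int
    seed: int


def _corr_pvalues(corr: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson correlations via the t transform."""
    r = np.clip(corr, -0.9999999999, 0.9999999999)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def revalidate_edges(
    network: CoexpressionNetwork,
    partition: ModulePartition,
    cohorts: dict,
    alpha: float = 0.05,
    require_all_cohorts: bool = False,
) -> tuple[EdgeValidationReport, CoexpressionNetwork]:
    """Recompute every discovery edge in external cohorts and prune.

    An edge is confirmed when a cohort containing both endpoints shows a
    same-sign Pearson correlation with two-sided p < ``alpha`` (all cohorts
    must agree when ``require_all_cohorts``).  Unconfirmed edges have their
    adjacency and TOM entries set to 0 in the returned pruned network.
    """
    if not isinstance(cohorts, dict):
        cohorts = {
            getattr(c, "cohort", "") or f"cohort{i}": c for i, c in enumerate(cohorts)
        }
    genes = network.genes
    n_genes = len(genes)
    sign_disc = np.sign(network.corr)
    confirmed_any = np.zeros((n_genes, n_genes), dtype=bool)
    confirmed_all = np.ones((n_genes, n_genes), dtype=bool)
    evaluable_any = np.zeros((n_genes, n_genes), dtype=bool)
    per_cohort: dict[str, dict] = {}
    overlap: dict[str, int] = {}

    for name, expr in cohorts.items():
        values = expr.values if hasattr(expr, "unit") else expr
        shared = genes.intersection(values.index)
        overlap[name] = len(shared)
        if len(shared) < 2:
            raise ValueError(f"cohort {name!r} shares fewer than 2 genes with the network")
        sub = values.loc[shared].to_numpy(dtype=float)
        n_samples = sub.shape[1]
        sd = sub.std(axis=1)
        ok_var = sd > 0
        r_c = np.full((n_genes, n_genes), np.nan)
        p_c = np.full((n_genes, n_genes), np.nan)
        pos = genes.get_indexer(shared)
        good = pos[ok_var]
        sub_ok = sub[ok_var]
        cc = np.corrcoef(sub_ok) if sub_ok.shape[0] > 1 else np.ones((1, 1))
        pp = _corr_pvalues(cc, n_samples)
        r_c[np.ix_(good, good)] = cc
        p_c[np.ix_(good, good)] = pp
        per_cohort[name] = {"corr": r_c, "p": p_c, "n_samples": n_samples}

        evaluable = np.isfinite(r_c)
        hit = evaluable & (np.sign(r_c) == sign_disc) & (p_c < alpha)
        confirmed_any |= hit
        confirmed_all &= np.where(evaluable, hit, True)
        evaluable_any |= evaluable

    confirmed = (confirmed_all & evaluable_any) if require_all_cohorts else confirmed_any
    confirmed |= confirmed.T
    np.fill_diagonal(confirmed, True)

    pruned = copy.copy(network)
    pruned.adjacency = np.where(confirmed, network.adjacency, 0.0)
    pruned.tom = np.where(confirmed, network.tom, 0.0)
    np.fill_diagonal(pruned.tom, 1.0)

    iu, ju = np.triu_indices(n_genes, k=1)
    overall = float(confirmed[iu, ju].mean())
    rates = {}
    lab = partition.labels.reindex(genes).to_numpy()
    for c in partition.communities:
        idx = np.flatnonzero(lab == c)
        if len(idx) < 2:
            continue
        block = confirmed[np.ix_(idx, idx)]
        bi, bj = np.triu_indices(len(idx), k=1)
        rates[c] = float(block[bi, bj].mean())
    report = EdgeValidationReport(
        genes=genes,
        confirmed=confirmed,
        alpha=alpha,
        cohort_overlap=overlap,
        community_rates=pd.Series(rates, dtype=float),
        overall_rate=overall,
        per_cohort=per_cohort,
    )
    return report, pruned


def _module_stats(
    idx: np.ndarray, adj_disc: np.ndarray, adj_test: np.ndarray
) -> tuple[float, float]:
    """(density in test cohort, discovery/test intramodular-connectivity corr)."""
    block_t = adj_test[np.ix_(idx, idx)]
    m = len(idx)
    density = float(block_t.sum() / (m * (m - 1))) if m > 1 else 0.0
    k_disc = adj_disc[np.ix_(idx, idx)].sum(axis=1)
    k_test = block_t.sum(axis=1)
    if np.std(k_disc) == 0 or np.std(k_test) == 0:
        conn = 0.0
    else:
        conn = float(np.corrcoef(k_disc, k_test)[0, 1])
    return density, conn


def preservation_z(
    partition: ModulePartition,
    discovery_expr,
    test_expr,
    n_permutations: int = 200,
    seed: int = 0,
    config: NetworkConfig | None = None,
    cohort_name: str = "test",
) -> PreservationReport:
    """Permutation Z statistics for community preservation in a test cohort.

    For each community: density = mean within-community adjacency in the test
    cohort (discovery soft-threshold power); connectivity = Pearson
    correlation of intramodular connectivities between cohorts.  The null
    draws same-size random gene sets from the network gene universe.
    Z_summary = mean(Z_density, Z_connectivity).
    """
    if n_permutations < 50:
        raise ValueError("n_permutations must be >= 50")
    cfg = config or NetworkConfig()
    disc_vals = discovery_expr.values if hasattr(discovery_expr, "unit") else discovery_expr
    test_vals = test_expr.values if hasattr(test_expr, "unit") else test_expr
    universe = partition.labels.index.intersection(disc_vals.index).intersection(
        test_vals.index
    )
    d = disc_vals.loc[universe].to_numpy(dtype=float)
    t = test_vals.loc[universe].to_numpy(dtype=float)
    keep = (d.std(axis=1) > 0) & (t.std(axis=1) > 0)
    universe = universe[keep]
    d, t = d[keep], t[keep]
    adj_disc = build_adjacency(np.corrcoef(d), cfg)
    adj_test = build_adjacency(np.corrcoef(t), cfg)

    lab = partition.labels.reindex(universe).to_numpy()
    rng = np.random.default_rng(seed)
    n_univ = len(universe)
    rows = []
    for c in partition.communities:
        idx = np.flatnonzero(lab == c)
        if len(idx) < 3:
            warnings.warn(f"community {c}: fewer than 3 shared genes, skipped")
            continue
        obs_d, obs_c = _module_stats(idx, adj_disc, adj_test)
        null_d = np.empty(n_permutations)
        null_c = np.empty(n_permutations)
        for b in range(n_permutations):
            perm = rng.choice(n_univ, size=len(idx), replace=False)
            null_d[b], null_c[b] = _module_stats(perm, adj_disc, adj_test)

        def _z(obs: float, null: np.ndarray) -> float:
            sd = null.std(ddof=1)
            if sd == 0:
                warnings.warn("null sd = 0: Z reported as +/- inf")
                return np.inf if obs > null.mean() else -np.inf
            return float((obs - null.mean()) / sd)

        z_d, z_c = _z(obs_d, null_d), _z(obs_c, null_c)
        rows.append(
            {
                "community": c,
                "size": int(len(idx)),
                "density": obs_d,
                "connectivity": obs_c,
                "null_density_mean": float(null_d.mean()),
                "null_density_sd": float(null_d.std(ddof=1)),
                "null_connectivity_mean": float(null_c.mean()),
                "null_connectivity_sd": float(null_c.std(ddof=1)),
                "z_density": z_d,
                "z_connectivity": z_c,
                "z_summary": float(np.mean([z_d, z_c])),
            }
        )
    table = pd.DataFrame(rows).set_index("community") if rows else pd.DataFrame()
    return PreservationReport(
        cohort=cohort_name, table=table, n_permutations=n_permutations, seed=seed
    )


def retain_modules(
    partition: ModulePartition,
    reports: list[PreservationReport],
    z_threshold: float = 3.0,
) -> tuple[ModulePartition, pd.DataFrame]:
    """Keep communities with Z_summary >= threshold in at least one cohort.

    Genes of removed communities are relabelled 0.  Also returns a summary
    table of max Z per community with the retained flag.
    """
    if not reports:
        raise ValueError("need at least one preservation report")
    rows = []
    for c in partition.communities:
        zs = {
            rep.cohort: float(rep.table.loc[c, "z_summary"])
            for rep in reports
            if c in rep.table.index
        }
        z_max = max(zs.values()) if zs else -np.inf
        rows.append({"community": c, "z_max": z_max, "retained": z_max >= z_threshold,
                     **{f"z_{k}": v for k, v in zs.items()}})
    summary = pd.DataFrame(rows).set_index("community")
    labels = partition.labels.copy()
    for c in summary.index[~summary.retained]:
        labels[labels == c] = 0
    # relabel retained communities 1..K by size
    out = pd.Series(0, index=labels.index, name="community")
    sizes = labels[labels != 0].value_counts()
    for new, old in enumerate(sorted(sizes.index, key=lambda c: (-sizes[c], c)), start=1):
        out[labels == old] = new
    return (
        ModulePartition(labels=out, merge_heights=partition.merge_heights,
                        merge_history=partition.merge_history),
        summary,
    )
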