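"""Weighted co-expression network construction and community detection.

Soft-threshold adjacency from Pearson correlations, scale-free topology fit
scan, topological overlap, average-linkage hierarchical community detection
with a static height cut, and eigengene-based merging of similar communities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .preprocessing import ExpressionMatrix

__all__ = [
    "NetworkConfig",
    "CoexpressionNetwork",
    "ModulePartition",
    "SoftThresholdScan",
    "correlation_matrix",
    "scan_soft_threshold",
    "build_adjacency",
    "topological_overlap",
    "build_network",
    "detect_communities",
    "merge_similar",
]


@dataclass
class NetworkConfig:
    signed_mode: str = "unsigned"  # "unsigned" | "signed"
    power: int = 13
    scale_free_r2_target: float = 0.80
    n_degree_bins: int = 10
    min_module_size: int = 30
    tree_cut_height: Optional[float] = None  # default: 0.99 quantile of merge heights
    merge_cut_height: float = 0.25

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if not 0.0 < self.merge_cut_height < 1.0:
            raise ValueError("merge_cut_height must be in (0, 1)")
        if self.signed_mode not in ("unsigned", "signed"):
            raise ValueError(f"unknown signed_mode {self.signed_mode!r}")


@dataclass
class CoexpressionNetwork:
    genes: pd.Index
    corr: np.ndarray
    adjacency: np.ndarray
    tom: np.ndarray
    config: NetworkConfig


@dataclass
class ModulePartition:
    """Gene → community labels; 0 means unassigned/background."""

    labels: pd.Series
    merge_heights: np.ndarray = field(default_factory=lambda: np.array([]))
    merge_history: list = field(default_factory=list)

    def community_genes(self, label: int) -> pd.Index:
        return self.labels.index[self.labels == label]

    @property
    def communities(self) -> list[int]:
        return sorted(c for c in self.labels.unique() if c != 0)


@dataclass
class SoftThresholdScan:
    table: pd.DataFrame  # power, r_squared, slope, mean_connectivity
    recommended: int


def correlation_matrix(expr) -> pd.DataFrame:
    """Gene × gene Pearson correlation (genes in rows of the input)."""
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    mat = values.to_numpy(dtype=float)
    if mat.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sd = mat.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance gene(s): {list(values.index[zero[:5]])}")
    corr = np.corrcoef(mat)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(np.clip(corr, -1.0, 1.0), index=values.index, columns=values.index)


def build_adjacency(corr, config: NetworkConfig) -> np.ndarray:
    """Soft-threshold adjacency; diagonal set to 0 for connectivity sums."""
    r = np.asarray(corr, dtype=float)
    if config.signed_mode == "unsigned":
        adj = np.abs(r) ** config.power
    else:
        adj = ((1.0 + r) / 2.0) ** config.power
    np.fill_diagonal(adj, 0.0)
    return adj


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    """Signed R² and slope of the binned log10 p(k) vs log10 k regression."""
    if k.max() == k.min():
        warnings.warn("degenerate connectivity distribution; R^2 reported as 0")
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k = np.array([k[idx == b].mean() if (idx == b).any() else np.nan for b in range(n_bins)])
    freq = np.array([(idx == b).mean() for b in range(n_bins)])
    ok = ~np.isnan(mean_k) & (freq > 0) & (mean_k > 0)
    if ok.sum() < 2:
        warnings.warn("fewer than 2 populated degree bins; R^2 reported as 0")
        return 0.0, 0.0
    x, y = np.log10(mean_k[ok]), np.log10(freq[ok])
    slope, _ = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    return float(-np.sign(slope) * r**2), float(slope)


def scan_soft_threshold(
    corr,
    powers: Sequence[int] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 13, 14, 16, 18, 20),
    config: Optional[NetworkConfig] = None,
) -> SoftThresholdScan:
    """Scale-free topology fit for candidate soft-threshold powers.

    For each power, genes are binned by connectivity and the signed R² of the
    log-log frequency/connectivity regression is reported (positive only when
    the slope is negative).  Recommended power = smallest with
    R² >= target, else the maximizer.
    """
    if len(powers) == 0:
        raise ValueError("candidate power list is empty")
    cfg = config or NetworkConfig()
    r = np.asarray(corr, dtype=float)
    if r.shape[0] < 30:
        warnings.warn("fewer than 30 genes: scale-free fit is unreliable")
    rows = []
    for p in powers:
        adj = build_adjacency(r, NetworkConfig(signed_mode=cfg.signed_mode, power=int(p)))
        k = adj.sum(axis=1)
        r2, slope = _scale_free_fit(k, cfg.n_degree_bins)
        rows.append({"power": int(p), "r_squared": r2, "slope": slope,
                     "mean_connectivity": float(k.mean())})
    table = pd.DataFrame(rows)
    above = table[table.r_squared >= cfg.scale_free_r2_target]
    rec = int(above.power.iloc[0]) if len(above) else int(table.loc[table.r_squared.idxmax(), "power"])
    return SoftThresholdScan(table=table, recommended=rec)


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij), diag 1."""
    a = np.asarray(adjacency, dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    shared = a @ a
    k = a.sum(axis=1)
    min_k = np.minimum.outer(k, k)
    denom = min_k + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def build_network(expr, config: Optional[NetworkConfig] = None) -> CoexpressionNetwork:
    """Correlation → adjacency → TOM for one expression matrix."""
    cfg = config or NetworkConfig()
    corr = correlation_matrix(expr)
    adj = build_adjacency(corr.to_numpy(), cfg)
    tom = topological_overlap(adj)
    return CoexpressionNetwork(genes=corr.index, corr=corr.to_numpy(), adjacency=adj,
                               tom=tom, config=cfg)


def _relabel_by_size(labels: np.ndarray, min_size: int, max_size: int | None = None) -> np.ndarray:
    """Drop clusters below min_size (or above max_size) to 0, relabel 1..K by size."""
    out = np.zeros_like(labels)
    sizes = pd.Series(labels).value_counts()
    keep = sizes[sizes >= min_size].index
    if max_size is not None:
        keep = [c for c in keep if sizes[c] <= max_size]
    order = sorted(keep, key=lambda c: (-sizes[c], c))
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out


def _gap_candidates(heights: np.ndarray, n_candidates: int = 8) -> list[float]:
    """Candidate static cut heights: midpoints of the largest gaps among the
    upper three quarters of the sorted merge heights."""
    sh = np.sort(heights)
    if len(sh) < 4:
        return [float(np.quantile(sh, 0.99))]
    start = len(sh) // 4
    gaps = np.diff(sh)[start:]
    order = np.argsort(gaps)[::-1][:n_candidates]
    cuts = [
        float((sh[start + gi] + sh[start + gi + 1]) / 2.0)
        for gi in order
        if gaps[gi] > 0
    ]
    return cuts or [float(np.quantile(sh, 0.99))]


def detect_communities(
    network: CoexpressionNetwork, config: Optional[NetworkConfig] = None
) -> ModulePartition:
    """Average-linkage clustering of 1 − TOM with a static height cut.

    When ``tree_cut_height`` is unset, candidate cuts are the midpoints of
    the largest gaps in the upper half of the sorted merge heights
    (background genes merge in a tight band near the maximum dissimilarity);
    the candidate producing the most clusters of at least
    ``min_module_size`` wins, ties going to the higher cut.  Clusters
    smaller than ``min_module_size`` get label 0.
    """
    cfg = config or network.config
    genes = network.genes
    if len(genes) < cfg.min_module_size:
        warnings.warn("fewer genes than min_module_size: all genes labelled 0")
        return ModulePartition(labels=pd.Series(0, index=genes, name="community"))
    dissim = 1.0 - network.tom
    np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2.0
    link = average(squareform(dissim, checks=False))
    heights = link[:, 2]
    max_size = int(0.9 * len(genes))
    if cfg.tree_cut_height is not None:
        cut = cfg.tree_cut_height
    else:
        best = None
        for cand in sorted(_gap_candidates(heights), reverse=True):
            lab = fcluster(link, t=cand, criterion="distance")
            sizes = pd.Series(lab).value_counts()
            n_big = int(((sizes >= cfg.min_module_size) & (sizes <= max_size)).sum())
            if best is None or n_big > best[0]:
                best = (n_big, cand)
        cut = best[1]
    raw = fcluster(link, t=cut, criterion="distance")
    labels = _relabel_by_size(
        raw, cfg.min_module_size, max_size if cfg.tree_cut_height is None else None
    )
    return ModulePartition(
        labels=pd.Series(labels, index=genes, name="community"),
        merge_heights=heights,
    )


def merge_similar(
    partition: ModulePartition,
    eigengenes: pd.DataFrame,
    merge_cut_height: float = 0.25,
    expr=None,
) -> ModulePartition:
    """Merge communities whose eigengenes are highly correlated.

    Average-linkage clustering of eigengene dissimilarity (1 − Pearson r) is
    cut at ``merge_cut_height``; merged groups collapse to one label.  When
    ``expr`` is given, eigengenes are recomputed after each round and merging
    iterates until stable.  Merge history is recorded.
    """
    from .community import compute_eigengene  # local import to avoid cycle

    labels = partition.labels.copy()
    history = list(partition.merge_history)
    eig = eigengenes.copy()
    while True:
        comms = sorted(c for c in labels.unique() if c != 0)
        if len(comms) < 2:
            break
        eg = eig.loc[[c for c in eig.index if c in comms]]
        dissim = 1.0 - np.corrcoef(eg.to_numpy())
        np.fill_diagonal(dissim, 0.0)
        dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
        link = average(squareform(dissim, checks=False))
        groups = fcluster(link, t=merge_cut_height, criterion="distance")
        if len(set(groups)) == len(comms):
            break
        mapping = {}
        for g in np.unique(groups):
            members = [eg.index[i] for i in np.flatnonzero(groups == g)]
            target = min(members)
            for m in members:
                mapping[m] = target
            if len(members) > 1:
                history.append({"merged": list(members), "into": target})
        labels = labels.map(lambda c: mapping.get(c, c))
        # recompute (or average) eigengenes of the merged communities
        new_eig = {}
        for c in sorted(set(mapping.values())):
            if expr is not None:
                genes = labels.index[labels == c]
                e, _ = compute_eigengene(expr, genes)
                new_eig[c] = e.to_numpy()
            else:
                members = [m for m, t in mapping.items() if t == c]
                v = eg.loc[members].to_numpy().mean(axis=0)
                new_eig[c] = v / np.linalg.norm(v)
        eig = pd.DataFrame(new_eig, index=eg.columns).T
    # normalize labels to 1..K by size
    out = pd.Series(0, index=labels.index, name="community")
    sizes = labels[labels != 0].value_counts()
    for new, old in enumerate(sorted(sizes.index, key=lambda c: (-sizes[c], c)), start=1):
        out[labels == old] = new
    return ModulePartition(labels=out, merge_heights=partition.merge_heights,
                           merge_history=history)
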