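"""Weighted gene co-expression network: power adjacency, TOM, modules, hubs.

The network is built from the unsigned power adjacency
a_ij = |cor(x_i, x_j)|^beta.  The soft-threshold beta is chosen as the
smallest value on a candidate grid for which the connectivity distribution
is approximately scale-free (R^2 of log10 p(k) against log10 k over
equal-occupancy bins at least a target, default 0.8).  Neighborhood
sharing is quantified by the topological overlap measure

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

modules are cut from an average-linkage tree on 1 - TOM at a fixed height,
and hub genes are the most connected genes within their module that also
pass a gene-significance cutoff (GS on the -log10 p scale) and a relative
intramodular connectivity cutoff K/Kmax.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

UNASSIGNED = 0


@dataclass
class HubConfig:
    n_hubs: int = 5
    gs_cutoff: float = 1.2  # on the -log10 p scale (p <= ~0.063)
    k_ratio_cutoff: float = 0.95
    beta: int = 8
    r2_target: float = 0.8
    beta_grid: tuple[int, ...] = tuple(range(1, 21))

    def __post_init__(self) -> None:
        if self.gs_cutoff < 0 or self.k_ratio_cutoff < 0:
            raise ValueError("cutoffs must be >= 0")


@dataclass
class AdjacencyNetwork:
    genes: list[str]
    adjacency: np.ndarray  # symmetric, diag 1, off-diag in [0,1]
    beta: float
    tom: np.ndarray | None = None
    modules: np.ndarray | None = None  # labels, 0 = unassigned
    r2: float | None = None

    @property
    def connectivity(self) -> np.ndarray:
        """k_i = sum_{j != i} a_ij (diagonal excluded)."""
        return self.adjacency.sum(axis=1) - np.diag(self.adjacency)


def power_adjacency(expr: pd.DataFrame, beta: float) -> AdjacencyNetwork:
    """Unsigned power adjacency |r|^beta over genes (rows) of ``expr``.

    Zero-variance genes are excluded with a warning.  The diagonal is set
    to 1 but never contributes to connectivity.
    """
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples per gene")
    var = expr.var(axis=1, ddof=0)
    bad = list(expr.index[var == 0])
    if bad:
        warnings.warn(f"excluding zero-variance genes: {bad[:5]}{'...' if len(bad) > 5 else ''}")
        expr = expr.drop(index=bad)
    genes = list(expr.index)
    r = np.corrcoef(expr.to_numpy(dtype=float))
    a = np.abs(np.clip(r, -1, 1)) ** beta
    np.fill_diagonal(a, 1.0)
    return AdjacencyNetwork(genes=genes, adjacency=a, beta=beta)


def scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 p(k) ~ log10 k over equal-occupancy connectivity bins."""
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(k) < n_bins:
        return float("nan")
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        return float("nan")
    counts, _ = np.histogram(k, bins=edges)
    widths = np.diff(edges)
    centers = np.array(
        [k[(k >= lo) & (k <= hi)].mean() for lo, hi in zip(edges[:-1], edges[1:])]
    )
    ok = (counts > 0) & (widths > 0)
    if ok.sum() < 3:
        return float("nan")
    # with equal-occupancy bins p(k) is the empirical density, count/width
    x = np.log10(centers[ok])
    y = np.log10(counts[ok] / (counts.sum() * widths[ok]))
    slope, intercept, r, _p, _se = stats.linregress(x, y)
    if np.isnan(r):
        return float("nan")
    return float(r ** 2)


def pick_beta(expr: pd.DataFrame, cfg: HubConfig | None = None) -> tuple[int, float]:
    """Smallest grid beta reaching the scale-free R^2 target.

    Falls back (with a warning) to the beta with maximal R^2 when no grid
    value reaches the target.  Returns (beta, R^2 at that beta).
    """
    cfg = cfg or HubConfig()
    if len(expr) < 10:
        raise ValueError("need >= 10 genes to assess scale-free fit")
    if not cfg.beta_grid:
        raise ValueError("empty beta grid")
    r = np.abs(np.corrcoef(expr.to_numpy(dtype=float)))
    np.fill_diagonal(r, 0.0)
    best_beta, best_r2 = None, -np.inf
    for beta in cfg.beta_grid:
        k = (r ** beta).sum(axis=1)
        r2 = scale_free_r2(k)
        if not np.isnan(r2) and r2 >= cfg.r2_target:
            return int(beta), float(r2)
        if not np.isnan(r2) and r2 > best_r2:
            best_beta, best_r2 = beta, r2
    warnings.warn(
        f"no beta on the grid reaches scale-free R^2 >= {cfg.r2_target}; "
        f"using beta={best_beta} (R^2={best_r2:.3f})"
    )
    if best_beta is None:
        best_beta, best_r2 = cfg.beta_grid[0], float("nan")
    return int(best_beta), float(best_r2)


def tom(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix; TOM_ii = 1, symmetric, in [0, 1]."""
    a = np.asarray(adjacency, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # sum_u a_iu a_uj (diagonal zeroed, so u != i and u != j)
    num = shared + a
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / (kmin + 1.0 - a)
    t = np.nan_to_num(t, nan=0.0)
    np.fill_diagonal(t, 1.0)
    return np.clip(t, 0.0, 1.0)


def detect_modules(
    tom_matrix: np.ndarray, min_size: int = 30, cut_height: float = 0.95
) -> np.ndarray:
    """Static cut of the average-linkage tree on 1 - TOM.

    Clusters smaller than ``min_size`` are labelled 0 (unassigned); real
    modules get labels 1, 2, ... in decreasing size order.
    """
    d = 1.0 - np.asarray(tom_matrix, dtype=float)
    np.fill_diagonal(d, 0.0)
    n = d.shape[0]
    if n < 2:
        return np.zeros(n, dtype=int)
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    labels = np.zeros(n, dtype=int)
    sizes = [(np.sum(raw == c), c) for c in np.unique(raw)]
    sizes.sort(key=lambda x: (-x[0], x[1]))
    next_label = 1
    for size, c in sizes:
        if size >= min_size:
            labels[raw == c] = next_label
            next_label += 1
    return labels


@dataclass
class HubReport:
    hubs: list[str]
    connectivity: pd.Series
    warning: str | None = None


def hub_genes(
    net: AdjacencyNetwork,
    gene_significance: pd.Series,
    cfg: HubConfig | None = None,
) -> HubReport:
    """Top-connectivity genes passing GS and K/Kmax cutoffs within modules.

    Gene significance is on the -log10(p) scale (so the default cutoff 1.2
    corresponds to p <= ~0.063).  Kmax is the maximum connectivity within
    the gene's module; with a single module that is the global maximum.
    Fewer qualifying genes than requested returns all of them with a
    warning.
    """
    cfg = cfg or HubConfig()
    if net.modules is None:
        modules = np.ones(len(net.genes), dtype=int)
    else:
        modules = net.modules
    k = pd.Series(net.connectivity, index=net.genes)
    gs = gene_significance.reindex(net.genes)
    qualified: list[str] = []
    for label in np.unique(modules):
        idx = [g for g, m in zip(net.genes, modules) if m == label]
        if len(idx) == 0:
            raise ValueError(f"module {label} is empty")
        kmax = k.loc[idx].max()
        if kmax <= 0:
            continue
        for g in idx:
            if (
                gs.loc[g] >= cfg.gs_cutoff
                and k.loc[g] / kmax >= cfg.k_ratio_cutoff
            ):
                qualified.append(g)
    qualified.sort(key=lambda g: (-k.loc[g], g))
    hubs = qualified[: cfg.n_hubs]
    warning = None
    if len(hubs) < cfg.n_hubs:
        warning = f"only {len(hubs)} genes pass the hub cutoffs"
        warnings.warn(warning)
    return HubReport(hubs=hubs, connectivity=k, warning=warning)


def gene_significance_from_pvalues(pmat: pd.DataFrame, how: str = "max") -> pd.Series:
    """GS_i = max (or mean) over conditions of -log10 raw p for gene i."""
    with np.errstate(divide="ignore"):
        gs = -np.log10(pmat.astype(float))
    gs = gs.replace(np.inf, 300.0)
    if how == "max":
        return gs.max(axis=1)
    if how == "mean":
        return gs.mean(axis=1)
    raise ValueError("how must be 'max' or 'mean'")


def build_network(
    expr: pd.DataFrame,
    cfg: HubConfig | None = None,
    beta: int | None = None,
    min_module_size: int = 30,
) -> AdjacencyNetwork:
    """adjacency -> TOM -> modules, with beta fixed or grid-selected."""
    cfg = cfg or HubConfig()
    r2 = None
    if beta is None:
        beta, r2 = pick_beta(expr, cfg)
    net = power_adjacency(expr, beta)
    net.r2 = r2
    net.tom = tom(net.adjacency)
    net.modules = detect_modules(net.tom, min_size=min_module_size)
    return net


def write_edge_list(net: AdjacencyNetwork, path, threshold: float = 1e-6) -> None:
    """TSV edge list (gene_i, gene_j, a_ij, TOM_ij), small weights dropped."""
    t = net.tom if net.tom is not None else tom(net.adjacency)
    with open(path, "w") as fh:
        fh.write("gene_i\tgene_j\tadjacency\ttom\n")
        n = len(net.genes)
        for i in range(n):
            for j in range(i + 1, n):
                a = net.adjacency[i, j]
                if a >= threshold:
                    fh.write(f"{net.genes[i]}\t{net.genes[j]}\t{a:.6g}\t{t[i, j]:.6g}\n")


def write_modules_tsv(net: AdjacencyNetwork, path) -> None:
    k = net.connectivity
    with open(path, "w") as fh:
        fh.write("gene\tmodule\tconnectivity\n")
        mods = net.modules if net.modules is not None else np.ones(len(net.genes), int)
        for g, m, ki in zip(net.genes, mods, k):
            fh.write(f"{g}\t{m}\t{ki:.6g}\n")
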