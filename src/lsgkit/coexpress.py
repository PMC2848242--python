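"""Seed-based co-expression clustering and hierarchical gene-condition trees.

Clusters are grown from designated seed transcripts: genes correlating
with a seed representative at Pearson r >= 0.90 are recruited, then the
cluster is adjusted — greedily dropping the weakest non-seed member — until
the average pairwise correlation reaches 0.75.  Tissue preferentiality
calls a gene preferential if its target-tissue intensity is at least
fold (default 2) times the maximum over every other tissue (inclusive
boundary).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

MIN_OVERLAP = 3  # pairwise-complete observations required for a correlation


@dataclass
class ClusterConfig:
    seed_r: float = 0.90
    avg_r: float = 0.75
    fold: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.avg_r <= self.seed_r <= 1:
            raise ValueError("require 0 < avg_r <= seed_r <= 1")
        if self.fold < 1:
            raise ValueError("fold must be >= 1")


@dataclass
class GeneCluster:
    seeds: set[str]
    members: set[str]
    avg_r: float
    preferred_tissue: str | None = None
    warning: str | None = None

    def __post_init__(self) -> None:
        if not self.seeds <= self.members:
            raise ValueError("seeds must be a subset of members")


def pearson(x, y) -> float:
    """Pairwise-complete Pearson r; NaN when undefined.

    Undefined when fewer than MIN_OVERLAP complete pairs remain or either
    vector has zero variance over the complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < MIN_OVERLAP:
        return float("nan")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd ** 2).sum() * (yd ** 2).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))


def correlation_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene pairwise-complete Pearson correlations."""
    return matrix.T.corr(method="pearson", min_periods=MIN_OVERLAP)


def dedupe_seeds(
    seed_profiles: pd.DataFrame, cfg: ClusterConfig | None = None
) -> tuple[list[str], dict[str, list[str]]]:
    """Group seeds by single linkage at r >= seed_r; pick one representative.

    Groups are the connected components of the r >= seed_r graph
    (transitive closure).  The representative is the medoid — the seed with
    the highest mean correlation to its group — with ties broken by the
    lexicographically smallest id.  Ungrouped seeds represent themselves.

    Returns (representatives, {representative: group members}).
    """
    cfg = cfg or ClusterConfig()
    ids = list(seed_profiles.index)
    if not ids:
        raise ValueError("no seeds given")
    corr = correlation_matrix(seed_profiles)
    # union-find over the threshold graph
    parent = {g: g for g in ids}

    def find(g):
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    for a, b in itertools.combinations(ids, 2):
        r = corr.loc[a, b]
        if not np.isnan(r) and r >= cfg.seed_r:
            parent[find(a)] = find(b)

    groups: dict[str, list[str]] = {}
    for g in ids:
        groups.setdefault(find(g), []).append(g)

    reps: list[str] = []
    out: dict[str, list[str]] = {}
    for members in groups.values():
        members = sorted(members)
        if len(members) == 1:
            rep = members[0]
        else:
            mean_r = {
                m: np.nanmean([corr.loc[m, o] for o in members if o != m])
                for m in members
            }
            best = max(mean_r.values())
            rep = min(m for m, v in mean_r.items() if v == best)
        reps.append(rep)
        out[rep] = members
    reps.sort()
    return reps, out


def grow_cluster(
    matrix: pd.DataFrame,
    representative: str,
    cfg: ClusterConfig | None = None,
    seed_ids: set[str] | None = None,
) -> GeneCluster:
    """Recruit every gene correlating with the representative at r >= seed_r.

    Any gene from ``seed_ids`` that meets the threshold (or is the
    representative) is flagged as a seed of the resulting cluster.
    """
    cfg = cfg or ClusterConfig()
    if representative not in matrix.index:
        raise KeyError(f"representative {representative!r} not in expression matrix")
    seed_ids = set(seed_ids or ()) | {representative}
    ref = matrix.loc[representative].to_numpy(dtype=float)
    members = {representative}
    for gene in matrix.index:
        if gene == representative:
            continue
        r = pearson(ref, matrix.loc[gene].to_numpy(dtype=float))
        if not np.isnan(r) and r >= cfg.seed_r:
            members.add(gene)
    seeds = members & seed_ids
    return GeneCluster(seeds=seeds, members=members, avg_r=average_pairwise_r(matrix, members))


def average_pairwise_r(matrix: pd.DataFrame, members) -> float:
    members = sorted(members)
    if len(members) < 2:
        return float("nan")
    corr = correlation_matrix(matrix.loc[members])
    vals = corr.to_numpy()[np.triu_indices(len(members), k=1)]
    return float(np.nanmean(vals))


def adjust_cluster(
    c: GeneCluster, matrix: pd.DataFrame, cfg: ClusterConfig | None = None
) -> GeneCluster:
    """Greedily drop weakest non-seed members until average r >= avg_r.

    Seeds are never removed; the removal order is deterministic (lowest
    mean correlation to the rest, ties by lexicographically largest id so
    earlier-sorting ids are preferentially retained).  If the threshold is
    unreachable without touching seeds, the seeds-only cluster is returned
    with a warning flag.
    """
    cfg = cfg or ClusterConfig()
    members = sorted(c.members)
    if len(members) < 2:
        return c
    corr = correlation_matrix(matrix.loc[members]).to_numpy()
    np.fill_diagonal(corr, np.nan)
    idx = {g: i for i, g in enumerate(members)}
    active = set(members)

    def avg_r() -> float:
        rows = [idx[g] for g in active]
        sub = corr[np.ix_(rows, rows)]
        return float(np.nanmean(sub[np.triu_indices(len(rows), k=1)])) if len(rows) > 1 else float("nan")

    cur = avg_r()
    warning = None
    while len(active) > 1 and not np.isnan(cur) and cur < cfg.avg_r:
        removable = sorted(active - c.seeds)
        if not removable:
            active = set(c.seeds)
            cur = avg_r()
            warning = "average r below threshold with seeds only"
            break
        rows = [idx[g] for g in sorted(active)]
        mean_to_rest = {
            g: float(np.nanmean(corr[idx[g], rows])) for g in removable
        }
        worst = min(mean_to_rest.values())
        victim = max(g for g, v in mean_to_rest.items() if v == worst)
        active.remove(victim)
        cur = avg_r()
    if warning is None and not np.isnan(cur) and cur < cfg.avg_r:
        warning = "average r below threshold with seeds only"
    return GeneCluster(
        seeds=set(c.seeds),
        members=active | set(c.seeds),
        avg_r=cur,
        preferred_tissue=c.preferred_tissue,
        warning=warning,
    )


def build_clusters(
    matrix: pd.DataFrame,
    seed_profiles: pd.DataFrame,
    cfg: ClusterConfig | None = None,
    overlap: str = "keep-largest",
) -> list[GeneCluster]:
    """Full seed pipeline: dedupe seeds, grow, adjust, resolve overlaps.

    Overlapping clusters (shared members) are resolved by keeping the
    largest cluster of each overlapping set — the only supported mode.
    """
    cfg = cfg or ClusterConfig()
    if overlap != "keep-largest":
        raise ValueError("only overlap='keep-largest' is supported")
    reps, _groups = dedupe_seeds(seed_profiles, cfg)
    seed_ids = set(seed_profiles.index)
    clusters = []
    for rep in reps:
        if rep not in matrix.index:
            continue
        c = grow_cluster(matrix, rep, cfg, seed_ids=seed_ids)
        clusters.append(adjust_cluster(c, matrix, cfg))
    # resolve member overlap: keep the largest cluster of each overlapping set
    clusters.sort(key=lambda c: (-len(c.members), min(c.members)))
    kept: list[GeneCluster] = []
    taken: set[str] = set()
    for c in clusters:
        if c.members & taken:
            continue
        kept.append(c)
        taken |= c.members
    return kept


def tissue_preferential(
    matrix: pd.DataFrame, gene: str, tissue: str, cfg: ClusterConfig | None = None
) -> bool:
    """True iff intensity(tissue) >= fold x max intensity over other tissues."""
    cfg = cfg or ClusterConfig()
    if tissue not in matrix.columns:
        raise KeyError(f"tissue {tissue!r} not in expression matrix")
    row = matrix.loc[gene]
    target = row[tissue]
    others = row.drop(tissue)
    if others.empty:
        return True
    return bool(target >= cfg.fold * others.max())


@dataclass
class Dendrogram:
    """Average-linkage tree at distance 1 - r, with branch correlations."""

    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix
    excluded: list[str] = field(default_factory=list)

    def branch_correlations(self) -> np.ndarray:
        """Per-merge branch correlation, 1 - merge height."""
        return 1.0 - self.linkage[:, 2]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.left), walk(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return walk(tree) + ";"


def hcluster(matrix: pd.DataFrame, axis: str = "genes") -> Dendrogram:
    """Agglomerative average-linkage clustering of genes or conditions.

    Distance is 1 - Pearson r.  Items whose correlation is undefined
    against any other item (zero variance / insufficient overlap) are
    excluded with a warning and listed in ``excluded``.
    """
    if axis == "conditions":
        matrix = matrix.T
    elif axis != "genes":
        raise ValueError("axis must be 'genes' or 'conditions'")
    if len(matrix) < 2:
        raise ValueError("need at least 2 items to cluster")
    corr = correlation_matrix(matrix)
    bad = [g for g in corr.index if corr.loc[g].drop(g).isna().all()]
    if bad:
        import warnings

        warnings.warn(f"excluding items with undefined correlation: {bad}")
        corr = corr.drop(index=bad, columns=bad)
    labels = list(corr.index)
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.nan_to_num(dist, nan=2.0)  # undefined pair -> maximal distance
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return Dendrogram(labels=labels, linkage=Z, excluded=bad)


def write_clusters_tsv(clusters: list[GeneCluster], matrix: pd.DataFrame, path) -> None:
    """TSV: cluster id, gene id, is_seed, mean r to the rest of the cluster."""
    with open(path, "w") as fh:
        fh.write("cluster\tgene\tis_seed\tmean_r\n")
        for ci, c in enumerate(clusters, start=1):
            members = sorted(c.members)
            corr = correlation_matrix(matrix.loc[members]) if len(members) > 1 else None
            for g in members:
                if corr is not None:
                    mean_r = np.nanmean(corr.loc[g].drop(g).to_numpy())
                else:
                    mean_r = np.nan
                fh.write(f"C{ci}\t{g}\t{int(g in c.seeds)}\t{mean_r:.4f}\n")
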