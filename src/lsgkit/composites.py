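"""Co-occurring TFBS composites and promoter-set over-representation.

Two (or three) binding sites on one promoter form a composite when their
matrices are distinct, their intervals do not overlap, and every
consecutive inter-site gap — measured between nearest edges,
start_next - end_prev - 1 — lies within [d_min, d_max].  Ordered keys
(denoted A*B) respect positional order relative to the TSS; unordered keys
(A,B,C) are canonicalized by sorting matrix ids.  Site orientation is
ignored and each key counts at most once per promoter.

Over-representation of a key in a cluster promoter set against a
background promoter set is tested with the one-sided Fisher exact test
(hypergeometric tail), BH-corrected within each analysis family.
Significance additionally requires the key to be predicted in the
unmasked cluster promoters (a guard against repeat-driven hits) and the
composite to be observed at least ``min_cell`` times overall.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .motifscan import HitRecord


@dataclass
class CompositeConfig:
    arity: int = 2
    ordered: bool = True  # convention: pairs ordered, triplets unordered
    d_min: int = 20  # run separately for each of 20, 50, 100
    d_max: int = 250
    min_cell: int = 5
    alpha: float = 0.1  # BH-adjusted significance cutoff
    distance: str = "edge"  # or "start"
    min_cell_on: str = "total"  # "total" | "cluster" | "all"
    sided: str = "greater"  # or "two-sided"

    def __post_init__(self) -> None:
        if self.arity not in (2, 3):
            raise ValueError("arity must be 2 or 3")
        if not 0 <= self.d_min <= self.d_max:
            raise ValueError("require 0 <= d_min <= d_max")
        if self.distance not in ("edge", "start"):
            raise ValueError("distance must be 'edge' or 'start'")
        if self.min_cell_on not in ("total", "cluster", "all"):
            raise ValueError("min_cell_on must be total|cluster|all")


@dataclass(frozen=True)
class CompositeKey:
    ids: tuple[str, ...]
    ordered: bool
    d_min: int

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("composite matrix ids must be distinct")
        if not self.ordered and list(self.ids) != sorted(self.ids):
            raise ValueError("unordered keys must be sorted")

    @property
    def arity(self) -> int:
        return len(self.ids)

    def __str__(self) -> str:
        sep = "*" if self.ordered else ","
        return sep.join(self.ids)


@dataclass(frozen=True)
class ContingencyTable:
    k: int  # cluster promoters containing the key
    n: int  # cluster promoters total
    K: int  # background promoters containing the key
    N: int  # background promoters total

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n and 0 <= self.K <= self.N):
            raise ValueError(f"invalid contingency table {self}")


@dataclass
class EnrichmentResult:
    key: CompositeKey | str
    table: ContingencyTable
    p_raw: float
    p_adj: float = float("nan")
    passed_min_cell: bool = True
    unmasked_consistent: bool = True
    significant: bool = False


def _gap(prev: HitRecord, nxt: HitRecord, mode: str) -> int:
    if mode == "edge":
        return nxt.start - prev.end - 1
    return nxt.start - prev.start


def find_composites(hits: list[HitRecord], cfg: CompositeConfig) -> set[CompositeKey]:
    """All composite keys realized by the hit list of one promoter.

    Every tuple of ``arity`` hits with pairwise-distinct matrix ids,
    non-overlapping intervals and all consecutive gaps within
    [d_min, d_max] contributes its key; keys are de-duplicated per
    promoter.  Hits are taken in positional order on the promoter.
    """
    hits = sorted(hits, key=lambda h: (h.start, h.end, h.matrix_id))
    keys: set[CompositeKey] = set()
    for combo in itertools.combinations(hits, cfg.arity):
        ids = [h.matrix_id for h in combo]
        if len(set(ids)) != cfg.arity:
            continue
        ok = True
        for prev, nxt in zip(combo, combo[1:]):
            if nxt.start <= prev.end:  # overlapping or nested intervals
                ok = False
                break
            g = _gap(prev, nxt, cfg.distance)
            if not cfg.d_min <= g <= cfg.d_max:
                ok = False
                break
        if not ok:
            continue
        if cfg.ordered:
            keys.add(CompositeKey(tuple(ids), True, cfg.d_min))
        else:
            keys.add(CompositeKey(tuple(sorted(ids)), False, cfg.d_min))
    return keys


def composite_presence(
    hits_by_promoter: dict[str, list[HitRecord]], cfg: CompositeConfig
) -> dict[str, set[CompositeKey]]:
    return {pid: find_composites(h, cfg) for pid, h in hits_by_promoter.items()}


def count_composites(
    cluster_hits: dict[str, list[HitRecord]],
    background_hits: dict[str, list[HitRecord]],
    cfg: CompositeConfig,
) -> dict[CompositeKey, ContingencyTable]:
    """Promoter counts (not occurrence counts) for every key seen in the cluster."""
    if not cluster_hits:
        raise ValueError("empty cluster promoter set")
    fg = composite_presence(cluster_hits, cfg)
    bg = composite_presence(background_hits, cfg)
    n, N = len(fg), len(bg)
    tables: dict[CompositeKey, ContingencyTable] = {}
    cluster_keys = set().union(*fg.values()) if fg else set()
    for key in cluster_keys:
        k = sum(key in s for s in fg.values())
        K = sum(key in s for s in bg.values())
        tables[key] = ContingencyTable(k=k, n=n, K=K, N=N)
    return tables


def fisher_enrichment(t: ContingencyTable, sided: str = "greater") -> float:
    """One-sided Fisher exact (hypergeometric tail) enrichment p-value.

    P(X >= k) for X ~ Hypergeometric(population n+N, successes k+K,
    draws n).  ``sided='two-sided'`` gives the standard two-sided FET.
    """
    if sided == "greater":
        return float(hypergeom.sf(t.k - 1, t.n + t.N, t.k + t.K, t.n))
    if sided == "two-sided":
        from scipy.stats import fisher_exact

        table = [[t.k, t.n - t.k], [t.K, t.N - t.K]]
        return float(fisher_exact(table, alternative="two-sided")[1])
    raise ValueError(f"unknown sidedness {sided!r}")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def apply_filters(
    tables: dict[CompositeKey, ContingencyTable],
    cfg: CompositeConfig,
    unmasked_cluster_keys: set[CompositeKey] | None = None,
) -> list[EnrichmentResult]:
    """Score, BH-adjust and flag every tabulated key.

    The minimum-cell rule (default: k + K >= min_cell overall) gates which
    comparisons enter the BH family.  A key is significant when its
    adjusted p <= alpha, it passed the minimum-cell rule, and — when an
    unmasked analysis is supplied — it was also predicted in the unmasked
    cluster promoters.
    """
    results: list[EnrichmentResult] = []
    for key in sorted(tables, key=str):
        t = tables[key]
        if cfg.min_cell_on == "total":
            passed = (t.k + t.K) >= cfg.min_cell
        elif cfg.min_cell_on == "cluster":
            passed = t.k >= cfg.min_cell
        else:  # "all": every cell of the 2x2 table
            passed = min(t.k, t.n - t.k, t.K, t.N - t.K) >= cfg.min_cell
        consistent = (
            True if unmasked_cluster_keys is None else key in unmasked_cluster_keys
        )
        results.append(
            EnrichmentResult(
                key=key,
                table=t,
                p_raw=fisher_enrichment(t, cfg.sided),
                passed_min_cell=passed,
                unmasked_consistent=consistent,
            )
        )
    tested = [r for r in results if r.passed_min_cell]
    if tested:
        adj = bh_adjust([r.p_raw for r in tested])
        for r, a in zip(tested, adj):
            r.p_adj = float(a)
            r.significant = bool(a <= cfg.alpha and r.unmasked_consistent)
    return results


def enrich_composites(
    cluster_hits: dict[str, list[HitRecord]],
    background_hits: dict[str, list[HitRecord]],
    cfg: CompositeConfig,
    unmasked_cluster_hits: dict[str, list[HitRecord]] | None = None,
) -> list[EnrichmentResult]:
    """count -> fisher -> BH -> flags, for one (arity, order, d_min) family."""
    tables = count_composites(cluster_hits, background_hits, cfg)
    unmasked_keys = None
    if unmasked_cluster_hits is not None:
        pres = composite_presence(unmasked_cluster_hits, cfg)
        unmasked_keys = set().union(*pres.values()) if pres else set()
    return apply_filters(tables, cfg, unmasked_keys)


def single_tfbs_enrichment(
    cluster_presence: dict[str, set[str]],
    background_presence: dict[str, set[str]],
    cfg: CompositeConfig | None = None,
    unmasked_cluster_presence: dict[str, set[str]] | None = None,
) -> list[EnrichmentResult]:
    """Per-matrix over-representation: 2x2 FET + BH, no distance machinery.

    Only matrices present in at least one cluster promoter are tested.
    """
    cfg = cfg or CompositeConfig(min_cell=0)
    if not cluster_presence:
        raise ValueError("empty cluster promoter set")
    n, N = len(cluster_presence), len(background_presence)
    matrices = sorted(set().union(*cluster_presence.values()))
    results: list[EnrichmentResult] = []
    unmasked_ids = None
    if unmasked_cluster_presence is not None:
        unmasked_ids = set().union(*unmasked_cluster_presence.values()) if unmasked_cluster_presence else set()
    for m in matrices:
        k = sum(m in s for s in cluster_presence.values())
        K = sum(m in s for s in background_presence.values())
        t = ContingencyTable(k=k, n=n, K=K, N=N)
        passed = (t.k + t.K) >= cfg.min_cell if cfg.min_cell_on == "total" else t.k >= cfg.min_cell
        results.append(
            EnrichmentResult(
                key=m,
                table=t,
                p_raw=fisher_enrichment(t, cfg.sided),
                passed_min_cell=passed,
                unmasked_consistent=True if unmasked_ids is None else m in unmasked_ids,
            )
        )
    tested = [r for r in results if r.passed_min_cell]
    if tested:
        adj = bh_adjust([r.p_raw for r in tested])
        for r, a in zip(tested, adj):
            r.p_adj = float(a)
            r.significant = bool(a <= cfg.alpha and r.unmasked_consistent)
    return results


def write_enrichment_tsv(results: list[EnrichmentResult], path, d_min=None) -> None:
    """TSV: key, distance class, k/n/K/N, raw and adjusted p, flags."""
    with open(path, "w") as fh:
        fh.write("key\td_min\tk\tn\tK\tN\tp_raw\tp_adj\tmin_cell\tunmasked\tsignificant\n")
        for r in results:
            dc = getattr(r.key, "d_min", d_min)
            fh.write(
                f"{r.key}\t{dc if dc is not None else '.'}\t{r.table.k}\t{r.table.n}\t"
                f"{r.table.K}\t{r.table.N}\t{r.p_raw:.6g}\t{r.p_adj:.6g}\t"
                f"{int(r.passed_min_cell)}\t{int(r.unmasked_consistent)}\t{int(r.significant)}\n"
            )
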