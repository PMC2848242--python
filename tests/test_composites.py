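"""Composite enumeration against brute force; Fisher/BH oracles."""

import itertools
import math

import numpy as np
import pytest

from lsgkit.composites import (
    CompositeConfig,
    CompositeKey,
    ContingencyTable,
    bh_adjust,
    count_composites,
    enrich_composites,
    find_composites,
    fisher_enrichment,
    apply_filters,
    single_tfbs_enrichment,
)
from lsgkit.motifscan import HitRecord


def hit(matrix, start, end, promoter="p"):
    return HitRecord(promoter, matrix, start, end, "+", 1.0, 1.0)


def brute_force_keys(hits, cfg: CompositeConfig):
    """Independent enumeration over every hit tuple in positional order."""
    keys = set()
    for combo in itertools.permutations(hits, cfg.arity):
        if any(b.start < a.start or (b.start == a.start and b.end < a.end)
               for a, b in zip(combo, combo[1:])):
            continue  # only positional order
        ids = [h.matrix_id for h in combo]
        if len(set(ids)) != cfg.arity:
            continue
        ok = True
        for a, b in zip(combo, combo[1:]):
            if b.start <= a.end:
                ok = False
                break
            gap = b.start - a.end - 1 if cfg.distance == "edge" else b.start - a.start
            if not (cfg.d_min <= gap <= cfg.d_max):
                ok = False
                break
        if not ok:
            continue
        ids_t = tuple(ids) if cfg.ordered else tuple(sorted(ids))
        keys.add(CompositeKey(ids_t, cfg.ordered, cfg.d_min))
    return keys


class TestFindComposites:
    def test_gap_arithmetic_boundaries(self):
        hits = [hit("A", 90, 100), hit("B", 121, 130)]  # gap 20
        k20 = find_composites(hits, CompositeConfig(d_min=20))
        assert {str(k) for k in k20} == {"A*B"}
        assert find_composites(hits, CompositeConfig(d_min=50)) == set()

    def test_gap_over_maximum_excluded(self):
        hits = [hit("A", 90, 100), hit("B", 352, 360)]  # gap 251
        assert find_composites(hits, CompositeConfig(d_min=20)) == set()

    def test_triplet_worked_example(self):
        hits = [hit("B", 10, 17), hit("A", 60, 65), hit("C", 300, 307)]
        # gaps: B->A 42, A->C 234, B->C 282
        trip = find_composites(
            hits, CompositeConfig(arity=3, ordered=False, d_min=20)
        )
        assert {str(k) for k in trip} == {"A,B,C"}
        pairs = find_composites(hits, CompositeConfig(arity=2, ordered=True, d_min=20))
        assert {str(k) for k in pairs} == {"B*A", "A*C"}

    def test_overlapping_hits_never_pair(self):
        hits = [hit("A", 10, 20), hit("B", 15, 25)]
        assert find_composites(hits, CompositeConfig(d_min=0)) == set()

    def test_key_counted_once_per_promoter(self):
        hits = [hit("A", 1, 8), hit("B", 40, 47), hit("A", 100, 107), hit("B", 140, 147)]
        keys = find_composites(hits, CompositeConfig(d_min=20))
        assert sum(1 for k in keys if str(k) == "A*B") == 1

    @pytest.mark.parametrize("arity,ordered", [(2, True), (2, False), (3, True), (3, False)])
    @pytest.mark.parametrize("d_min", [20, 50, 100])
    def test_equals_bruteforce_on_random_hitsets(self, rng, arity, ordered, d_min):
        cfg = CompositeConfig(arity=arity, ordered=ordered, d_min=d_min)
        for _ in range(30):
            hits = []
            pos = 1
            for _h in range(int(rng.integers(0, 9))):
                pos += int(rng.integers(1, 120))
                w = int(rng.integers(6, 13))
                hits.append(hit(f"M{rng.integers(1, 5)}", pos, pos + w - 1))
            assert find_composites(hits, cfg) == brute_force_keys(hits, cfg)

    def test_ordered_keys_canonicalize_to_unordered(self, rng):
        for _ in range(20):
            hits = []
            pos = 1
            for _h in range(6):
                pos += int(rng.integers(10, 150))
                hits.append(hit(f"M{rng.integers(1, 5)}", pos, pos + 7))
            ordered = find_composites(hits, CompositeConfig(arity=2, ordered=True, d_min=20))
            unordered = find_composites(hits, CompositeConfig(arity=2, ordered=False, d_min=20))
            un_ids = {k.ids for k in unordered}
            assert all(tuple(sorted(k.ids)) in un_ids for k in ordered)


def hypergeom_tail_oracle(k, n, K, N):
    """P(X >= k), X ~ Hypergeom(N+n total, K+k successes, n draws)."""
    total, succ, draws = n + N, k + K, n
    denom = math.comb(total, draws)
    return sum(
        math.comb(succ, x) * math.comb(total - succ, draws - x)
        for x in range(k, min(succ, draws) + 1)
    ) / denom


class TestFisher:
    def test_k_zero_gives_one(self):
        assert fisher_enrichment(ContingencyTable(0, 10, 5, 100)) == 1.0

    def test_extreme_table_single_term(self):
        t = ContingencyTable(k=5, n=5, K=0, N=20)
        expected = math.comb(5, 5) * math.comb(20, 0) / math.comb(25, 5)
        assert fisher_enrichment(t) == pytest.approx(expected, abs=1e-12)

    def test_worked_tail_sum(self):
        t = ContingencyTable(k=6, n=10, K=10, N=100)
        assert fisher_enrichment(t) == pytest.approx(
            hypergeom_tail_oracle(6, 10, 10, 100), abs=1e-12
        )

    def test_exhaustive_small_tables(self):
        """All tables with n+N <= 60 agree with the tail-sum oracle."""
        for n in range(1, 30):
            for N in range(1, 61 - n):
                for k in range(0, n + 1, max(1, n // 4)):
                    for K in range(0, N + 1, max(1, N // 4)):
                        t = ContingencyTable(k, n, K, N)
                        assert fisher_enrichment(t) == pytest.approx(
                            hypergeom_tail_oracle(k, n, K, N), abs=1e-12
                        )


def textbook_bh(p):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


class TestBH:
    def test_closed_form_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_matches_textbook_implementation(self, rng):
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_adjust(p), textbook_bh(list(p)), atol=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestEnrichmentFilters:
    def _tables(self):
        key_a = CompositeKey(("A", "B"), True, 20)
        key_b = CompositeKey(("B", "A"), True, 20)
        return {
            key_a: ContingencyTable(40, 100, 50, 1000),
            key_b: ContingencyTable(2, 100, 30, 1000),
        }

    def test_unmasked_consistency_required(self):
        tables = self._tables()
        res = apply_filters(tables, CompositeConfig(), unmasked_cluster_keys=set())
        assert all(not r.significant for r in res)
        res2 = apply_filters(tables, CompositeConfig(), unmasked_cluster_keys=set(tables))
        sig = {str(r.key) for r in res2 if r.significant}
        assert "A*B" in sig

    def test_min_cell_rule(self):
        key = CompositeKey(("A", "B"), True, 20)
        tables = {key: ContingencyTable(2, 10, 1, 100)}
        res = apply_filters(tables, CompositeConfig(min_cell=5))
        assert not res[0].passed_min_cell
        assert np.isnan(res[0].p_adj)

    def test_alpha_boundary(self):
        key = CompositeKey(("A", "B"), True, 20)
        tables = {key: ContingencyTable(10, 100, 80, 1000)}
        res = apply_filters(tables, CompositeConfig(alpha=0.1))
        assert res[0].p_adj > 0.1 and not res[0].significant


class TestSingleTFBS:
    def test_monotone_most_enriched_matrix(self):
        cluster = {f"c{i}": {"X", "Y"} if i < 9 else {"Y"} for i in range(10)}
        bg = {f"b{i}": ({"X"} if i < 2 else set()) | {"Y"} for i in range(100)}
        res = single_tfbs_enrichment(cluster, bg)
        best = min(res, key=lambda r: r.p_raw)
        assert best.key == "X"

    def test_absent_matrix_untested(self):
        cluster = {"c1": {"X"}}
        bg = {"b1": {"X", "Z"}, "b2": {"Z"}}
        res = single_tfbs_enrichment(cluster, bg)
        assert {r.key for r in res} == {"X"}

    def test_null_rates_not_significant(self, rng):
        """Identical cluster/background rates: adjusted p near 1."""
        adjs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            cluster = {f"c{i}": {m for m in "ABCDE" if r.random() < 0.3} for i in range(50)}
            bg = {f"b{i}": {m for m in "ABCDE" if r.random() < 0.3} for i in range(500)}
            res = single_tfbs_enrichment(cluster, bg)
            adjs.extend(r2.p_adj for r2 in res if np.isfinite(r2.p_adj))
        assert np.mean(adjs) > 0.5
        assert np.mean([a <= 0.1 for a in adjs]) < 0.05


def test_count_composites_empty_cluster_errors():
    with pytest.raises(ValueError):
        count_composites({}, {"b": []}, CompositeConfig())


def test_count_composites_promoter_counts(rng):
    cfg = CompositeConfig(d_min=20)
    fg = {
        "p1": [hit("A", 1, 8, "p1"), hit("B", 40, 47, "p1")],
        "p2": [hit("A", 1, 8, "p2"), hit("B", 40, 47, "p2"), hit("A", 100, 107, "p2"), hit("B", 150, 157, "p2")],
        "p3": [],
    }
    bg = {"b1": [hit("A", 1, 8, "b1"), hit("B", 40, 47, "b1")], "b2": []}
    tables = count_composites(fg, bg, cfg)
    key = next(k for k in tables if str(k) == "A*B")
    t = tables[key]
    assert (t.k, t.n, t.K, t.N) == (2, 3, 1, 2)  # promoters, not occurrences
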