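"""Inverse-overlap tests, knowledge-graph relation discovery, direction
cross-tabulation and the 2x2 chi-square."""
import itertools
import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from mirmint.integration import (
    SHORTEST,
    SHORTEST_PLUS_ONE,
    ContingencyTable2x2,
    RelationRecord,
    chi_square_2x2,
    direction_table,
    find_relations,
    inverse_overlap,
    relation_degree,
)
from mirmint.synthetic import SimulationConfig, simulate_study


def brute_force_relations(graph, demirnas, degs, mode):
    """Oracle: enumerate all simple paths of length <= 2 per pair."""
    out = {}
    for m in demirnas:
        if m not in graph:
            continue
        for g in degs:
            if g == m or g not in graph:
                continue
            direct = graph.has_edge(m, g)
            inters = sorted(
                v for v in graph.nodes
                if v not in (m, g) and graph.has_edge(m, v) and graph.has_edge(v, g)
            )
            if direct:
                out[(m, g)] = (1, None)
            elif mode == SHORTEST_PLUS_ONE and inters:
                out[(m, g)] = (2, inters[0])
    return out


class TestFindRelations:
    def test_single_direct_edge_found_in_both_modes(self):
        g = nx.DiGraph()
        g.add_edge("m1", "g1")
        for mode in (SHORTEST, SHORTEST_PLUS_ONE):
            recs = find_relations(g, {"m1": "up"}, {"g1": "down"}, mode=mode)
            assert len(recs) == 1
            assert recs[0].path_length == 1 and recs[0].intermediate is None

    def test_intermediate_only_pair_needs_plus_one_mode(self):
        g = nx.DiGraph()
        g.add_edge("m1", "R")
        g.add_edge("R", "g1")
        assert find_relations(g, {"m1": "up"}, {"g1": "down"}, mode=SHORTEST) == []
        recs = find_relations(g, {"m1": "up"}, {"g1": "down"}, mode=SHORTEST_PLUS_ONE)
        assert len(recs) == 1
        assert recs[0].path_length == 2 and recs[0].intermediate == "R"

    def test_smallest_intermediate_reported(self):
        g = nx.DiGraph()
        for r in ("Rb", "Ra", "Rc"):
            g.add_edge("m1", r)
            g.add_edge(r, "g1")
        recs = find_relations(g, {"m1": "up"}, {"g1": "up"}, mode=SHORTEST_PLUS_ONE)
        assert recs[0].intermediate == "Ra"

    def test_missing_query_nodes_skipped(self):
        g = nx.DiGraph()
        g.add_edge("m1", "g1")
        recs = find_relations(g, {"m1": "up", "mX": "down"}, {"g1": "up", "gX": "down"})
        assert len(recs) == 1

    @pytest.mark.parametrize("mode", [SHORTEST, SHORTEST_PLUS_ONE])
    def test_matches_bruteforce_path_oracle(self, mode, rng):
        g = nx.gnp_random_graph(60, 0.06, seed=17, directed=True)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        nodes = sorted(g.nodes)
        demirnas = {n: ("up" if i % 2 else "down") for i, n in enumerate(nodes[:15])}
        degs = {n: ("up" if i % 3 else "down") for i, n in enumerate(nodes[30:50])}
        recs = find_relations(g, demirnas, degs, mode=mode)
        oracle = brute_force_relations(g, demirnas, degs, mode)
        got = {(r.mirna, r.gene): (r.path_length, r.intermediate) for r in recs}
        assert got == oracle

    def test_insertion_order_invariance(self):
        edges = [("m1", "g2"), ("m2", "g1"), ("m1", "R"), ("R", "g1")]
        g1 = nx.DiGraph(edges)
        g2 = nx.DiGraph(edges[::-1])
        dm = {"m1": "up", "m2": "down"}
        dg = {"g1": "down", "g2": "up"}
        r1 = find_relations(g1, dm, dg, mode=SHORTEST_PLUS_ONE)
        r2 = find_relations(g2, dm, dg, mode=SHORTEST_PLUS_ONE)
        assert r1 == r2
        assert [(r.mirna, r.gene) for r in r1] == sorted((r.mirna, r.gene) for r in r1)


class TestDirectionTable:
    def _recs(self, counts):
        """counts: {(mdir, gdir): n} -> unique RelationRecords."""
        recs = []
        i = 0
        for (md, gd), n in counts.items():
            for _ in range(n):
                recs.append(RelationRecord(f"m{i}", md, f"g{i}", gd, 1))
                i += 1
        return recs

    def test_printed_configuration_shares(self):
        # 53 up->down of 92 unique relations is 57.61%
        recs = self._recs({("up", "down"): 53, ("down", "up"): 37,
                           ("up", "up"): 1, ("down", "down"): 1})
        t = direction_table(recs)
        assert t.total == 92
        pct = t.percentages()
        assert pct[0, 1] == pytest.approx(57.61, abs=0.01)
        assert pct[1, 0] == pytest.approx(40.22, abs=0.01)

    def test_single_cell_hundred_percent(self):
        t = direction_table(self._recs({("up", "down"): 7}))
        assert t.percentages()[0, 1] == 100.0

    def test_flipping_mirna_directions_swaps_rows(self):
        counts = {("up", "down"): 5, ("down", "up"): 3, ("up", "up"): 2}
        t1 = direction_table(self._recs(counts))
        flipped = {(("down" if md == "up" else "up"), gd): n
                   for (md, gd), n in counts.items()}
        t2 = direction_table(self._recs(flipped))
        assert np.array_equal(t1.observed[::-1], t2.observed)

    def test_duplicate_pairs_collapse(self):
        recs = [RelationRecord("m1", "up", "g1", "down", 1),
                RelationRecord("m1", "up", "g1", "down", 2, intermediate="R")]
        t = direction_table(recs)
        assert t.total == 1

    def test_cells_sum_to_relation_count_and_percent_to_100(self, rng):
        recs = self._recs({("up", "down"): 11, ("down", "up"): 6,
                           ("up", "up"): 4, ("down", "down"): 2})
        t = direction_table(recs)
        assert t.observed.sum() == len(recs)
        assert t.percentages().sum() == pytest.approx(100.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            direction_table([])


class TestChiSquare:
    def test_perfect_independence(self):
        t = ContingencyTable2x2(np.array([[10, 10], [10, 10]]))
        res = chi_square_2x2(t, continuity_correction=False)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_yates_on_strong_inverse_table(self):
        # [[1,53],[37,1]] with continuity correction, hand-derivable
        res = chi_square_2x2(ContingencyTable2x2(np.array([[1, 53], [37, 1]])))
        assert res.statistic == pytest.approx(80.042, abs=0.05)
        assert res.df == 1 and res.p < 1e-15

    def test_uncorrected_equals_cross_product_identity(self, rng):
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 40, size=4)
            t = ContingencyTable2x2(np.array([[a, b], [c, d]], dtype=float))
            res = chi_square_2x2(t, continuity_correction=False)
            n = a + b + c + d
            oracle = (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
            assert res.statistic == pytest.approx(oracle)

    def test_agrees_with_scipy_contingency(self, rng):
        for correction in (False, True):
            obs = np.array([[8, 25], [30, 9]], dtype=float)
            res = chi_square_2x2(ContingencyTable2x2(obs), continuity_correction=correction)
            ref = stats.chi2_contingency(obs, correction=correction)
            assert res.statistic == pytest.approx(ref.statistic)
            assert res.p == pytest.approx(ref.pvalue)
            assert np.allclose(res.expected, ref.expected_freq)

    def test_correction_never_increases_statistic(self, rng):
        for _ in range(100):
            a, b, c, d = rng.integers(1, 30, size=4)
            t = ContingencyTable2x2(np.array([[a, b], [c, d]], dtype=float))
            with_c = chi_square_2x2(t, continuity_correction=True).statistic
            without = chi_square_2x2(t, continuity_correction=False).statistic
            assert with_c <= without + 1e-12

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(ContingencyTable2x2(np.array([[0, 0], [5, 5]])))


class TestInverseOverlap:
    def test_planted_inverse_pairs_all_present_when_certain(self):
        cfg = SimulationConfig(n_mirnas=40, n_genes=300, p_target_true=1.0,
                               target_map_density=0.01, seed=6)
        s = simulate_study(cfg)
        res = inverse_overlap(
            s.truth.de_genes_up, s.truth.de_genes_down,
            s.truth.de_mirnas_up, s.truth.de_mirnas_down,
            s.target_map, set(s.truth.gene_ids),
        )
        up_res = res["mirna_up_targets_vs_degs_down"]
        assert set(up_res.overlap_genes) >= s.truth.de_genes_down

    def test_disjoint_targets_and_degs_give_null_result(self):
        bg = {"t1", "t2", "d1", "d2"}
        res = inverse_overlap(set(), {"d1"}, {"m1"}, set(), {"m1": {"t1"}}, bg)
        r = res["mirna_up_targets_vs_degs_down"]
        assert r.k == 0 and r.p == 1.0

    def test_known_counts_match_enumeration(self):
        # N=100, K=10, n=20, k=5 against direct pmf summation
        bg = [f"g{i}" for i in range(100)]
        degs_down = set(bg[:10])
        targets = set(bg[:5]) | set(bg[50:65])  # 20 targets, 5 overlap
        tm = {"m1": targets}
        res = inverse_overlap(set(), degs_down, {"m1"}, set(), tm, set(bg))
        r = res["mirna_up_targets_vs_degs_down"]
        assert (r.k, r.K, r.n, r.N) == (5, 10, 20, 100)
        oracle = sum(
            math.comb(10, i) * math.comb(90, 20 - i) / math.comb(100, 20)
            for i in range(5, 11)
        )
        assert r.p == pytest.approx(oracle)

    def test_overlapping_direction_sets_rejected(self):
        with pytest.raises(ValueError):
            inverse_overlap({"a"}, {"a"}, set(), set(), {}, {"a"})


class TestRelationDegree:
    def test_counts_unique_pairs_per_mirna(self):
        recs = [
            RelationRecord("m1", "up", "g1", "down", 1),
            RelationRecord("m1", "up", "g2", "down", 1),
            RelationRecord("m1", "up", "g2", "down", 2, intermediate="R"),
            RelationRecord("m2", "down", "g1", "up", 1),
        ]
        assert relation_degree(recs) == {"m1": 2, "m2": 1}
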