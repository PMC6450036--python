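"""Cell-type inference: medians, CTA scores, hypergeometric test, BH, calls."""

import itertools
import math

import numpy as np
import pytest

from celltyper import (
    ClusterAssignment,
    MarkerRecord,
    MarkerTable,
    annotate_cluster,
    annotate_sample,
    bh_adjust,
    cluster_medians,
    cluster_p_value,
    cta_score,
    gene_frequency,
    normalize_counts,
)
from celltyper.simulate import marker_table_with_frequencies

from conftest import make_matrix, make_profile


def hypergeom_tail_oracle(M: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by direct summation of the hypergeometric pmf (math.comb)."""
    total = math.comb(M, n)
    return sum(
        math.comb(K, j) * math.comb(M - K, n - j)
        for j in range(k, min(n, K) + 1)
    ) / total


def bh_oracle(p):
    """Reference BH step-up: sorted p * n/rank, cumulative min from the top."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adjusted = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted


def profile_with_overlap(M, K, n, k):
    """Universe of M genes, first K are markers, n expressed with overlap k."""
    genes = [f"u{i:02d}" for i in range(M)]
    expressed = set(genes[:k]) | set(genes[K:K + (n - k)])
    assert len(expressed) == n
    profile = make_profile({g: (1.0 if g in expressed else 0.0) for g in genes})
    table = MarkerTable([
        MarkerRecord(species="Mm", gene_symbol=g, cell_type="T")
        for g in genes[:K]
    ])
    return profile, table


class TestClusterMedians:
    @staticmethod
    def _profiles(dense, clusters):
        m = make_matrix(dense)
        assign = ClusterAssignment(dict(zip(m.cells, clusters)))
        # bypass normalization: treat counts as already-normalized values
        from celltyper.qc import NormalizedMatrix
        norm = NormalizedMatrix(genes=m.genes, cells=m.cells,
                                values=m.counts.astype(float))
        return cluster_medians(norm, assign)

    def test_identical_cells_give_member_profile(self):
        (p,) = self._profiles([[3, 3, 3], [1, 1, 1]], [0, 0, 0])
        assert p.median_expression == {"g0": 3.0, "g1": 1.0}
        assert p.n_cells == 3

    def test_odd_cluster_order_statistic(self):
        (p,) = self._profiles([[0, 0, 0, 5, 9]], [0] * 5)
        assert p.median_expression["g0"] == 0.0

    def test_even_cluster_uses_midpoint(self):
        (p,) = self._profiles([[1, 3]], [0, 0])
        assert p.median_expression["g0"] == 2.0

    def test_unknown_barcode_is_error(self):
        m = make_matrix([[1]])
        from celltyper.qc import NormalizedMatrix
        norm = NormalizedMatrix(genes=m.genes, cells=m.cells,
                                values=m.counts.astype(float))
        with pytest.raises(ValueError, match="absent"):
            cluster_medians(norm, ClusterAssignment({"ghost": 0}))


class TestCtaScore:
    def test_all_markers_silent_scores_zero(self, tiny_table):
        freq = gene_frequency(tiny_table)
        profile = make_profile({g: 0.0 for g in tiny_table.genes})
        assert cta_score(profile, "Alpha", tiny_table, freq) == 0.0

    def test_eight_unit_markers_weight_one(self):
        # A's 8 markers each appear in 2 cell types (f = f_max = 2 -> w = 1);
        # one extra singleton gene sets f_min = 1.
        records = []
        for i in range(8):
            records.append(MarkerRecord(species="Mm", gene_symbol=f"m{i}",
                                        cell_type="A"))
            records.append(MarkerRecord(species="Mm", gene_symbol=f"m{i}",
                                        cell_type=f"Other{i}"))
        records.append(MarkerRecord(species="Mm", gene_symbol="solo",
                                    cell_type="Solo"))
        table = MarkerTable(records)
        freq = gene_frequency(table)
        profile = make_profile({f"m{i}": 1.0 for i in range(8)})
        assert cta_score(profile, "A", table, freq) == pytest.approx(4.0)

    def test_single_marker_with_weight_1_5(self):
        # w(g) = 1.5 needs (f_max - f)/(f_max - f_min) = 1/4: f=4 in [1, 5];
        # the frequency table and the scored one-marker cell type are separate
        freq = gene_frequency(
            marker_table_with_frequencies({"g": 4, "broad": 5, "rare": 1})
        )
        one = MarkerTable([
            MarkerRecord(species="Mm", gene_symbol="g", cell_type="Only")
        ])
        profile = make_profile({"g": 3.5})
        assert cta_score(profile, "Only", one, freq) == pytest.approx(5.25)

    def test_absent_marker_counts_in_denominator(self, tiny_table):
        freq = gene_frequency(tiny_table)
        # Alpha has 3 markers; only Gene1 (f=1 -> w=2) is on the matrix axis
        profile = make_profile({"Gene1": 2.0})
        expected = (2.0 * 2.0) / 3 ** (1 / 3)
        assert cta_score(profile, "Alpha", tiny_table, freq) == pytest.approx(expected)

    def test_linear_in_profile_and_winner_stable(self, tiny_table):
        freq = gene_frequency(tiny_table)
        base = make_profile({"Gene1": 1.0, "Gene3": 0.5, "Gene4": 0.2})
        scaled = make_profile({g: 3.0 * v
                               for g, v in base.median_expression.items()})
        for ct in tiny_table.cell_types:
            assert cta_score(scaled, ct, tiny_table, freq) == pytest.approx(
                3.0 * cta_score(base, ct, tiny_table, freq)
            )

    def test_adding_silent_marker_decreases_score(self):
        table = MarkerTable([
            MarkerRecord(species="Mm", gene_symbol="a", cell_type="T"),
        ])
        bigger = MarkerTable(table.records + [
            MarkerRecord(species="Mm", gene_symbol="never", cell_type="T"),
        ])
        profile = make_profile({"a": 1.0})
        s1 = cta_score(profile, "T", table, gene_frequency(table))
        s2 = cta_score(profile, "T", bigger, gene_frequency(bigger))
        assert s2 < s1

    def test_unknown_cell_type_is_error(self, tiny_table):
        freq = gene_frequency(tiny_table)
        with pytest.raises(KeyError):
            cta_score(make_profile({"Gene1": 1.0}), "Nope", tiny_table, freq)


class TestClusterPValue:
    def test_perfect_overlap_universe_10(self):
        profile, table = profile_with_overlap(M=10, K=5, n=5, k=5)
        p = cluster_p_value(profile, "T", table)
        assert p == pytest.approx(1 / math.comb(10, 5))

    def test_zero_overlap_is_one(self):
        profile, table = profile_with_overlap(M=10, K=3, n=4, k=0)
        assert cluster_p_value(profile, "T", table) == pytest.approx(1.0)

    def test_universe_4_overlap_1(self):
        profile, table = profile_with_overlap(M=4, K=2, n=2, k=1)
        assert cluster_p_value(profile, "T", table) == pytest.approx(5 / 6)

    def test_matches_comb_oracle_small_universes(self):
        for M in (3, 6, 9, 12):
            for K in range(1, M + 1):
                for n in range(0, M + 1):
                    for k in range(max(0, n + K - M), min(n, K) + 1):
                        profile, table = profile_with_overlap(M, K, n, k)
                        assert cluster_p_value(profile, "T", table) == pytest.approx(
                            hypergeom_tail_oracle(M, K, n, k)
                        ), (M, K, n, k)

    def test_oracle_agrees_with_literal_draw_enumeration(self):
        # validates the comb-sum oracle itself: enumerate every n-subset of
        # the universe and count those with >= k marker overlaps
        for M, K, n, k in [(6, 3, 4, 2), (8, 4, 5, 3), (9, 2, 6, 1)]:
            markers = set(range(K))
            hits = total = 0
            for draw in itertools.combinations(range(M), n):
                total += 1
                hits += len(markers & set(draw)) >= k
            assert hits / total == pytest.approx(hypergeom_tail_oracle(M, K, n, k))


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == [pytest.approx(0.2)]

    def test_step_up_cumulative_minimum(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_reference_step_up(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40)).tolist()
            assert bh_adjust(p) == pytest.approx(bh_oracle(p))
        # output is component-wise >= input and <= 1
        p = rng.random(50).tolist()
        q = bh_adjust(p)
        assert all(qi >= pi and qi <= 1.0 for pi, qi in zip(p, q))


class TestAnnotateCluster:
    def test_unique_expressed_type_wins(self, tiny_table):
        # only Alpha's exclusive markers are on; large silent background
        values = {f"bg{i}": 0.0 for i in range(100)}
        values.update({"Gene1": 3.0, "Gene2": 2.0, "Gene3": 0.0, "Gene4": 0.0})
        call = annotate_cluster(make_profile(values), tiny_table)
        assert call.label == "Alpha"
        assert call.ranked_scores[0].cell_type == "Alpha"

    def test_all_zero_profile_is_unknown(self, tiny_table):
        values = {g: 0.0 for g in tiny_table.genes}
        call = annotate_cluster(make_profile(values), tiny_table)
        assert call.label == "Unknown"
        assert all(s.cta == 0.0 and s.p_value == 1.0
                   for s in call.ranked_scores)

    def test_identical_marker_sets_break_alphabetically(self):
        table = MarkerTable([
            MarkerRecord(species="Mm", gene_symbol="g", cell_type="Zeta"),
            MarkerRecord(species="Mm", gene_symbol="g", cell_type="Beta"),
        ])
        values = {"g": 1.0}
        values.update({f"bg{i}": 0.0 for i in range(50)})
        call = annotate_cluster(make_profile(values), table)
        top, second = call.ranked_scores[:2]
        assert top.cta == second.cta
        assert top.cell_type == "Beta"


class TestAnnotateSample:
    @staticmethod
    def _three_cluster_fixture(tiny_table):
        genes = sorted(tiny_table.genes) + [f"bg{i}" for i in range(60)]
        plan = {0: {"Gene1", "Gene2"}, 1: {"Gene3", "Gene4"},
                2: {"Gene5", "Gene6"}}
        cols, barcodes, assign = [], [], {}
        for cid, on_genes in plan.items():
            for j in range(12):
                b = f"c{cid}_{j:02d}"
                barcodes.append(b)
                assign[b] = cid
                cols.append([2000 if g in on_genes else
                             (1 if g == "bg0" else 0) for g in genes])
        m = make_matrix(np.array(cols).T, genes=genes, cells=barcodes)
        return m, ClusterAssignment(assign)

    def test_planted_types_recovered(self, tiny_table):
        m, assign = self._three_cluster_fixture(tiny_table)
        calls = annotate_sample(normalize_counts(m), assign, tiny_table)
        assert [c.label for c in calls] == ["Alpha", "Beta", "Gamma"]

    def test_invariant_to_cell_order(self, tiny_table):
        m, assign = self._three_cluster_fixture(tiny_table)
        perm = np.random.default_rng(3).permutation(m.n_cells)
        m2 = m.subset_cells(perm)
        calls1 = annotate_sample(normalize_counts(m), assign, tiny_table)
        calls2 = annotate_sample(normalize_counts(m2), assign, tiny_table)
        for a, b in zip(calls1, calls2):
            assert a.label == b.label
            assert a.winner.cta == pytest.approx(b.winner.cta)

    def test_no_marker_overlap_is_unknown(self, tiny_table):
        genes = [f"x{i}" for i in range(30)]
        m = make_matrix(np.full((30, 12), 10), genes=genes)
        assign = ClusterAssignment({c: 0 for c in m.cells})
        calls = annotate_sample(normalize_counts(m), assign, tiny_table)
        assert [c.label for c in calls] == ["Unknown"]
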