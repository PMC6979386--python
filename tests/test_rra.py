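import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import beta

import perturbrank as pr
from perturbrank.rra import CellRanking

from conftest import prepare


def make_ranking(M, direction="descending", zero=(), marker="m"):
    return CellRanking(
        marker_id=marker,
        direction=direction,
        ranks=np.arange(1, M + 1),
        zero_flags=np.isin(np.arange(M), list(zero)),
        cell_ids=np.array([f"c{i}" for i in range(M)], dtype=object),
    )


class TestRankCells:
    def make_matrices(self, values, raw_counts):
        cells = [f"c{i + 1}" for i in range(len(values))]
        scaled = pr.ExpressionMatrix(
            np.array(values, float).reshape(-1, 1), cells, ["m"], "scaled"
        )
        raw = pr.ExpressionMatrix(
            np.array(raw_counts).reshape(-1, 1), cells, ["m"], "raw_counts"
        )
        return scaled, raw

    def test_descending_ranks_and_dropout_flags(self):
        scaled, raw = self.make_matrices([5, 1, 0], [5, 1, 0])
        r = pr.rank_cells(scaled, raw, "m", "descending")
        np.testing.assert_array_equal(r.ranks, [1, 2, 3])
        np.testing.assert_array_equal(r.zero_flags, [False, False, True])
        assert r.alpha == pytest.approx(2 / 3)

    def test_ascending_reverses(self):
        scaled, raw = self.make_matrices([5, 1, 0], [5, 1, 0])
        r = pr.rank_cells(scaled, raw, "m", "ascending")
        np.testing.assert_array_equal(r.ranks, [3, 2, 1])

    def test_ties_broken_by_barcode(self):
        scaled, raw = self.make_matrices([2, 2, 2], [1, 1, 1])
        r = pr.rank_cells(scaled, raw, "m", "descending")
        np.testing.assert_array_equal(r.ranks, [1, 2, 3])
        assert r.alpha == 1.0

    def test_missing_marker_lists_near_matches(self):
        scaled, raw = self.make_matrices([1], [1])
        with pytest.raises(KeyError, match="similar"):
            pr.rank_cells(scaled, raw, "mm", "descending")


class TestOrderStatisticPvalues:
    def test_uniform_case(self):
        np.testing.assert_allclose(pr.order_statistic_pvalues([0.2]), [0.2])

    def test_two_values_closed_form(self):
        p = pr.order_statistic_pvalues([0.1, 0.5])
        np.testing.assert_allclose(p, [1 - 0.9**2, 0.5**2], atol=1e-12)

    def test_zero_percentile(self):
        assert pr.order_statistic_pvalues([0.0, 0.5])[0] == 0.0

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            pr.order_statistic_pvalues([0.5, 0.1])

    def test_matches_beta_cdf(self):
        u = np.sort(np.random.default_rng(0).random(6))
        p = pr.order_statistic_pvalues(u)
        n = len(u)
        expected = [beta.cdf(u[k - 1], k, n + 1 - k) for k in range(1, n + 1)]
        np.testing.assert_allclose(p, expected, atol=1e-12)


class TestRho:
    def test_positive_two_front_cells(self):
        ranking = make_ranking(10)
        rho, j = pr.rho_positive(ranking, [0, 1])  # ranks 1 and 2
        assert j == 2
        assert rho == pytest.approx(0.04, abs=1e-12)  # min(0.19, 0.04)

    def test_positive_single_cell_is_uniform(self):
        ranking = make_ranking(100)
        rho, j = pr.rho_positive(ranking, [0])
        assert (rho, j) == (pytest.approx(0.01), 1)

    def test_positive_all_dropout_gives_one(self):
        ranking = make_ranking(10, zero=(0, 1))
        rho, j = pr.rho_positive(ranking, [0, 1])
        assert (rho, j) == (1.0, 0)

    def test_negative_excludes_leading_dropouts(self):
        ranking = make_ranking(10, direction="ascending", zero=(0, 1))
        rho, j = pr.rho_negative(ranking, [0, 1, 2])
        # only p_3 = Beta(3,1).cdf(0.3) = 0.3^3 survives the truncation
        assert j == 2
        assert rho == pytest.approx(0.3**3, abs=1e-12)

    def test_negative_all_dropout_gives_one(self):
        ranking = make_ranking(10, direction="ascending", zero=(0, 1, 2))
        rho, j = pr.rho_negative(ranking, [0, 1, 2])
        assert (rho, j) == (1.0, 3)

    def test_negative_single_nonzero_front_cell(self):
        ranking = make_ranking(100, direction="ascending")
        rho, j = pr.rho_negative(ranking, [0])
        assert (rho, j) == (pytest.approx(0.01), 0)

    @pytest.mark.parametrize("M", [10, 100])
    def test_single_cell_rho_equals_percentile(self, M):
        ranking = make_ranking(M)
        for pos in range(0, M, max(1, M // 7)):
            rho, _ = pr.rho_positive(ranking, [pos])
            assert rho == pytest.approx((pos + 1) / M)

    def test_better_rank_never_hurts(self):
        # moving a nonzero target cell to a smaller descending rank can
        # only shrink (or preserve) rho_pos
        ranking = make_ranking(30)
        rng = np.random.default_rng(1)
        for _ in range(50):
            idx = rng.choice(30, size=4, replace=False)
            worst = idx.max()
            better = idx.copy()
            better[np.argmax(idx)] = rng.integers(0, worst)
            if len(set(better)) < 4:
                continue
            rho_a, _ = pr.rho_positive(ranking, idx)
            rho_b, _ = pr.rho_positive(ranking, better)
            assert rho_b <= rho_a + 1e-12


class TestSelectionScore:
    def test_negative_branch(self):
        assert pr.selection_score(0.001, 0.9) == pytest.approx(
            math.log(0.001)
        )

    def test_positive_branch(self):
        assert pr.selection_score(0.9, 0.001) == pytest.approx(
            -math.log(0.001)
        )

    def test_tie_is_zero(self):
        assert pr.selection_score(0.5, 0.5) == 0.0

    def test_floor_clamps_zero_pvalues(self):
        assert pr.selection_score(0.0, 0.9, floor=1 / 1001) == pytest.approx(
            math.log(1 / 1001)
        )


class TestRraTest:
    def test_detects_implanted_negative_selection(self, effect_screen):
        cfg, raw, identity, _ = effect_screen
        scaled = prepare(raw)
        res = pr.rra_test(scaled, scaled.raw, "G0001", identity,
                          n_perm=300, seed=5)
        mine = next(r for r in res if r.target_id == "G0001")
        assert mine.score < 0
        assert mine.p_neg <= 0.02

    def test_rank_invariance_to_marker_scaling(self, effect_screen):
        cfg, raw, identity, _ = effect_screen
        scaled = prepare(raw)
        doubled = pr.ExpressionMatrix(
            scaled.dense() * 3.7, scaled.cell_ids, scaled.gene_ids,
            "scaled", raw=scaled.raw,
        )
        a = pr.rra_table(pr.rra_test(scaled, scaled.raw, "G0002", identity,
                                     n_perm=100, seed=7))
        b = pr.rra_table(pr.rra_test(doubled, scaled.raw, "G0002", identity,
                                     n_perm=100, seed=7))
        pd.testing.assert_frame_equal(a, b)

    def test_deterministic_given_seed(self, null_screen):
        cfg, raw, identity, _ = null_screen
        scaled = prepare(raw)
        a = pr.rra_table(pr.rra_test(scaled, scaled.raw, "G0003", identity,
                                     n_perm=100, seed=9))
        b = pr.rra_table(pr.rra_test(scaled, scaled.raw, "G0003", identity,
                                     n_perm=100, seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_results_carry_counts_and_bounds(self, null_screen):
        cfg, raw, identity, _ = null_screen
        scaled = prepare(raw)
        for r in pr.rra_test(scaled, scaled.raw, "G0002", identity,
                             n_perm=50, seed=2):
            assert 0 <= r.n_nonzero <= r.n_cells
            for v in (r.rho_neg, r.rho_pos, r.p_neg, r.p_pos,
                      r.fdr_neg, r.fdr_pos):
                assert 0 <= v <= 1

    def test_score_sign_matches_winning_direction(self, effect_screen):
        cfg, raw, identity, _ = effect_screen
        scaled = prepare(raw)
        for r in pr.rra_test(scaled, scaled.raw, "G0004", identity,
                             n_perm=100, seed=3):
            if r.p_neg < r.p_pos:
                assert r.score < 0
            elif r.p_pos < r.p_neg:
                assert r.score > 0
            else:
                assert r.score == 0

    def test_signature_marker_accepted(self, effect_screen):
        cfg, raw, identity, _ = effect_screen
        scaled = prepare(raw)
        res = pr.rra_test(scaled, scaled.raw,
                          ("sig", ["G0011", "G0012"]), identity,
                          n_perm=50, seed=1)
        assert res[0].marker_id == "sig"

    def test_zero_permutations_rejected(self, null_screen):
        cfg, raw, identity, _ = null_screen
        scaled = prepare(raw)
        with pytest.raises(ValueError):
            pr.rra_test(scaled, scaled.raw, "G0001", identity, n_perm=0)
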