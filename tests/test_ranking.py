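import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proximal.ranking import (
    ConvergenceError,
    EnzymeDataMatrix,
    EnzymeStats,
    load_packaged_stats,
    minmax_scale_columns,
    normalize_matrix,
    quantile_normalize,
    rank,
    score,
    summarize,
)


def _random_matrix(seed, rows=9, cols=6):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.gamma(2.0, 10.0, (rows, cols)))


class TestMinMaxScaling:
    def test_column_2_4_6_scales_to_0_half_1(self):
        out = minmax_scale_columns(pd.DataFrame({"s": [2.0, 4.0, 6.0]}))
        assert out["s"].tolist() == [0.0, 0.5, 1.0]

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_columns_span_exactly_zero_to_one(self, seed):
        out = minmax_scale_columns(_random_matrix(seed))
        assert np.allclose(out.min(axis=0), 0.0)
        assert np.allclose(out.max(axis=0), 1.0)


class TestQuantileNormalization:
    def test_two_by_two_example(self):
        out = quantile_normalize(pd.DataFrame([[1.0, 2.0], [3.0, 4.0]]))
        assert out.to_numpy().tolist() == [[1.5, 1.5], [3.5, 3.5]]

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_idempotent_on_tie_free_matrices(self, seed):
        q1 = quantile_normalize(_random_matrix(seed))
        assert np.allclose(quantile_normalize(q1), q1)

    def test_ties_receive_the_mean_over_tied_ranks(self):
        out = quantile_normalize(pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [0.0, 2.0, 4.0]}))
        # column a: ranks 0,1 tied -> mean of reference[0:2]
        ref = np.sort(np.array([[1, 0], [1, 2], [5, 4]], dtype=float), axis=0).mean(axis=1)
        assert np.allclose(out["a"], [ref[:2].mean(), ref[:2].mean(), ref[2]])


class TestNormalizeMatrix:
    def test_complete_matrix_converges_in_a_single_pass(self):
        m = EnzymeDataMatrix(_random_matrix(1), kind="activity")
        norm, imputed = normalize_matrix(m)
        assert imputed.isna().all().all()
        assert np.allclose(norm.min(axis=0), 0.0) and np.allclose(norm.max(axis=0), 1.0)

    def test_missing_values_converge_at_tenth_percent(self):
        raw = _random_matrix(2)
        for i, j in [(0, 1), (3, 4), (5, 2)]:
            raw.iloc[i, j] = np.nan
        norm, imputed = normalize_matrix(EnzymeDataMatrix(raw, kind="abundance"), tol=1e-3)
        assert imputed.notna().sum().sum() == 3

    def test_imputation_recovers_structured_data(self):
        """On a multiplicative enzymes x studies structure (row effect x study
        effect) all columns share one ranking, so imputed values should land
        near the unmasked run.  An imputed entry can perturb a column's ranks
        by at most the number of imputed cells in that column, and one rank
        step moves a quantile-normalised value by ~1/(n_rows - 1); the
        tolerance below is that analytic bound."""
        rng = np.random.default_rng(9)
        row = rng.gamma(3, 5, 9)
        col = rng.gamma(2, 2, 6)
        full = pd.DataFrame(np.outer(row, col))
        norm_full, _ = normalize_matrix(EnzymeDataMatrix(full.copy(), kind="activity"))
        masked = full.copy()
        cells = [(i, j) for i in range(9) for j in range(6)]
        perm = rng.permutation(len(cells))
        dropped = [cells[k] for k in perm[: int(0.3 * len(cells))]]  # 30 % masked
        for i, j in dropped:
            masked.iloc[i, j] = np.nan
        per_col = max(sum(1 for _, j in dropped if j == c) for c in range(6))
        tol = (per_col + 1) / (len(full) - 1)
        norm_masked, _ = normalize_matrix(EnzymeDataMatrix(masked, kind="activity"))
        for i, j in dropped:
            assert abs(norm_masked.iloc[i, j] - norm_full.iloc[i, j]) < tol

    def test_non_convergence_raises_with_residual(self):
        raw = _random_matrix(3)
        raw.iloc[0, 0] = np.nan
        with pytest.raises(ConvergenceError, match="iterations"):
            normalize_matrix(EnzymeDataMatrix(raw, kind="activity"), max_iter=1)

    def test_all_missing_rows_are_dropped_with_warning(self):
        raw = _random_matrix(4)
        raw.iloc[2, :] = np.nan
        with pytest.warns(UserWarning, match="no observed"):
            m = EnzymeDataMatrix(raw, kind="activity")
        assert len(m.data) == 8


class TestSummarize:
    def test_averages_sum_to_one_for_each_kind(self):
        act, _ = normalize_matrix(EnzymeDataMatrix(_random_matrix(5), kind="activity"))
        ab, _ = normalize_matrix(EnzymeDataMatrix(_random_matrix(6), kind="abundance"))
        stats = summarize(act, ab)
        assert abs(stats.table["activity_avg"].sum() - 1.0) < 5e-4
        assert abs(stats.table["abundance_avg"].sum() - 1.0) < 5e-4

    def test_final_averages_are_scale_invariant(self):
        raw = _random_matrix(7)
        ab, _ = normalize_matrix(EnzymeDataMatrix(raw.copy(), kind="abundance"))
        act1, _ = normalize_matrix(EnzymeDataMatrix(raw.copy(), kind="activity"))
        scaled = raw.copy()
        scaled[2] = scaled[2] * 13.7  # rescaling one study's units
        act2, _ = normalize_matrix(EnzymeDataMatrix(scaled, kind="activity"))
        s1, s2 = summarize(act1, ab), summarize(act2, ab)
        assert np.allclose(s1.table["activity_avg"], s2.table["activity_avg"])

    def test_zero_total_is_an_error(self):
        zero = pd.DataFrame(np.zeros((3, 2)))
        with pytest.raises(ValueError, match="zero"):
            summarize(zero, zero)


class TestScore:
    def test_packaged_table_values(self):
        stats = load_packaged_stats()
        assert stats.average("activity", "1A2") == pytest.approx(0.0414)
        assert stats.average("abundance", "1A2") == pytest.approx(0.0895)
        assert abs(stats.table["activity_avg"].sum() - 1.0) < 5e-4
        assert abs(stats.table["abundance_avg"].sum() - 1.0) < 5e-4

    def test_enzymes_without_data_are_skipped_and_reported(self):
        res = score({"1A1", "1A2", "1B1", "3A4"})
        assert res.reported == 0.0395
        assert res.missing == ("1A1", "1B1")
        assert res.used == ("1A2", "3A4")

    def test_single_enzyme_score(self):
        assert score({"2E1"}).reported == 0.0317

    def test_empty_or_all_unavailable_set_scores_zero(self):
        assert score(set()).value == 0.0
        assert score({"1A1", "1B1"}).value == 0.0


class TestRank:
    def test_single_item_gets_rank_one(self):
        (s,) = rank([("only", {"3A4"})])
        assert s.rank == 1

    def test_ties_keep_input_order_with_distinct_ranks(self):
        ranked = rank([("first", {"2E1"}), ("second", {"2E1"})])
        assert [(s.id, s.rank) for s in ranked] == [("first", 1), ("second", 2)]

    def test_descending_score_order(self):
        ranked = rank([("low", {"2D6"}), ("high", {"3A4", "2C9"}), ("mid", {"2E1"})])
        assert [s.id for s in ranked] == ["high", "mid", "low"]
        assert [s.rank for s in ranked] == [1, 2, 3]


def test_custom_stats_table_is_usable():
    table = pd.DataFrame(
        {"activity_avg": [0.6, 0.4], "abundance_avg": [0.3, 0.7]},
        index=["2E1", "3A4"],
    )
    res = score({"2E1", "3A4"}, EnzymeStats(table))
    assert res.value == pytest.approx(0.6 * 0.3 + 0.4 * 0.7)
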