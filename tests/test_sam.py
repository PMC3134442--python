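"""One-class SAM caller: filters, statistics, permutation q-values."""

import numpy as np
import pandas as pd
import pytest

from rncmap.containers import FormatError, RatioMatrix
from rncmap.sam import (
    InsufficientReplicatesError,
    call_targets,
    filter_features,
    knn_impute,
    median_center,
    sam_one_class,
    _sign_patterns,
    spot_quality_filter,
)

from oracles import oracle_sam


def tidy_measurements(rows):
    return pd.DataFrame(
        rows,
        columns=["gene_id", "sample_id", "value",
                 "regression_correlation", "signal_over_background"],
    )


class TestSpotQualityFilter:
    @pytest.mark.parametrize(
        "corr,sob,kept",
        [
            (0.61, 2.6, True),   # just above both cutoffs survives
            (0.60, 10.0, False),  # boundary correlation fails (strict >)
            (0.9, 2.5, False),   # boundary signal/background fails
            (0.59, 2.4, False),
        ],
    )
    def test_strict_thresholds(self, corr, sob, kept):
        table = tidy_measurements(
            [("g1", "r1", 1.5, corr, sob), ("g1", "r2", 0.5, 0.9, 9.0)]
        )
        matrix = spot_quality_filter(table)
        assert np.isnan(matrix.data.loc["g1", "r1"]) != kept
        assert matrix.data.loc["g1", "r2"] == 0.5

    def test_missing_quality_columns_rejected(self):
        bad = pd.DataFrame({"gene_id": ["g"], "sample_id": ["r"], "value": [1.0]})
        with pytest.raises(FormatError):
            spot_quality_filter(bad)

    def test_survivor_count_matches_recount(self, rng):
        genes = [f"g{i}" for i in range(30)]
        rows = [
            (g, f"r{j}", rng.normal(), rng.uniform(0.3, 1.0), rng.uniform(1.0, 5.0))
            for g in genes
            for j in range(4)
        ]
        table = tidy_measurements(rows)
        matrix = spot_quality_filter(table)
        expected = sum(
            1 for _, _, _, c, s in rows if c > 0.6 and s > 2.5
        )
        assert int(matrix.data.notna().sum().sum()) == expected


class TestFilterFeatures:
    def test_two_missing_dropped_one_kept(self):
        data = pd.DataFrame(
            [[1.0, np.nan, np.nan, 2.0], [1.0, np.nan, 0.5, 2.0], [1.0, 2.0, 0.5, 2.0]],
            index=["drop", "keep1", "keep0"],
            columns=list("abcd"),
        )
        out = filter_features(RatioMatrix(data))
        assert out.gene_ids == ["keep1", "keep0"]

    def test_identity_when_complete(self, rng):
        data = pd.DataFrame(rng.normal(size=(5, 3)), index=list("abcde"))
        out = filter_features(RatioMatrix(data))
        pd.testing.assert_frame_equal(out.data, data.astype(float))

    def test_matches_brute_force_recount(self, rng):
        values = rng.normal(size=(50, 4))
        values[rng.random((50, 4)) < 0.3] = np.nan
        data = pd.DataFrame(values, index=[f"g{i}" for i in range(50)])
        out = filter_features(RatioMatrix(data), max_missing=1)
        expected = [
            f"g{i}" for i in range(50) if np.isnan(values[i]).sum() <= 1
        ]
        assert out.gene_ids == expected


class TestSamOneClass:
    def test_all_zero_matrix_is_null(self):
        data = pd.DataFrame(np.zeros((100, 4)), index=[f"g{i}" for i in range(100)])
        result = sam_one_class(RatioMatrix(data), seed=0)
        assert np.all(result.d == 0)
        assert not np.any(result.q < 100)

    def test_matches_exhaustive_oracle_on_fixture(self):
        # fixed 6 x 4 fixture, s0 pinned to 0 for hand-computability
        rows = {
            "g1": [2.1, 1.8, 2.4, 1.9],
            "g2": [-0.2, 0.4, 0.1, -0.3],
            "g3": [0.9, 1.4, 0.6, 1.1],
            "g4": [-1.5, -1.1, -1.8, -1.2],
            "g5": [0.05, -0.1, 0.2, 0.03],
            "g6": [3.0, 2.7, 3.3, 2.9],
        }
        matrix = RatioMatrix(pd.DataFrame.from_dict(rows, orient="index"))
        result = sam_one_class(matrix, n_permutations=800, seed=1, s0=0.0)
        d_exp, q_exp = oracle_sam(rows, s0=0.0)
        for gene, d, q in zip(result.gene_ids, result.d, result.q):
            assert d == pytest.approx(d_exp[gene], rel=1e-12)
            assert q == pytest.approx(q_exp[gene], rel=1e-12)

    @pytest.mark.parametrize("n_rep", [2, 3, 4])
    def test_matches_oracle_on_random_matrices(self, rng, n_rep):
        values = rng.normal(0, 1, (15, n_rep))
        rows = {f"g{i:02d}": list(map(float, values[i])) for i in range(15)}
        matrix = RatioMatrix(pd.DataFrame.from_dict(rows, orient="index"))
        result = sam_one_class(matrix, seed=3, s0=0.1)
        d_exp, q_exp = oracle_sam(rows, s0=0.1)
        for gene, d, q in zip(result.gene_ids, result.d, result.q):
            assert d == pytest.approx(d_exp[gene], rel=1e-12)
            assert q == pytest.approx(q_exp[gene], rel=1e-12)

    def test_matches_oracle_with_missing_cells(self, rng):
        values = rng.normal(0, 1, (10, 4))
        rows = {}
        for i in range(10):
            row = list(map(float, values[i]))
            if i % 3 == 0:
                row[i % 4] = None
            rows[f"g{i:02d}"] = row
        frame = pd.DataFrame.from_dict(rows, orient="index").astype(float)
        result = sam_one_class(RatioMatrix(frame), seed=5, s0=0.2)
        d_exp, q_exp = oracle_sam(rows, s0=0.2)
        for gene, d, q in zip(result.gene_ids, result.d, result.q):
            assert d == pytest.approx(d_exp[gene], rel=1e-12)
            assert q == pytest.approx(q_exp[gene], rel=1e-12)

    def test_d_invariant_to_missing_positions(self):
        a = RatioMatrix(pd.DataFrame([[1.0, 2.0, np.nan, 3.0]], index=["g"]))
        b = RatioMatrix(pd.DataFrame([[np.nan, 1.0, 2.0, 3.0]], index=["g"]))
        da = sam_one_class(a, seed=0, s0=0.0).d[0]
        db = sam_one_class(b, seed=0, s0=0.0).d[0]
        assert da == pytest.approx(db)

    def test_scale_equivariance_of_ranking(self, rng):
        values = rng.normal(0.3, 1, (40, 4))
        base = RatioMatrix(pd.DataFrame(values, index=[f"g{i}" for i in range(40)]))
        scaled = RatioMatrix(base.data * 7.5)
        r1 = sam_one_class(base, seed=0)
        r2 = sam_one_class(scaled, seed=0)
        assert list(np.argsort(-np.abs(r1.d))) == list(np.argsort(-np.abs(r2.d)))
        np.testing.assert_allclose(r1.d, r2.d, rtol=1e-9)

    def test_insufficient_replicates_rejected(self):
        one_col = RatioMatrix(pd.DataFrame([[1.0]], index=["g"]))
        with pytest.raises(InsufficientReplicatesError):
            sam_one_class(one_col, seed=0)
        sparse = RatioMatrix(
            pd.DataFrame([[1.0, np.nan, np.nan]], index=["g"], columns=list("abc"))
        )
        with pytest.raises(InsufficientReplicatesError):
            sam_one_class(sparse, seed=0)

    def test_exhaustive_enumeration_when_cheap(self):
        assert len(_sign_patterns(3, 800, 0)) == 8
        assert len(_sign_patterns(4, 16, 0)) == 16
        assert len(_sign_patterns(10, 100, 0)) == 100

    def test_planted_signal_recovered(self, rng):
        n, planted = 400, 25
        values = rng.normal(0, 0.5, (n, 4))
        values[:planted] += 2.0
        matrix = RatioMatrix(pd.DataFrame(values, index=[f"g{i:03d}" for i in range(n)]))
        result = sam_one_class(matrix, seed=11)
        targets = call_targets(result, q_threshold=1.0)
        hits = {f"g{i:03d}" for i in range(planted)}
        assert len(targets.genes & hits) >= 0.9 * planted
        false = targets.genes - hits
        assert len(false) <= 0.05 * max(len(targets.genes), 1)


class TestCallTargets:
    def test_empty_result_gives_empty_set(self):
        data = pd.DataFrame(np.zeros((3, 4)), index=list("abc"))
        result = sam_one_class(RatioMatrix(data), seed=0)
        assert call_targets(result).genes == frozenset()

    def test_threshold_monotonicity(self, rng):
        values = rng.normal(0.5, 1, (60, 4))
        result = sam_one_class(
            RatioMatrix(pd.DataFrame(values, index=[f"g{i}" for i in range(60)])),
            seed=0,
        )
        tight = call_targets(result, q_threshold=1.0)
        loose = call_targets(result, q_threshold=5.0)
        assert tight.genes <= loose.genes

    def test_positive_sign_restriction(self, rng):
        values = rng.normal(0, 0.3, (50, 4))
        values[:5] -= 3.0  # strongly depleted genes
        result = sam_one_class(
            RatioMatrix(pd.DataFrame(values, index=[f"g{i}" for i in range(50)])),
            seed=0,
        )
        positive = call_targets(result, q_threshold=5.0, sign="positive")
        both = call_targets(result, q_threshold=5.0, sign="both")
        assert all(result.d[result.gene_ids.index(g)] > 0 for g in positive.genes)
        assert positive.genes <= both.genes


class TestPreprocessing:
    def test_median_center_zeroes_column_medians(self, small_matrix):
        centered = median_center(small_matrix)
        meds = centered.data.median(axis=0, skipna=True)
        np.testing.assert_allclose(meds.to_numpy(), 0.0, atol=1e-12)

    def test_knn_impute_fills_all_missing(self, small_matrix):
        out = knn_impute(filter_features(small_matrix))
        assert not out.data.isna().any().any()

    def test_knn_impute_preserves_observed(self, small_matrix):
        filtered = filter_features(small_matrix)
        out = knn_impute(filtered)
        obs = filtered.data.notna()
        pd.testing.assert_frame_equal(out.data[obs], filtered.data[obs])

    def test_knn_impute_uses_similar_rows(self):
        # two tight clusters; the imputed value must come from the right one
        rows = {f"lo{i}": [0.0, 0.1, -0.1, 0.05] for i in range(10)}
        rows.update({f"hi{i}": [5.0, 5.1, 4.9, 5.05] for i in range(10)})
        rows["query"] = [5.0, 5.1, 4.9, np.nan]
        matrix = RatioMatrix(pd.DataFrame.from_dict(rows, orient="index"))
        out = knn_impute(matrix)
        assert out.data.loc["query"].iloc[3] == pytest.approx(5.05, abs=0.2)
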