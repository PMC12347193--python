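"""Filter cascade: each stage against an independent oracle, plus the
cascade-level invariants (idempotence, report reconciliation, registry
audit on generated matrices)."""

import numpy as np
import pytest

from omisurv.matrix import InvalidInputError
from omisurv.preprocess import (
    PreprocessConfig,
    drop_all_nan_features,
    drop_duplicate_features,
    drop_quasi_constant,
    expression_floor_filter,
    impute_within,
    run_cascade,
    variance_filter,
)
from omisurv.simulate import SimConfig, gen_multiomics

from conftest import make_matrix


class TestDropAllNan:
    def test_fully_missing_feature_removed_others_kept(self):
        m = make_matrix(
            [[1, None, 2], [3, None, 4], [5, None, None], [7, None, 8], [9, None, 0]]
        )
        out, rep = drop_all_nan_features(m)
        assert out.feature_ids == ["f0", "f2"]
        assert rep.dropped_ids == ["f1"]

    def test_mostly_missing_feature_retained(self):
        # missing in 4 of 5 samples: kept for later imputation
        m = make_matrix([[1, None], [2, None], [3, None], [4, None], [5, 9]])
        out, _ = drop_all_nan_features(m)
        assert out.feature_ids == ["f0", "f1"]

    def test_identity_when_no_fully_missing(self):
        m = make_matrix([[1, 2], [3, 4]])
        out, rep = drop_all_nan_features(m)
        np.testing.assert_array_equal(out.values, m.values)
        assert rep.dropped_ids == []

    def test_empty_matrix_rejected(self):
        from omisurv.matrix import OmicsMatrix

        empty = OmicsMatrix(
            sample_ids=["s0"], feature_ids=[], values=np.empty((1, 0)),
            modality="protein",
        )
        with pytest.raises(InvalidInputError):
            drop_all_nan_features(empty)

    def test_matches_columnwise_scan_oracle(self, rng):
        values = rng.normal(size=(30, 15))
        miss = rng.random((30, 15)) < 0.4
        miss[:, [3, 9]] = True  # two fully-missing columns
        values[miss] = np.nan
        m = make_matrix(values)
        out, rep = drop_all_nan_features(m)
        oracle = {f"f{j}" for j in range(15) if np.isnan(values[:, j]).all()}
        assert set(rep.dropped_ids) == oracle


class TestQuasiConstant:
    def test_constant_feature_dropped(self):
        vals = np.column_stack([np.full(100, 3.5), np.arange(100.0)])
        out, rep = drop_quasi_constant(make_matrix(vals))
        assert rep.dropped_ids == ["f0"]

    @pytest.mark.parametrize(
        "n_shared,expect_drop", [(999, True), (997, False)]
    )
    def test_mode_fraction_boundary(self, n_shared, expect_drop):
        # 1000 samples; n_shared share one value -> fraction n_shared/1000
        col = np.concatenate([np.zeros(n_shared), np.arange(1, 1001 - n_shared)])
        vals = np.column_stack([col, np.arange(1000.0)])
        _, rep = drop_quasi_constant(make_matrix(vals), threshold=0.998)
        assert ("f0" in rep.dropped_ids) == expect_drop

    def test_missing_entries_excluded_from_count(self):
        # 5 observed entries, 4 equal -> fraction 0.8 < 0.998 -> kept
        m = make_matrix([[1], [1], [1], [1], [2], [None], [None]])
        _, rep = drop_quasi_constant(m)
        assert rep.dropped_ids == []

    def test_parameter_validation(self):
        m = make_matrix([[1, 2], [3, 4]])
        with pytest.raises(InvalidInputError):
            drop_quasi_constant(m, threshold=0.4)
        with pytest.raises(InvalidInputError):
            drop_quasi_constant(make_matrix([[1, 2]]))


class TestDuplicates:
    def test_second_of_pair_dropped_first_kept(self):
        vals = np.column_stack([np.arange(5.0)] * 2 + [np.ones(5)])
        m = make_matrix(vals, feature_ids=["g1", "g7", "g9"])
        out, rep = drop_duplicate_features(m)
        assert out.feature_ids == ["g1", "g9"]
        assert rep.parameters["representatives"] == {"g7": "g1"}

    def test_triple_duplicate_drops_two(self, rng):
        col = rng.normal(size=8)
        vals = np.column_stack([col, rng.normal(size=8), col, col])
        _, rep = drop_duplicate_features(make_matrix(vals))
        assert rep.dropped_ids == ["f2", "f3"]

    def test_no_duplicates_identity(self, rng):
        m = make_matrix(rng.normal(size=(6, 4)))
        out, rep = drop_duplicate_features(m)
        assert rep.dropped_ids == [] and out.feature_ids == m.feature_ids

    def test_matches_hash_grouping_oracle(self, rng):
        cols = [rng.normal(size=10) for _ in range(6)]
        order = [0, 1, 0, 2, 1, 3, 4, 0, 5]
        m = make_matrix(np.column_stack([cols[i] for i in order]))
        _, rep = drop_duplicate_features(m)
        seen, expected = set(), []
        for j, i in enumerate(order):
            if i in seen:
                expected.append(f"f{j}")
            seen.add(i)
        assert rep.dropped_ids == expected

    def test_missing_pattern_participates_in_equality(self):
        # same observed values but different missing positions: not duplicates
        m = make_matrix([[1, 1], [None, 2], [2, None], [3, 3]])
        _, rep = drop_duplicate_features(m)
        assert rep.dropped_ids == []


class TestVarianceFilter:
    def test_zero_variance_dropped(self):
        vals = np.column_stack([np.full(10, 2.0), np.arange(10.0)])
        _, rep = variance_filter(make_matrix(vals), threshold=0.01)
        assert rep.dropped_ids == ["f0"]

    def test_balanced_binary_dropped_at_exact_boundary(self):
        # population variance of a 50/50 0-1 split is exactly 0.25; the rule
        # is strictly greater-than, so the feature goes
        col = np.array([0.0, 1.0] * 10)
        vals = np.column_stack([col, np.arange(20.0)])
        _, rep = variance_filter(make_matrix(vals), threshold=0.25)
        assert rep.dropped_ids == ["f0"]

    def test_unit_variance_feature_kept(self, rng):
        vals = np.column_stack([rng.normal(size=200), np.zeros(200)])
        out, _ = variance_filter(make_matrix(vals), threshold=0.25)
        assert out.feature_ids == ["f0"]

    def test_population_variance_on_observed_entries(self):
        # observed [0, 2]: population variance 1.0 > 0.25 -> kept
        m = make_matrix([[0], [None], [2]])
        out, _ = variance_filter(m, threshold=0.25)
        assert out.n_features == 1


class TestExpressionFloor:
    def test_cutoff_is_127_fpkm_on_log2_scale(self):
        assert 2**7 - 1 == 127

    def test_max_below_cutoff_dropped(self):
        vals = np.column_stack([np.full(5, 6.9), np.full(5, 8.0)])
        m = make_matrix(vals, modality="gene_expression")
        _, rep = expression_floor_filter(m, cutoff=7.0)
        assert rep.dropped_ids == ["f0"]

    def test_single_high_sample_keeps_feature(self):
        col = np.zeros(6)
        col[3] = 7.5
        m = make_matrix(np.column_stack([col]), modality="gene_expression")
        out, _ = expression_floor_filter(m, cutoff=7.0)
        assert out.n_features == 1

    def test_wrong_modality_rejected(self):
        with pytest.raises(InvalidInputError):
            expression_floor_filter(make_matrix([[1.0]], modality="protein"))

    def test_mean_aggregation_alternative(self):
        # one spike at 8 but mean 2 -> dropped under the mean rule
        col = np.array([0.0, 0, 0, 8.0])
        m = make_matrix(np.column_stack([col]), modality="gene_expression")
        _, rep = expression_floor_filter(m, cutoff=7.0, aggregation="mean")
        assert rep.dropped_ids == ["f0"]


class TestImpute:
    def test_mean_of_observed_within_group(self):
        m = make_matrix([[1], [None], [3]])
        out = impute_within(m, group_by=None)
        assert out.values[1, 0] == 2.0

    def test_identity_without_missing(self, rng):
        m = make_matrix(rng.normal(size=(4, 3)))
        out = impute_within(m)
        assert out is m

    def test_groupwise_means_differ(self):
        m = make_matrix(
            [[0], [2], [None], [10], [None], [14]],
            cohort=["A", "A", "A", "B", "B", "B"],
        )
        out = impute_within(m, group_by="cohort")
        assert out.values[2, 0] == 1.0 and out.values[4, 0] == 12.0

    def test_fully_missing_in_group_names_feature_and_group(self):
        m = make_matrix(
            [[1, 1], [None, 2], [None, 3]], cohort=["A", "LUSC", "LUSC"],
            feature_ids=["f_k", "f_other"],
        )
        with pytest.raises(InvalidInputError, match=r"f_k.*LUSC"):
            impute_within(m, group_by="cohort")


class TestCascade:
    @pytest.fixture
    def pathological_cohort(self):
        cfg = SimConfig(
            n_samples=80,
            modality_widths={"gene_expression": 40, "mutation": 25},
            pathologies={
                "gene_expression": {
                    "all_missing": 2,
                    "constant": 2,
                    "quasi_constant": 2,
                    "duplicate": 2,
                    "low_variance": 2,
                },
                "mutation": {"constant": 1, "duplicate": 1, "low_variance": 1},
            },
            seed=42,
        )
        return gen_multiomics(cfg)

    def test_removes_exactly_the_registered_columns(self, pathological_cohort):
        matrices, truth = pathological_cohort
        for mod, m in matrices.items():
            clean, _ = run_cascade(m)
            removed = set(m.feature_ids) - set(clean.feature_ids)
            assert removed == truth.pathological_ids(mod), mod

    def test_idempotent_and_reports_reconcile(self, pathological_cohort):
        matrices, _ = pathological_cohort
        m = matrices["gene_expression"]
        once, reports = run_cascade(m)
        twice, reports2 = run_cascade(once)
        np.testing.assert_array_equal(once.values, twice.values)
        assert all(not r.dropped_ids for r in reports2)
        # widths reconcile stage by stage, and dropped sets are disjoint
        width = m.n_features
        dropped_all: list[str] = []
        for r in reports:
            assert r.features_in == width
            width = r.features_out
            dropped_all.extend(r.dropped_ids)
        assert width == once.n_features
        assert len(dropped_all) == len(set(dropped_all))

    def test_samples_never_dropped_or_reordered(self, pathological_cohort):
        matrices, _ = pathological_cohort
        for m in matrices.values():
            clean, _ = run_cascade(m)
            assert clean.sample_ids == m.sample_ids

    def test_output_has_no_missing_entries(self, pathological_cohort):
        matrices, _ = pathological_cohort
        for m in matrices.values():
            clean, _ = run_cascade(m)
            assert not np.isnan(clean.values).any()
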