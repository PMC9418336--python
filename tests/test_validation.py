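"""Design-based validation: sample size, allocation, error-matrix
estimators, class merging, area reports."""

import numpy as np
import pandas as pd
import pytest

from smallfield import datasets, validation
from smallfield.core import ClassMap


class TestSampleSize:
    def test_reference_design_yields_1875(self):
        w = np.array([0.2, 0.1, 0.15, 0.3, 0.15, 0.05, 0.05])
        assert validation.sample_size(w, 0.75, 0.01) == 1875
        # independent of weights when UA is uniform
        assert validation.sample_size(np.full(7, 1 / 7), 0.75, 0.01) == 1875

    def test_half_ua_gives_2500(self):
        assert validation.sample_size(np.full(4, 0.25), 0.5, 0.01) == 2500

    def test_doubling_se_quarters_n(self):
        w = np.full(5, 0.2)
        n1 = validation.sample_size(w, 0.75, 0.01)
        n2 = validation.sample_size(w, 0.75, 0.02)
        assert n2 == pytest.approx(n1 / 4, abs=1)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            validation.sample_size(np.array([0.5, 0.2]), 0.75, 0.01)
        with pytest.raises(ValueError):
            validation.sample_size(np.full(4, 0.25), 0.75, 0.0)


class TestAllocation:
    def test_floor_and_remainder_of_reference_design(self):
        w = np.array([0.2, 0.1, 0.15, 0.3, 0.15, 0.05, 0.05])
        alloc = validation.allocate(1875, w, per_class_floor=200)
        assert alloc.sum() == 1875
        assert np.all(alloc >= 200)
        assert (alloc - 200).sum() == 475

    def test_uniform_weights_split_remainder_evenly(self):
        alloc = validation.allocate(1875, np.full(7, 1 / 7), 200)
        assert alloc.sum() == 1875
        assert set(alloc - 200) <= {67, 68}

    def test_infeasible_floor_rejected(self):
        with pytest.raises(ValueError):
            validation.allocate(100, np.full(7, 1 / 7), 200)


class TestErrorMatrixEstimators:
    def test_identity_matrix_perfect_scores(self):
        p = np.diag([0.3, 0.5, 0.2])
        est = validation.error_matrix_from_proportions(p)
        assert est.overall_accuracy == pytest.approx(1.0)
        np.testing.assert_allclose(est.users_accuracy, 1.0)
        np.testing.assert_allclose(est.producers_accuracy, 1.0)

    def test_counts_and_proportions_paths_agree(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 60, (4, 4)).astype(float)
        w = np.array([0.4, 0.3, 0.2, 0.1])
        from_counts = validation.error_matrix_from_counts(counts, w)
        from_props = validation.error_matrix_from_proportions(from_counts.p)
        assert from_props.overall_accuracy == pytest.approx(
            from_counts.overall_accuracy, abs=1e-12)
        np.testing.assert_allclose(from_props.users_accuracy,
                                   from_counts.users_accuracy, atol=1e-12)
        np.testing.assert_allclose(from_props.area_shares,
                                   from_counts.area_shares, atol=1e-12)

    def test_area_shares_sum_to_one(self):
        est = datasets.mozambique_error_matrix()
        assert est.area_shares.sum() == pytest.approx(est.p.sum(), abs=1e-12)

    def test_estimators_invariant_to_class_reordering(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 50, (5, 5)).astype(float)
        w = rng.dirichlet(np.ones(5))
        est = validation.error_matrix_from_counts(counts, w)
        perm = rng.permutation(5)
        est_p = validation.error_matrix_from_counts(
            counts[np.ix_(perm, perm)], w[perm])
        assert est_p.overall_accuracy == pytest.approx(est.overall_accuracy)
        np.testing.assert_allclose(est_p.users_accuracy,
                                   est.users_accuracy[perm], atol=1e-12)
        np.testing.assert_allclose(est_p.se_area_shares(),
                                   est.se_area_shares()[perm], atol=1e-12)

    def test_cis_require_counts(self):
        est = validation.error_matrix_from_proportions(np.diag([0.5, 0.5]))
        with pytest.raises(ValueError, match="counts"):
            est.se_overall_accuracy()

    def test_tiny_stratum_flagged_undefined(self):
        counts = np.array([[1.0, 0.0], [5.0, 45.0]])
        est = validation.error_matrix_from_counts(counts,
                                                  np.array([0.5, 0.5]))
        assert np.isnan(est.se_users_accuracy()[0])

    def test_malformed_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            validation.error_matrix_from_proportions(np.diag([0.5, 0.3]))


class TestMergeClasses:
    def test_identity_mapping_is_noop(self):
        est = datasets.mozambique_error_matrix()
        same = validation.merge_classes(est, {c: c for c in est.class_codes})
        np.testing.assert_allclose(same.p, est.p)

    def test_all_to_one_gives_perfect_accuracy(self):
        est = datasets.mozambique_error_matrix()
        one = validation.merge_classes(est, {c: 1 for c in est.class_codes})
        assert one.overall_accuracy == pytest.approx(est.p.sum())

    def test_merging_never_decreases_overall_accuracy(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.dirichlet(np.ones(16)).reshape(4, 4)
            est = validation.error_matrix_from_proportions(p)
            mapping = {c: rng.integers(1, 3) for c in est.class_codes}
            merged = validation.merge_classes(est, mapping)
            assert merged.overall_accuracy >= est.overall_accuracy - 1e-12

    def test_counts_mode_survives_merge_with_cis(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(5, 60, (4, 4)).astype(float)
        est = validation.error_matrix_from_counts(
            counts, rng.dirichlet(np.ones(4)))
        merged = validation.merge_classes(est, {1: 1, 2: 1, 3: 2, 4: 2})
        assert merged.has_counts()
        assert np.all(np.isfinite(merged.se_area_shares()))


class TestSamplingAndCoverage:
    def test_stratified_draw_matches_allocation(self):
        rng = np.random.default_rng(0)
        cmap = ClassMap(rng.integers(1, 4, (64, 64)).astype(np.uint8))
        alloc = {1: 30, 2: 25, 3: 20}
        sample = validation.draw_validation_sample(cmap, alloc, seed=1)
        got = sample.groupby("map_class").size().to_dict()
        assert got == alloc
        # samples actually lie in their stratum, without replacement
        assert np.all(cmap.codes[sample["row"], sample["col"]]
                      == sample["map_class"])
        assert not sample.duplicated(["row", "col"]).any()

    def test_overfull_stratum_rejected(self):
        cmap = ClassMap(np.ones((8, 8), np.uint8))
        with pytest.raises(ValueError, match="stratum"):
            validation.draw_validation_sample(cmap, {1: 100}, seed=0)

    def test_area_ci_covers_truth_in_most_replicates(self):
        """Reduced version of the coverage property (200 replicates)."""
        W = np.array([0.4, 0.35, 0.25])
        Q = np.array([[0.9, 0.07, 0.03],
                      [0.08, 0.85, 0.07],
                      [0.05, 0.05, 0.9]])
        true_area = W @ Q
        rng = np.random.default_rng(7)
        cover = np.zeros(3)
        reps = 200
        for _ in range(reps):
            counts = np.stack([rng.multinomial(50, Q[i]) for i in range(3)])
            est = validation.error_matrix_from_counts(counts, W)
            ci = 1.96 * est.se_area_shares()
            cover += np.abs(est.area_shares - true_area) <= ci
        assert np.all(cover / reps >= 0.90)


class TestAreaReport:
    def test_report_lists_all_classes_with_shares(self):
        est = datasets.mozambique_error_matrix()
        rep = validation.area_report(est, class_names={
            int(c): str(c) for c in est.class_codes})
        assert len(rep) == 7
        assert rep["area_share"].sum() == pytest.approx(est.p.sum())

    def test_counts_mode_report_has_cis(self):
        counts = np.array([[40.0, 10.0], [5.0, 45.0]])
        est = validation.error_matrix_from_counts(counts,
                                                  np.array([0.6, 0.4]))
        rep = validation.area_report(est)
        assert "area_ci95" in rep.columns
        assert np.all(rep["area_ci95"] > 0)
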