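"""Cross-validated SVM, channel selection and permutation significance."""

import numpy as np
import pytest

import eegresp as er
from eegresp.classify import rank_auc
from eegresp.core import BandPowerTable, DataValidationError


def gaussian_features(n_pos, n_neg, d=2, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_pos + n_neg, d))
    X[:n_pos] += shift
    y = np.array([True] * n_pos + [False] * n_neg)
    return X, y


class TestBalancedAccuracy:
    @pytest.mark.parametrize(
        "sens,spec,expected", [(1.0, 0.0, 0.5), (0.7, 0.8, 0.75), (1.0, 1.0, 1.0)]
    )
    def test_identity(self, sens, spec, expected):
        assert er.balanced_accuracy(sens, spec) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            er.balanced_accuracy(1.2, 0.5)


class TestGridSearch:
    def test_single_point_grid_returned(self):
        X, y = gaussian_features(8, 8, seed=1)
        spec = er.ClassifierSpec(c_grid=(3.0,), gamma_grid=(0.7,), inner_folds=2)
        assert er.grid_search_params(X, y, spec) == (3.0, 0.7)

    def test_tie_breaks_to_smallest_c_then_gamma(self):
        # constant features: every grid point scores identically
        X = np.zeros((16, 2))
        y = np.array([True] * 8 + [False] * 8)
        spec = er.ClassifierSpec(c_grid=(10.0, 0.1, 1.0), gamma_grid=(5.0, 0.5), inner_folds=2)
        assert er.grid_search_params(X, y, spec) == (0.1, 0.5)

    def test_separable_data_achieves_perfect_inner_accuracy(self):
        X, y = gaussian_features(10, 10, shift=8.0, seed=2)
        spec = er.ClassifierSpec(inner_folds=2)
        C, gamma = er.grid_search_params(X, y, spec)
        from sklearn.svm import SVC

        clf = SVC(kernel="rbf", C=C, gamma=gamma).fit(X, y.astype(int))
        assert (clf.predict(X) == y.astype(int)).all()

    def test_one_class_rejected(self):
        X = np.zeros((6, 1))
        with pytest.raises(DataValidationError):
            er.grid_search_params(X, np.ones(6, dtype=int), er.ClassifierSpec())


class TestCrossValidatedSVM:
    def test_separable_clouds_perfect_auc(self):
        X, y = gaussian_features(24, 24, d=2, shift=6.0, seed=3)
        res = er.cross_validated_svm(X, y, er.ClassifierSpec())
        assert res.auc == 1.0
        assert res.balanced_accuracy >= 0.95

    def test_balanced_accuracy_identity_exact(self, lean_spec):
        X, y = gaussian_features(10, 14, shift=1.0, seed=4)
        res = er.cross_validated_svm(X, y, lean_spec)
        assert res.balanced_accuracy == (res.sensitivity + res.specificity) / 2

    def test_one_pooled_score_per_subject(self, lean_spec):
        X, y = gaussian_features(10, 14, seed=5)
        res = er.cross_validated_svm(X, y, lean_spec)
        assert res.pooled_scores.shape == (24,)
        assert len(res.per_fold_params) == lean_spec.n_folds

    def test_permuted_labels_near_chance(self, lean_spec):
        X, y = gaussian_features(17, 31, d=3, shift=2.0, seed=6)
        rng = np.random.default_rng(0)
        aucs = [
            er.cross_validated_svm(X, rng.permutation(y), lean_spec).auc
            for _ in range(25)
        ]
        assert 0.4 < np.mean(aucs) < 0.6

    def test_duplicated_feature_column_changes_little(self, lean_spec):
        X, y = gaussian_features(17, 31, d=1, shift=2.0, seed=7)
        a = er.cross_validated_svm(X, y, lean_spec)
        b = er.cross_validated_svm(np.hstack([X, X]), y, lean_spec)
        assert abs(a.auc - b.auc) <= 0.02

    def test_label_leak_canary(self, lean_spec):
        """A feature equal to the label must be learnable (sanity ceiling)."""
        rng = np.random.default_rng(8)
        y = np.array([True] * 10 + [False] * 14)
        X = np.hstack([rng.normal(size=(24, 2)), y[:, None].astype(float)])
        res = er.cross_validated_svm(X, y, lean_spec)
        assert res.auc >= 0.99

    def test_reproducible_with_fixed_seed(self, lean_spec):
        X, y = gaussian_features(10, 14, shift=0.5, seed=9)
        a = er.cross_validated_svm(X, y, lean_spec)
        b = er.cross_validated_svm(X, y, lean_spec)
        assert np.array_equal(a.pooled_scores, b.pooled_scores)
        assert a.per_fold_params == b.per_fold_params

    def test_too_few_per_class_rejected(self):
        X, y = gaussian_features(4, 20, seed=10)
        with pytest.raises(DataValidationError):
            er.cross_validated_svm(X, y, er.ClassifierSpec(n_folds=5))

    def test_nan_features_rejected(self, lean_spec):
        X, y = gaussian_features(10, 14, seed=11)
        X[0, 0] = np.nan
        with pytest.raises(DataValidationError):
            er.cross_validated_svm(X, y, lean_spec)


class TestRankAUC:
    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(12)
        y = rng.integers(0, 2, 50).astype(bool)
        y[0], y[1] = True, False
        s = rng.normal(size=50)
        assert rank_auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(13)
        y = np.array([True] * 10 + [False] * 10)
        s = rng.normal(size=20)
        assert rank_auc(y, s) == pytest.approx(rank_auc(y, np.exp(s) + 5))


class TestChannelProcedures:
    def _table(self, X):
        return BandPowerTable.single_band(np.exp(X / 2), "delta")

    def test_screen_returns_one_result_per_channel(self, lean_spec):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(24, 7))
        y = np.array([True] * 10 + [False] * 14)
        screen = er.single_channel_screen(self._table(X), y, "delta", lean_spec)
        assert len(screen) == 7
        assert set(screen) == set(er.CHANNELS_62[:7])

    def test_planted_channel_wins_screen(self, lean_spec):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(48, 8))
        y = np.array([True] * 17 + [False] * 31)
        X[y, 3] += 3.0
        screen = er.single_channel_screen(self._table(X), y, "delta", lean_spec)
        best = max(screen, key=lambda ch: screen[ch].auc)
        assert best == er.CHANNELS_62[3]

    def test_trace_bookkeeping_small(self, lean_spec):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(24, 5))
        y = np.array([True] * 10 + [False] * 14)
        trace = er.forward_channel_selection(self._table(X), y, "delta", lean_spec)
        assert len(trace.steps) == 5
        assert sorted(trace.channels_in_order) == sorted(er.CHANNELS_62[:5])
        assert trace.best_auc == max(r.auc for _, r in trace.steps)
        # earliest maximizing prefix
        aucs = [r.auc for _, r in trace.steps]
        assert trace.best_step == aucs.index(max(aucs))

    def test_selection_at_least_matches_best_single(self, lean_spec):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(48, 6))
        y = np.array([True] * 17 + [False] * 31)
        X[y, 2] += 2.0
        table = self._table(X)
        screen = er.single_channel_screen(table, y, "delta", lean_spec)
        trace = er.forward_channel_selection(table, y, "delta", lean_spec, max_steps=4)
        assert trace.best_auc >= max(r.auc for r in screen.values()) - 0.02

    def test_max_steps_truncates(self, lean_spec):
        rng = np.random.default_rng(18)
        X = rng.normal(size=(24, 6))
        y = np.array([True] * 10 + [False] * 14)
        trace = er.forward_channel_selection(self._table(X), y, "delta", lean_spec, max_steps=2)
        assert len(trace.steps) == 2


class TestPermutationTest:
    def test_strong_signal_attains_floor(self, lean_spec):
        X, y = gaussian_features(10, 14, d=2, shift=6.0, seed=19)
        res = er.permutation_test_features(X, y, lean_spec, n_perm=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)
        assert res.observed_auc == 1.0

    def test_add_one_formula_degenerate(self, lean_spec):
        X, y = gaussian_features(10, 14, seed=20)
        res = er.permutation_test_features(X, y, lean_spec, n_perm=1, seed=0)
        assert res.p_value in (0.5, 1.0)
        assert res.null_aucs.shape == (1,)

    def test_reproducible(self, lean_spec):
        X, y = gaussian_features(10, 14, shift=0.5, seed=21)
        a = er.permutation_test_features(X, y, lean_spec, n_perm=20, seed=3)
        b = er.permutation_test_features(X, y, lean_spec, n_perm=20, seed=3)
        assert np.array_equal(a.null_aucs, b.null_aucs)
        assert a.p_value == b.p_value

    def test_table_interface_matches_features(self, lean_spec):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(24, 4))
        y = np.array([True] * 10 + [False] * 14)
        table = BandPowerTable.single_band(np.exp(X / 2), "delta")
        sub = [er.CHANNELS_62[1], er.CHANNELS_62[3]]
        a = er.permutation_test(table, y, sub, "delta", spec=lean_spec, n_perm=10, seed=5)
        b = er.permutation_test_features(
            np.exp(X[:, [1, 3]] / 2), y, lean_spec, n_perm=10, seed=5
        )
        assert a.p_value == b.p_value
        assert a.observed_auc == b.observed_auc

    def test_empty_subset_rejected(self, lean_spec):
        table = BandPowerTable.single_band(np.ones((24, 2)), "delta")
        y = np.array([True] * 10 + [False] * 14)
        with pytest.raises(ValueError):
            er.permutation_test(table, y, [], "delta", spec=lean_spec)
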