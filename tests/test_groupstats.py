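"""Responder labeling, change rates, gated tests and FDR adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

import eegresp as er
from eegresp.core import BandPowerTable, ClinicalRecord, DataValidationError
from eegresp.groupstats import ChangeRateTable, compare_two_samples


def brute_force_bh(p):
    """Independent step-up oracle, straight from the procedure's definition."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


def make_changes(values, valid=None, bands=("theta",)):
    values = np.asarray(values, float)
    if values.ndim == 2:
        values = values[:, :, None]
    if valid is None:
        valid = np.isfinite(values)
    subjects = tuple(f"s{i}" for i in range(values.shape[0]))
    channels = tuple(er.CHANNELS_62[: values.shape[1]])
    return ChangeRateTable(subjects, channels, tuple(bands), values, valid)


class TestLabelResponders:
    def _rec(self, sev_pre, sev_post, sx_pre, sx_post):
        return ClinicalRecord("s", sev_pre, sev_post, sx_pre, sx_post)

    def test_clear_responder(self):
        labels = er.label_responders([self._rec(40, 8, 12, 2)])
        assert labels["s"] is True

    def test_clear_nonresponder(self):
        labels = er.label_responders([self._rec(40, 30, 12, 8)])
        assert labels["s"] is False

    def test_both_criteria_required(self):
        # 75% Sev improvement but only ~42% on Sx -> not a responder
        labels = er.label_responders([self._rec(40, 10, 12, 7)])
        assert labels["s"] is False

    def test_sev_only_rule(self):
        labels = er.label_responders([self._rec(40, 10, 12, 7)], rule="sev")
        assert labels["s"] is True

    def test_boundary_is_strict(self):
        labels = er.label_responders([self._rec(40, 20, 12, 6)])
        assert labels["s"] is False  # exactly 50% is not "> 50%"

    def test_zero_pre_score_excluded_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="eegresp"):
            labels = er.label_responders(
                [ClinicalRecord("z", 0, 0, 10, 2), self._rec(40, 8, 12, 2)]
            )
        assert "z" not in labels and len(labels) == 1
        assert any("z" in r.message for r in caplog.records)


class TestChangeRate:
    def _tables(self, pre_vals, post_vals):
        pre = BandPowerTable.single_band(np.asarray(pre_vals, float), "beta", "pre")
        post = BandPowerTable.single_band(np.asarray(post_vals, float), "beta", "post")
        return pre, post

    def test_arithmetic(self):
        pre, post = self._tables([[2.0]], [[1.0]])
        assert er.change_rate(pre, post).values[0, 0, 0] == pytest.approx(0.5)

    def test_identity_gives_zero(self):
        pre, post = self._tables([[1.7]], [[1.7]])
        assert er.change_rate(pre, post).values[0, 0, 0] == 0.0

    def test_fc6_beta_reference_means(self):
        # group-mean pre 0.481 and post 0.331 give a 31.2% power decrease
        pre, post = self._tables([[0.481]], [[0.331]])
        assert er.change_rate(pre, post).values[0, 0, 0] == pytest.approx(0.312, abs=5e-4)

    def test_zero_pre_flagged_invalid(self):
        pre, post = self._tables([[0.0, 1.0]], [[1.0, 0.5]])
        changes = er.change_rate(pre, post)
        assert not changes.valid[0, 0, 0]
        assert np.isnan(changes.values[0, 0, 0])
        assert changes.values[0, 1, 0] == pytest.approx(0.5)

    def test_axis_mismatch_rejected(self):
        pre = BandPowerTable.single_band(np.ones((2, 2)), "beta", "pre")
        post = BandPowerTable.single_band(np.ones((2, 2)), "theta", "post")
        with pytest.raises(DataValidationError):
            er.change_rate(pre, post)

    @given(k=st.floats(0.01, 100))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_common_rescaling(self, k):
        rng = np.random.default_rng(7)
        a, b = rng.uniform(0.1, 2.0, (2, 3, 4))
        pre, post = self._tables(a, b)
        pre_k, post_k = self._tables(k * a, k * b)
        assert np.allclose(
            er.change_rate(pre, post).values, er.change_rate(pre_k, post_k).values
        )


class TestFdrAdjust:
    def test_single_p_identity(self):
        assert er.fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_worked_case(self):
        adj = er.fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.all(er.fdr_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            er.fdr_adjust([0.5, 1.2])

    def test_matches_brute_force_and_statsmodels(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m)
            ours = er.fdr_adjust(p)
            assert np.allclose(ours, brute_force_bh(p), atol=1e-12)
            assert np.allclose(ours, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_never_below_raw_and_monotone(self, p):
        adj = er.fdr_adjust(p)
        p = np.asarray(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestCompareGroups:
    labels = np.array([True] * 8 + [False] * 10)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(18, 5))
        vals[self.labels, 2] += 3.0
        res = er.compare_groups(make_changes(vals), self.labels, "theta")
        assert np.argmin(res.p_adj) == 2
        assert res.tests[2].p_adj < 0.05

    def test_label_swap_flips_statistic_sign(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(18, 3))
        a = er.compare_groups(make_changes(vals), self.labels, "theta")
        b = er.compare_groups(make_changes(vals), ~self.labels, "theta")
        for ta, tb in zip(a.tests, b.tests):
            if ta.test_used in ("pooled-t", "welch-t"):
                assert ta.statistic == pytest.approx(-tb.statistic)
                assert ta.p_raw == pytest.approx(tb.p_raw)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(18, 4))
        perm = rng.permutation(18)
        a = er.compare_groups(make_changes(vals), self.labels, "theta")
        b = er.compare_groups(make_changes(vals[perm]), self.labels[perm], "theta")
        assert np.allclose([t.p_raw for t in a.tests], [t.p_raw for t in b.tests])

    def test_degenerate_channel_excluded(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(18, 3))
        vals[:, 1] = 0.25  # identical constant in both groups
        res = er.compare_groups(make_changes(vals), self.labels, "theta")
        assert res.tests[1].valid is False
        assert np.isnan(res.tests[1].p_raw)
        assert res.tests[0].valid and res.tests[2].valid

    def test_nonnormal_data_routed_to_mann_whitney(self):
        rng = np.random.default_rng(7)
        # heavy-tailed, strongly skewed samples fail the normality gate
        vals = np.exp(rng.normal(size=(18, 1)) * 2.5) ** 2
        res = er.compare_groups(make_changes(vals), self.labels, "theta")
        assert res.tests[0].test_used == "mann-whitney"
        assert res.tests[0].df is None

    def test_welch_df_fractional_when_variances_differ(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 0.5, 20)
        y = rng.normal(0, 4.0, 25)
        res = compare_two_samples(x, y)
        if res["test_used"] == "welch-t":
            n1, n2 = 20, 25
            assert res["df"] != n1 + n2 - 2
            assert min(n1, n2) - 1 <= res["df"] <= n1 + n2 - 2

    def test_too_small_group_rejected(self):
        vals = np.random.default_rng(9).normal(size=(3, 2))
        with pytest.raises(DataValidationError):
            er.compare_groups(make_changes(vals), np.array([True, False, False]), "theta")
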