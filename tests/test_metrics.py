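"""Ftot, Pearson correlation, rRMSE and their aggregation."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import pearsonr

from shoulderload.metrics import (
    PredictionSet,
    activity_level_metrics,
    compute_ftot,
    concatenate_to_activities,
    participant_level_metrics,
    pearson,
    rrmse,
)


def brute_force_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / (vx * vy) ** 0.5


def brute_force_rrmse(pred, truth):
    n = len(pred)
    mse = sum((p - t) ** 2 for p, t in zip(pred, truth)) / n
    return 100.0 * mse**0.5 / (max(truth) - min(truth))


class TestFtot:
    @pytest.mark.parametrize(
        "row, expected",
        [((3.0, 4.0, 0.0), 5.0), ((0.0, 0.0, 0.0), 0.0), ((1.0, 2.0, 2.0), 3.0)],
    )
    def test_euclidean_norm_examples(self, row, expected):
        assert compute_ftot(np.array([row]))[0] == pytest.approx(expected)

    def test_rejects_wrong_shape_and_nonfinite(self):
        with pytest.raises(ValueError):
            compute_ftot(np.zeros((4, 2)))
        with pytest.raises(ValueError):
            compute_ftot(np.array([[1.0, np.nan, 0.0]]))


class TestPearson:
    def test_perfect_and_inverse_correlation(self, rng):
        x = rng.standard_normal(50)
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(-x + 3.0, x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert pearson(np.array([1.0, 2, 3, 5]), np.array([1.0, 2, 3, 4])) == \
            pytest.approx(0.9827, abs=1e-3)

    def test_constant_input_returns_nan_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(pearson(np.ones(5), np.arange(5.0)))

    def test_agrees_with_brute_force_and_scipy(self, rng):
        for _ in range(50):
            x, y = rng.standard_normal(30), rng.standard_normal(30)
            r = pearson(x, y)
            assert r == pytest.approx(brute_force_pearson(list(x), list(y)), abs=1e-10)
            assert r == pytest.approx(pearsonr(x, y).statistic, abs=1e-10)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_separate_positive_affine_maps(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        a, b = rng.uniform(0.1, 5, 2)
        c, d = rng.uniform(-3, 3, 2)
        assert pearson(a * x + c, b * y + d) == pytest.approx(pearson(x, y), abs=1e-9)


class TestRrmse:
    def test_zero_for_identical_series(self, rng):
        x = rng.uniform(0, 10, 40)
        assert rrmse(x, x) == 0.0

    def test_constant_offset_formula(self, rng):
        truth = rng.uniform(0, 10, 40)
        truth[0], truth[-1] = 0.0, 10.0  # fix the range at 10
        c = 2.5
        assert rrmse(truth + c, truth) == pytest.approx(100 * c / 10.0)

    def test_hand_computed_example(self):
        assert rrmse(np.array([0.0, 0.0]), np.array([0.0, 10.0])) == pytest.approx(70.7107, abs=1e-3)

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            rrmse(np.ones(5), np.ones(5))

    def test_agrees_with_brute_force(self, rng):
        for _ in range(50):
            truth = rng.uniform(0, 100, 25)
            pred = truth + rng.standard_normal(25)
            assert rrmse(pred, truth) == pytest.approx(
                brute_force_rrmse(list(pred), list(truth)), abs=1e-10)

    def test_invariant_under_common_positive_scale_and_shift(self, rng):
        truth = rng.uniform(0, 100, 30)
        pred = truth + rng.standard_normal(30)
        base = rrmse(pred, truth)
        assert rrmse(3 * pred, 3 * truth) == pytest.approx(base, abs=1e-9)
        assert rrmse(pred + 7, truth + 7) == pytest.approx(base, abs=1e-9)


def _prediction_set(rng, participants=(1, 2), iterations=(0, 1), n=30,
                    activities=(("desk_work", 3), ("ramp", 2))):
    ps = PredictionSet(entries={})
    for pid in participants:
        for act, n_sub in activities:
            for sub in range(n_sub):
                truth = rng.uniform(10, 100, (n, 3))
                for it in iterations:
                    pred = truth + rng.standard_normal((n, 3))
                    ps.add((pid, act, sub), it, pred, truth)
    return ps


class TestAggregation:
    def test_concatenation_length_and_order(self, rng):
        ps = _prediction_set(rng, participants=(1,), iterations=(0,), n=100)
        acts = concatenate_to_activities(ps, 1, 0)
        assert acts["desk_work"][0].shape == (300, 3)
        assert acts["ramp"][1].shape == (200, 3)
        # concatenation follows subtrial order: first block equals subtrial 0
        np.testing.assert_array_equal(
            acts["desk_work"][1][:100], ps.entries[(1, "desk_work", 0, 0)][1])

    def test_incomplete_activity_dropped_with_log(self, rng, caplog):
        ps = _prediction_set(rng, participants=(1,), iterations=(0,))
        del ps.entries[(1, "desk_work", 1, 0)]
        with caplog.at_level(logging.INFO, logger="shoulderload.metrics"):
            acts = concatenate_to_activities(ps, 1, 0)
        assert "desk_work" not in acts
        assert "ramp" in acts
        assert any("incomplete" in r.message for r in caplog.records)

    def test_activity_level_record_counts_and_averaging(self, rng):
        ps = _prediction_set(rng)
        table = activity_level_metrics(ps)
        assert len(table) == 2 * 2  # participants x activities
        assert (table["n_iterations"] == 2).all()
        # averaging over identical iterations equals the single value
        ps_same = PredictionSet(entries={})
        truth = rng.uniform(10, 100, (50, 3))
        pred = truth + 1.0
        for it in (0, 1):
            for sub in range(2):
                ps_same.add((1, "ramp", sub), it, pred, truth)
        row = activity_level_metrics(ps_same).iloc[0]
        single = PredictionSet(entries={k: v for k, v in ps_same.entries.items() if k[3] == 0})
        row_single = activity_level_metrics(single).iloc[0]
        assert row["pcc"] == pytest.approx(row_single["pcc"])
        assert row["rrmse"] == pytest.approx(row_single["rrmse"])

    def test_participant_level_counts_and_lengths(self, rng):
        ps = _prediction_set(rng, n=40)
        table = participant_level_metrics(ps)
        assert len(table) == 2 * 2  # participants x iterations
        assert (table["n_samples"] == 40 * 5).all()  # 3 + 2 subtrials

    def test_metrics_invariant_to_activity_concatenation_order(self, rng):
        """Scoring depends only on the pred/truth pairing, not on which
        activity block comes first."""
        ps = _prediction_set(rng, participants=(1,), iterations=(0,))
        base = participant_level_metrics(ps)
        renamed = PredictionSet(entries={})
        swap = {"desk_work": "z_desk", "ramp": "a_ramp"}  # reverses block order
        for (pid, act, sub, it), pair in ps.entries.items():
            renamed.add((pid, swap[act], sub), it, *pair)
        swapped = participant_level_metrics(renamed)
        assert base["rrmse"].iloc[0] == pytest.approx(swapped["rrmse"].iloc[0], abs=1e-12)
        assert base["pcc"].iloc[0] == pytest.approx(swapped["pcc"].iloc[0], abs=1e-12)
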