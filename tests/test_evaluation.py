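"""Error-rate identities, worked examples, grids, best-task selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from earauth import (
    AuthClassifier,
    ProtocolConfig,
    aggregate_mean,
    compute_accuracy,
    compute_rates,
    evaluate_classifier,
    factor_analysis,
    leave_one_out_far,
    make_study_profiles,
    run_full_grid,
    select_best_tasks,
    synthesize_corpus,
)
from earauth.evaluation import montage_summary, rate_table, round_rate


class _ScoreStub:
    def __init__(self, scores):
        self._scores = np.asarray(scores, dtype=float)

    def predict_proba(self, X):
        s = self._scores[: len(X)]
        return np.column_stack([1 - s, s])


def _clf_from_scores(scores, n_features=2):
    return AuthClassifier(
        model=_ScoreStub(scores), target_subject="P1", target_task="breathe",
        scheme="default", seed=0, params={}, n_features=n_features,
    )


class TestComputeRates:
    def test_worked_counts(self):
        r = compute_rates(FA=200, FA_S=0, TA=80, TA_U=0)
        assert (r.FAR, r.FRR) == (0.0, 0.0)
        assert compute_rates(200, 2, 80, 0).FAR == pytest.approx(0.01)
        worst = compute_rates(100, 100, 100, 100)
        assert (worst.FAR, worst.FRR, worst.ACC) == (1.0, 1.0, 0.0)

    def test_zero_denominators_rejected(self):
        with pytest.raises(ValueError):
            compute_rates(0, 0, 10, 1)
        with pytest.raises(ValueError):
            compute_rates(10, 1, 0, 0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_rates(10, 11, 10, 0)

    @given(
        FA=st.integers(1, 10_000), TA=st.integers(1, 10_000),
        fa_frac=st.floats(0, 1), ta_frac=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_report_identities(self, FA, TA, fa_frac, ta_frac):
        FA_S = int(round(fa_frac * FA))
        TA_U = int(round(ta_frac * TA))
        r = compute_rates(FA, FA_S, TA, TA_U)
        assert r.FAR * r.FA == pytest.approx(r.FA_S)
        assert r.FRR * r.TA == pytest.approx(r.TA_U)
        assert r.E == r.FA + r.TA and r.E_W == r.FA_S + r.TA_U
        assert r.epsilon == pytest.approx(r.E_W / r.E)
        assert r.HTER == pytest.approx((r.FAR + r.FRR) / 2)
        assert r.ACC == pytest.approx(100 * (1 - r.HTER))
        assert 0 <= r.FAR <= 1 and 0 <= r.FRR <= 1 and 0 <= r.ACC <= 100


class TestComputeAccuracy:
    def test_headline_worked_example(self):
        # zero false accepts, 0.36% false rejects -> 99.82% accuracy
        hter, acc = compute_accuracy(0.0, 0.0036)
        assert acc == pytest.approx(99.82)

    @pytest.mark.parametrize("far,frr,expected", [(0, 0, 100.0), (0.5, 0.5, 50.0), (1, 1, 0.0)])
    def test_boundary_cases(self, far, frr, expected):
        assert compute_accuracy(far, frr)[1] == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compute_accuracy(-0.1, 0.5)
        with pytest.raises(ValueError):
            compute_accuracy(0.1, 1.5)


class TestEvaluateClassifier:
    def test_always_reject_and_always_accept(self):
        y = np.array([1.0] * 10 + [0.0] * 30)
        X = np.zeros((40, 2))
        rej = evaluate_classifier(_clf_from_scores(np.zeros(40)), X, y)
        assert (rej.FAR, rej.FRR) == (0.0, 1.0)
        acc = evaluate_classifier(_clf_from_scores(np.ones(40)), X, y)
        assert (acc.FAR, acc.FRR) == (1.0, 0.0)

    def test_counts_match_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            y = (rng.uniform(size=30) < 0.4).astype(float)
            if y.min() == y.max():
                continue
            scores = rng.uniform(size=30)
            rep = evaluate_classifier(_clf_from_scores(scores), np.zeros((30, 2)), y)
            fa = fas = ta = tau = 0
            for yi, si in zip(y, scores):  # instance-by-instance oracle
                accept = si > 0.5
                if yi == 0:
                    fa += 1
                    fas += accept
                else:
                    ta += 1
                    tau += not accept
            assert (rep.FA, rep.FA_S, rep.TA, rep.TA_U) == (fa, fas, ta, tau)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_classifier(_clf_from_scores(np.ones(5)), np.zeros((5, 2)), np.ones(5))


class TestAggregation:
    def test_printed_table_means(self):
        # per-participant rows reproduce the published Mean cells
        assert round_rate(aggregate_mean([0, 0, 0, 0, 0.0002, 0.0004, 0])) == 0.00009
        assert round_rate(aggregate_mean([0, 0.0125, 0, 0.0125, 0.0125, 0.0250, 0])) == 0.00893
        assert round_rate(aggregate_mean([0.0250, 0.0250, 0, 0.0125, 0.0375, 0.0125, 0.0125])) == 0.01786
        assert round_rate(aggregate_mean([0.0250, 0.0250, 0.0500, 0.0125, 0, 0, 0])) == 0.01607

    def test_all_zeros(self):
        assert aggregate_mean([0, 0, 0]) == 0.0

    def test_empty_and_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            aggregate_mean([])
        with pytest.raises(ValueError):
            aggregate_mean([0.5, 1.2])

    def test_rounding_half_away_from_zero(self):
        assert round_rate(0.000085) == 0.00009
        assert round_rate(0.0625 / 7) == 0.00893


class TestBestTaskSelection:
    def _grid(self, rows):
        return pd.DataFrame(
            [dict(subject=s, task=t, montage="left3", scheme="default",
                  FA=100, FA_S=0, TA=60, TA_U=0, FAR=far, FRR=frr,
                  HTER=(far + frr) / 2, ACC=100 * (1 - (far + frr) / 2))
             for s, t, far, frr in rows]
        )

    def test_far_then_frr_tie_break(self):
        grid = self._grid([
            ("P1", "breathe", 0.0, 0.05),
            ("P1", "song", 0.0, 0.01),
            ("P1", "face", 0.2, 0.0),
        ])
        best, _ = select_best_tasks(grid)
        assert best.iloc[0]["task"] == "song"

    def test_battery_order_final_tie_break(self):
        grid = self._grid([("P1", "song", 0.0, 0.0), ("P1", "sport", 0.0, 0.0)])
        best, _ = select_best_tasks(grid)
        assert best.iloc[0]["task"] == "sport"  # sport precedes song in the battery

    def test_single_subject_single_task(self):
        best, headline = select_best_tasks(self._grid([("P1", "listen", 0.0, 0.0036)]))
        assert best.iloc[0]["task"] == "listen"
        assert headline["ACC"] == pytest.approx(99.82)

    def test_headline_from_means(self):
        grid = self._grid([("P1", "breathe", 0.0, 0.0), ("P2", "breathe", 0.0, 0.0072)])
        _, headline = select_best_tasks(grid)
        assert headline["FAR_mean"] == 0.0
        assert headline["FRR_mean"] == pytest.approx(0.0036)
        assert headline["ACC"] == pytest.approx(99.82)

    def test_incomplete_grid_rejected(self):
        grid = self._grid([("P1", "breathe", 0.0, 0.0), ("P2", "song", 0.0, 0.0)])
        with pytest.raises(ValueError, match="incomplete"):
            select_best_tasks(grid)


@pytest.fixture(scope="module")
def duo():
    profiles = make_study_profiles(2, seed=3)
    return synthesize_corpus(profiles, ProtocolConfig(n_trials=3), seed=3)


class TestGridProtocols:
    def test_grid_shape_and_identities(self, duo):
        grid = run_full_grid(duo, montages=("left3",), schemes=("default",), seed=0)
        assert len(grid) == 2 * 9
        for r in grid.itertuples(index=False):
            assert r.FAR == pytest.approx(r.FA_S / r.FA)
            assert r.FRR == pytest.approx(r.TA_U / r.TA)
            assert r.ACC == pytest.approx(100 * (1 - (r.FAR + r.FRR) / 2))

    def test_two_montages_same_shape(self, duo):
        grid = run_full_grid(duo, montages=("left3", "right3"), schemes=("default",), seed=0)
        left = grid[grid.montage == "left3"]
        right = grid[grid.montage == "right3"]
        assert len(left) == len(right) == 18

    def test_grid_deterministic(self, duo):
        a = run_full_grid(duo, montages=("left3",), schemes=("default",), seed=5)
        b = run_full_grid(duo, montages=("left3",), schemes=("default",), seed=5)
        assert a.equals(b)

    def test_rate_table_and_summary_shapes(self, duo):
        grid = run_full_grid(duo, montages=("left3",), schemes=("default",), seed=0)
        table = rate_table(grid, "FAR")
        assert table.shape == (9, 3)  # 2 subjects + Mean column
        summ = montage_summary(grid)
        assert set(summ.columns) >= {"montage", "FAR_mean", "FAR_se", "FRR_mean", "FRR_se"}

    def test_single_subject_grid_rejected(self):
        profiles = make_study_profiles(1, seed=3)
        solo = synthesize_corpus(profiles, ProtocolConfig(n_trials=2), seed=3)
        with pytest.raises(ValueError):
            run_full_grid(solo)

    def test_factor_analysis_four_schemes_in_order(self, duo):
        fa = factor_analysis(duo, seed=0)
        assert list(fa["scheme"]) == ["default", "inherence_only", "knowledge_only", "combined"]
        assert fa["FAR"].between(0, 1).all() and fa["FRR"].between(0, 1).all()


class TestLeaveOneOut:
    def test_three_subjects_give_two_fars(self, small_corpus, small_fm):
        fars = leave_one_out_far(small_corpus, "P1", "breathe", fm=small_fm, seed=0)
        assert len(fars) == 2
        assert all(0 <= f <= 1 for f in fars)

    def test_unknown_target_rejected(self, small_corpus, small_fm):
        with pytest.raises(ValueError):
            leave_one_out_far(small_corpus, "P9", "breathe", fm=small_fm)
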