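"""Negative-example schemes, split hygiene, and the boosted authenticator."""

import numpy as np
import pytest

from earauth import (
    AuthClassifier,
    assemble_training_set,
    crossval_error,
    load_classifier,
    predict,
    save_classifier,
    train_authenticator,
)
from earauth.authentication import LabeledSet, SCHEMES


class _StubModel:
    """Scores each row by its first feature value (already in [0, 1])."""

    def predict_proba(self, X):
        s = np.clip(np.asarray(X)[:, 0], 0.0, 1.0)
        return np.column_stack([1 - s, s])


def _stub_clf(n_features=3):
    return AuthClassifier(
        model=_StubModel(), target_subject="P1", target_task="breathe",
        scheme="default", seed=0, params={}, n_features=n_features,
    )


def _toy_labeled_set(separation=6.0, n=60, seed=0):
    rng = np.random.default_rng(seed)
    pos = rng.normal(separation, 1.0, size=(n, 4))
    neg = rng.normal(0.0, 1.0, size=(3 * n, 4))
    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(n), np.zeros(3 * n)])
    idx = rng.permutation(len(y))
    cut = len(y) // 3
    te, tr = idx[:cut], idx[cut:]
    return LabeledSet(
        X_train=X[tr], y_train=y[tr], X_test=X[te], y_test=y[te],
        train_rows=tr, test_rows=te, scheme="default",
        target_subject="P1", target_task="breathe", seed=seed,
    )


class TestSchemePools:
    @pytest.mark.parametrize("scheme,subject_rule,task_rule", [
        ("default", "other", "any"),
        ("inherence_only", "other", "same"),
        ("knowledge_only", "same", "other"),
    ])
    def test_negative_pool_respects_rule(self, small_fm, scheme, subject_rule, task_rule):
        ls = assemble_training_set(small_fm, "P1", "breathe", scheme=scheme, seed=0)
        neg_rows = np.concatenate([
            ls.train_rows[ls.y_train == 0], ls.test_rows[ls.y_test == 0]
        ])
        labels = small_fm.labels.iloc[neg_rows]
        if subject_rule == "other":
            assert (labels["subject"] != "P1").all()
        else:
            assert (labels["subject"] == "P1").all()
        if task_rule == "same":
            assert (labels["task"] == "breathe").all()
        elif task_rule == "other":
            assert (labels["task"] != "breathe").all()

    def test_combined_uses_both_pools(self, small_fm):
        ls = assemble_training_set(small_fm, "P1", "breathe", scheme="combined", seed=0)
        neg_rows = np.concatenate([
            ls.train_rows[ls.y_train == 0], ls.test_rows[ls.y_test == 0]
        ])
        labels = small_fm.labels.iloc[neg_rows]
        assert not ((labels["subject"] == "P1") & (labels["task"] == "breathe")).any()

    def test_positives_are_target_only(self, small_fm):
        ls = assemble_training_set(small_fm, "P2", "song", seed=0)
        pos_rows = np.concatenate([
            ls.train_rows[ls.y_train == 1], ls.test_rows[ls.y_test == 1]
        ])
        labels = small_fm.labels.iloc[pos_rows]
        assert (labels["subject"] == "P2").all()
        assert (labels["task"] == "song").all()

    def test_single_subject_inherence_scheme_fails(self):
        from earauth import ProtocolConfig, build_features, make_subject_profile, montage, synthesize_corpus

        prof = make_subject_profile(1)
        corpus = synthesize_corpus([prof], ProtocolConfig(n_trials=2), seed=0)
        fm = build_features(corpus, montage("left3"))
        with pytest.raises(ValueError, match="negative"):
            assemble_training_set(fm, prof.subject_id, "breathe", scheme="inherence_only")

    def test_unknown_scheme_rejected(self, small_fm):
        with pytest.raises(ValueError, match="scheme"):
            assemble_training_set(small_fm, "P1", "breathe", scheme="possession_only")


class TestSplitHygiene:
    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_no_row_leaks_between_train_and_test(self, small_fm, scheme):
        ls = assemble_training_set(small_fm, "P1", "sport", scheme=scheme, seed=3)
        assert len(set(ls.train_rows) & set(ls.test_rows)) == 0

    def test_trial_split_keeps_trials_whole(self, small_fm):
        ls = assemble_training_set(small_fm, "P1", "sport", seed=3)
        trip = small_fm.labels[["subject", "task", "trial"]].apply(tuple, axis=1)
        train_trials = set(trip.iloc[ls.train_rows])
        test_trials = set(trip.iloc[ls.test_rows])
        assert train_trials.isdisjoint(test_trials)

    def test_negative_cap_respected(self, small_fm):
        for ratio in (2.0, 10.0):
            ls = assemble_training_set(small_fm, "P1", "breathe", neg_ratio=ratio, seed=0)
            n_pos = (ls.y_train == 1).sum() + (ls.y_test == 1).sum()
            n_neg = (ls.y_train == 0).sum() + (ls.y_test == 0).sum()
            assert n_neg <= ratio * n_pos

    def test_one_third_holdout_of_positives(self, small_fm):
        ls = assemble_training_set(small_fm, "P1", "breathe", seed=0)
        n_pos_test = int((ls.y_test == 1).sum())
        n_pos = n_pos_test + int((ls.y_train == 1).sum())
        # 4 trials -> 1 test trial of 20 windows
        assert n_pos_test == round(n_pos / 3 / 20) * 20

    def test_window_split_mode(self, small_fm):
        ls = assemble_training_set(small_fm, "P1", "breathe", split_by="window", seed=0)
        assert len(set(ls.train_rows) & set(ls.test_rows)) == 0
        n_pos_test = int((ls.y_test == 1).sum())
        assert n_pos_test == pytest.approx(80 / 3, abs=1)

    def test_deterministic_per_seed(self, small_fm):
        a = assemble_training_set(small_fm, "P1", "breathe", seed=5)
        b = assemble_training_set(small_fm, "P1", "breathe", seed=5)
        np.testing.assert_array_equal(a.train_rows, b.train_rows)
        np.testing.assert_array_equal(a.test_rows, b.test_rows)


class TestTraining:
    def test_separable_toy_has_zero_holdout_error(self):
        ls = _toy_labeled_set()
        clf = train_authenticator(ls, seed=0)
        dec, _ = predict(clf, ls.X_test)
        assert np.mean(dec != (ls.y_test > 0.5)) == 0.0

    def test_same_seed_reproduces_predictions(self):
        ls = _toy_labeled_set()
        a = train_authenticator(ls, seed=1)
        b = train_authenticator(ls, seed=1)
        np.testing.assert_array_equal(a.scores(ls.X_test), b.scores(ls.X_test))

    def test_permuted_labels_score_near_base_rate(self):
        ls = _toy_labeled_set(separation=6.0, n=90, seed=2)
        rng = np.random.default_rng(0)
        ls.y_train = rng.permutation(ls.y_train)
        ls.y_test = rng.permutation(ls.y_test)
        clf = train_authenticator(ls, seed=0)
        dec, _ = predict(clf, ls.X_test)
        err = np.mean(dec != (ls.y_test > 0.5))
        p = np.mean(ls.y_test)
        base = min(p, 1 - p)
        # binomial noise band around the base rate
        sd = np.sqrt(base * (1 - base) / len(ls.y_test))
        assert abs(err - base) < 5 * sd + 0.05

    def test_single_class_training_rejected(self):
        ls = _toy_labeled_set()
        ls.y_train[:] = 1.0
        with pytest.raises(ValueError, match="both classes"):
            train_authenticator(ls)

    def test_crossval_error_separable_is_low(self):
        ls = _toy_labeled_set()
        assert crossval_error(ls, n_rounds=3, seed=0) <= 0.02


class TestPredict:
    def test_strict_threshold_at_half(self):
        clf = _stub_clf()
        X = np.array([[0.49, 0, 0], [0.5, 0, 0], [0.51, 0, 0]])
        dec, scores = predict(clf, X)
        assert dec.tolist() == [False, False, True]
        np.testing.assert_allclose(scores, [0.49, 0.5, 0.51])

    def test_empty_batch(self):
        dec, scores = predict(_stub_clf(), np.empty((0, 3)))
        assert dec.size == 0 and scores.size == 0

    def test_decisions_consistent_with_returned_scores(self):
        clf = _stub_clf()
        X = np.random.default_rng(0).uniform(size=(50, 3))
        dec, scores = predict(clf, X)
        np.testing.assert_array_equal(dec, scores > clf.threshold)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            predict(_stub_clf(n_features=5), np.zeros((2, 3)))


def test_classifier_serialization_round_trip(tmp_path):
    ls = _toy_labeled_set()
    clf = train_authenticator(ls, seed=0)
    path = save_classifier(clf, tmp_path / "clf.json")
    back = load_classifier(path)
    np.testing.assert_allclose(back.scores(ls.X_test), clf.scores(ls.X_test), rtol=1e-6)
    assert (back.target_subject, back.target_task, back.scheme) == ("P1", "breathe", "default")
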