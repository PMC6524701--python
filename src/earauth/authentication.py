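"""Per-(subject, task) binary authenticators.

A classifier is trained for each (target subject, target task) pair:
positive examples are that subject performing that task; negative
examples are drawn under one of four schemes that isolate the
authentication factors involved (P = participant, T = task, c = correct,
i = incorrect, * = any):

==================  =================  =========================================
scheme              negatives          what rejecting them requires
==================  =================  =========================================
``default``         P_i, T_*           inherence + knowledge
``inherence_only``  P_i, T_c           inherence (wrong person, right task)
``knowledge_only``  P_c, T_i           knowledge (right person, wrong task)
``combined``        P_i, T_* + P_c,    both pools mixed
                    T_i
==================  =================  =========================================

Negatives are sampled without replacement up to ``neg_ratio`` times the
positive count; one third of the data is withheld for testing,
stratified by class.  The split unit defaults to whole trials so that
within-trial autocorrelation cannot leak across the train/test boundary
(window-level splitting is available as ``split_by="window"``).

The model is a gradient-boosted ensemble of shallow trees under logistic
loss (XGBoost); authentication accepts an attempt when the predicted
probability strictly exceeds 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from xgboost import XGBClassifier

from .features import FeatureMatrix

SCHEMES: tuple[str, ...] = ("default", "inherence_only", "knowledge_only", "combined")

#: Human-readable positive/negative rules, one per scheme.
SCHEME_RULES: dict[str, tuple[str, str]] = {
    "default": ("P_c, T_c", "P_i, T_*"),
    "inherence_only": ("P_c, T_c", "P_i, T_c"),
    "knowledge_only": ("P_c, T_c", "P_c, T_i"),
    "combined": ("P_c, T_c", "P_i, T_* + P_c, T_i"),
}

# colsample_bytree < 1 keeps any single spectral bin from carrying the
# whole decision: each tree sees a random feature subset, so acceptance
# requires matching the target's broad spectral pattern, not one
# uniquely-loud bin.  That is what makes spoofing with a copied secret
# fail even when one bin matches by chance.
DEFAULT_PARAMS: dict = {
    "n_estimators": 100,
    "max_depth": 3,
    "learning_rate": 0.1,
    "colsample_bytree": 0.15,
}

DEFAULT_NEG_RATIO = 10.0
TEST_FRACTION = 1.0 / 3.0


@dataclass
class LabeledSet:
    """Train/test split for one target under one scheme.

    ``train_rows``/``test_rows`` index back into the source FeatureMatrix
    so leakage can be audited; they never intersect.
    """

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    train_rows: np.ndarray
    test_rows: np.ndarray
    scheme: str
    target_subject: str
    target_task: str
    seed: int


@dataclass
class AuthClassifier:
    """A fitted authenticator for one (subject, task) pair."""

    model: XGBClassifier
    target_subject: str
    target_task: str
    scheme: str
    seed: int
    params: dict
    n_features: int
    threshold: float = 0.5

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension mismatch: classifier expects {self.n_features}, "
                f"got shape {X.shape}"
            )
        if X.shape[0] == 0:
            return np.empty(0)
        return self.model.predict_proba(X)[:, 1].astype(np.float64)


def _negative_mask(labels, target_subject: str, target_task: str, scheme: str,
                   exclude_subjects: Sequence[str]) -> np.ndarray:
    subj = labels["subject"].to_numpy()
    task = labels["task"].to_numpy()
    other_subj = (subj != target_subject) & ~np.isin(subj, list(exclude_subjects))
    if scheme == "default":
        mask = other_subj
    elif scheme == "inherence_only":
        mask = other_subj & (task == target_task)
    elif scheme == "knowledge_only":
        mask = (subj == target_subject) & (task != target_task)
    elif scheme == "combined":
        mask = other_subj | ((subj == target_subject) & (task != target_task))
    else:
        raise ValueError(f"unknown training scheme {scheme!r}; choose from {SCHEMES}")
    return mask


def _trial_units(labels, rows: np.ndarray) -> list[np.ndarray]:
    """Group row indices into (subject, task, trial) units, in stable order."""
    keys = list(
        zip(
            labels["subject"].to_numpy()[rows],
            labels["task"].to_numpy()[rows],
            labels["trial"].to_numpy()[rows],
        )
    )
    units: dict[tuple, list[int]] = {}
    for r, k in zip(rows, keys):
        units.setdefault(k, []).append(int(r))
    return [np.array(v) for v in units.values()]


def _split_units(units: list[np.ndarray], rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    order = rng.permutation(len(units))
    n_test = max(1, int(round(len(units) * TEST_FRACTION)))
    test_idx = set(order[:n_test].tolist())
    train = [units[i] for i in range(len(units)) if i not in test_idx]
    test = [units[i] for i in range(len(units)) if i in test_idx]
    return (
        np.concatenate(train) if train else np.empty(0, dtype=int),
        np.concatenate(test) if test else np.empty(0, dtype=int),
    )


def assemble_training_set(
    fm: FeatureMatrix,
    target_subject: str,
    target_task: str,
    scheme: str = "default",
    neg_ratio: float = DEFAULT_NEG_RATIO,
    seed: int = 0,
    split_by: str = "trial",
    exclude_subjects: Sequence[str] = (),
) -> LabeledSet:
    """Build a labeled 2/3-train, 1/3-test set for one authentication target.

    ``exclude_subjects`` removes subjects from the negative pool (used by
    the leave-one-out robustness analysis); the target subject's
    positives are never affected.
    """
    if split_by not in ("trial", "window"):
        raise ValueError("split_by must be 'trial' or 'window'")
    labels = fm.labels
    pos_rows = np.flatnonzero(
        (labels["subject"] == target_subject).to_numpy()
        & (labels["task"] == target_task).to_numpy()
    )
    if pos_rows.size == 0:
        raise ValueError(f"no positive windows for ({target_subject}, {target_task})")
    if target_subject in exclude_subjects:
        raise ValueError("cannot exclude the target subject itself")
    neg_rows_all = np.flatnonzero(
        _negative_mask(labels, target_subject, target_task, scheme, exclude_subjects)
    )
    if neg_rows_all.size == 0:
        raise ValueError(
            f"scheme {scheme!r} has no eligible negative examples for "
            f"({target_subject}, {target_task}): corpus lacks the required "
            "other subjects or tasks"
        )

    rng = np.random.default_rng(np.random.SeedSequence([404, seed]))
    n_neg_target = int(np.floor(neg_ratio * pos_rows.size))

    if split_by == "window":
        chosen = rng.permutation(neg_rows_all)[: min(n_neg_target, neg_rows_all.size)]
        pos_perm = rng.permutation(pos_rows)
        neg_perm = rng.permutation(chosen)
        n_pos_test = max(1, int(round(pos_perm.size * TEST_FRACTION)))
        n_neg_test = max(1, int(round(neg_perm.size * TEST_FRACTION)))
        pos_train, pos_test = pos_perm[n_pos_test:], pos_perm[:n_pos_test]
        neg_train, neg_test = neg_perm[n_neg_test:], neg_perm[:n_neg_test]
    else:
        # Sample whole trials into the negative pool until the window
        # budget is met; the final trial is truncated to respect the cap.
        units = _trial_units(labels, neg_rows_all)
        order = rng.permutation(len(units))
        picked: list[np.ndarray] = []
        total = 0
        for ui in order:
            unit = units[ui]
            if total >= n_neg_target:
                break
            room = n_neg_target - total
            if unit.size > room:
                unit = rng.permutation(unit)[:room]
            picked.append(unit)
            total += unit.size
        pos_units = _trial_units(labels, pos_rows)
        pos_train, pos_test = _split_units(pos_units, rng)
        neg_train, neg_test = _split_units(picked, rng)

    X = fm.values
    train_rows = np.concatenate([pos_train, neg_train])
    test_rows = np.concatenate([pos_test, neg_test])
    y_train = np.concatenate([np.ones(pos_train.size), np.zeros(neg_train.size)])
    y_test = np.concatenate([np.ones(pos_test.size), np.zeros(neg_test.size)])
    return LabeledSet(
        X_train=X[train_rows],
        y_train=y_train,
        X_test=X[test_rows],
        y_test=y_test,
        train_rows=train_rows,
        test_rows=test_rows,
        scheme=scheme,
        target_subject=target_subject,
        target_task=target_task,
        seed=seed,
    )


def train_authenticator(
    ls: LabeledSet,
    params: Mapping | None = None,
    seed: int = 0,
) -> AuthClassifier:
    """Fit a gradient-boosted authenticator on the training portion.

    Deterministic per (LabeledSet, params, seed); the withheld test side
    is never touched.
    """
    classes = np.unique(ls.y_train)
    if classes.size < 2:
        raise ValueError("training set must contain both classes")
    merged = {**DEFAULT_PARAMS, **(params or {})}
    model = XGBClassifier(
        objective="binary:logistic",
        eval_metric="error",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        **merged,
    )
    model.fit(ls.X_train, ls.y_train)
    return AuthClassifier(
        model=model,
        target_subject=ls.target_subject,
        target_task=ls.target_task,
        scheme=ls.scheme,
        seed=seed,
        params=merged,
        n_features=ls.X_train.shape[1],
    )


def crossval_error(
    ls: LabeledSet,
    params: Mapping | None = None,
    n_rounds: int = 100,
    seed: int = 0,
) -> float:
    """Repeated shuffled-split validation error on the training portion.

    Each round refits on a random 2/3 of the training data and scores the
    plain binary error rate epsilon = E_W / E on the remaining third.
    Used for model selection / sanity checks; never sees the holdout.
    """
    from sklearn.model_selection import StratifiedShuffleSplit

    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    splitter = StratifiedShuffleSplit(
        n_splits=n_rounds, test_size=TEST_FRACTION, random_state=seed
    )
    errors = []
    merged = {**DEFAULT_PARAMS, **(params or {})}
    for fold, (tr, va) in enumerate(splitter.split(ls.X_train, ls.y_train)):
        model = XGBClassifier(
            objective="binary:logistic",
            eval_metric="error",
            tree_method="hist",
            n_jobs=1,
            random_state=seed + fold,
            **merged,
        )
        model.fit(ls.X_train[tr], ls.y_train[tr])
        pred = model.predict_proba(ls.X_train[va])[:, 1] > 0.5
        errors.append(float(np.mean(pred != (ls.y_train[va] > 0.5))))
    return float(np.mean(errors))


def predict(clf: AuthClassifier, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Score a batch of feature vectors: (decisions, scores).

    An attempt is accepted iff its score strictly exceeds the threshold;
    a score of exactly 0.5 is rejected.
    """
    scores = clf.scores(X)
    return scores > clf.threshold, scores


def save_classifier(clf: AuthClassifier, path: str | Path) -> Path:
    """Serialize model + metadata; ``path`` is the metadata JSON file."""
    path = Path(path)
    model_path = path.with_suffix(".model.json")
    booster = (
        clf.model.booster
        if isinstance(clf.model, _BoosterAdapter)
        else clf.model.get_booster()
    )
    booster.save_model(str(model_path))
    meta = {
        "target_subject": clf.target_subject,
        "target_task": clf.target_task,
        "scheme": clf.scheme,
        "seed": clf.seed,
        "params": clf.params,
        "n_features": clf.n_features,
        "threshold": clf.threshold,
        "model_file": model_path.name,
    }
    path.write_text(json.dumps(meta, indent=1), encoding="utf-8")
    return path


class _BoosterAdapter:
    """Duck-typed predict_proba over a bare Booster (for deserialization)."""

    def __init__(self, booster) -> None:
        self.booster = booster

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p = self.booster.inplace_predict(np.asarray(X, dtype=np.float32))
        return np.column_stack([1.0 - p, p])


def load_classifier(path: str | Path) -> AuthClassifier:
    import xgboost

    path = Path(path)
    meta = json.loads(path.read_text(encoding="utf-8"))
    booster = xgboost.Booster()
    booster.load_model(str(path.parent / meta["model_file"]))
    model = _BoosterAdapter(booster)
    return AuthClassifier(
        model=model,
        target_subject=meta["target_subject"],
        target_task=meta["target_task"],
        scheme=meta["scheme"],
        seed=meta["seed"],
        params=meta["params"],
        n_features=meta["n_features"],
        threshold=meta["threshold"],
    )
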