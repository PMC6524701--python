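"""Imposter spoof-attack simulation.

An imposter records a full nine-task session while consulting the
target's written list of passthoughts (``knowledge_level = 1``: the
secret parameters are copied exactly; lower values blur them toward
independent guesses).  Each of the target's nine per-task classifiers is
then probed with the imposter's windows for the matching task — 200
attempts per classifier, 1,800 in total under the default protocol.  An
*inside* imposter appeared in the training corpus (their recordings may
have served as negative examples); an *outside* imposter did not.

The imposter's neural fingerprint is always their own: knowing the
secret does not copy the inherence factor.  A ``fit_noise`` multiplier
> 1 models the borrowed earpiece fitting the imposter's ear poorly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .authentication import AuthClassifier, predict
from .features import FeatureMatrix, MontageSelection, build_features, montage
from .recording import Corpus, ProtocolConfig
from .synthetic import (
    GeneratorConfig,
    SubjectProfile,
    make_imposter_profile,
    synthesize_corpus,
)

DEFAULT_ATTEMPTS_PER_CLASSIFIER = 200


@dataclass
class AttackReport:
    """Attempt/success bookkeeping for one imposter vs one target."""

    target_subject: str
    attacker_id: str
    attacker_kind: str  # "inside" or "outside"
    per_classifier: dict[str, tuple[int, int]] = field(default_factory=dict)  # task -> (attempts, successes)

    def __post_init__(self) -> None:
        if self.attacker_kind not in ("inside", "outside"):
            raise ValueError("attacker_kind must be 'inside' or 'outside'")
        for task, (att, suc) in self.per_classifier.items():
            if not 0 <= suc <= att:
                raise ValueError(f"task {task}: successes {suc} exceed attempts {att}")

    @property
    def total_attempts(self) -> int:
        return sum(a for a, _ in self.per_classifier.values())

    @property
    def total_successes(self) -> int:
        return sum(s for _, s in self.per_classifier.values())

    def to_dict(self) -> dict:
        return {
            "target_subject": self.target_subject,
            "attacker_id": self.attacker_id,
            "attacker_kind": self.attacker_kind,
            "per_classifier": {t: list(v) for t, v in self.per_classifier.items()},
            "total_attempts": self.total_attempts,
            "total_successes": self.total_successes,
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")
        return path


def run_spoof_attack(
    target_classifiers: Mapping[str, AuthClassifier],
    imposter_features: FeatureMatrix,
    attempts_per_classifier: int = DEFAULT_ATTEMPTS_PER_CLASSIFIER,
    attacker_kind: str = "inside",
    allow_truncation: bool = False,
) -> AttackReport:
    """Probe each task classifier with the imposter's matching-task windows.

    The first ``attempts_per_classifier`` windows of the imposter's
    session for that task are scored; a window whose score exceeds the
    threshold counts as a successful spoof.  By default it is an error
    for the imposter session to be shorter than the attempt budget; pass
    ``allow_truncation`` to attack with whatever windows exist.
    """
    if imposter_features.n_windows == 0:
        raise ValueError("imposter feature set is empty")
    attackers = imposter_features.labels["subject"].unique()
    if len(attackers) != 1:
        raise ValueError(f"imposter features must come from one subject, got {list(attackers)}")
    attacker_id = attackers[0]
    targets = {clf.target_subject for clf in target_classifiers.values()}
    if attacker_id in targets:
        raise ValueError("imposter and target must be different subjects")

    per_classifier: dict[str, tuple[int, int]] = {}
    target_subject = next(iter(targets))
    for task, clf in target_classifiers.items():
        task_fm = imposter_features.select(task=task)
        if task_fm.n_windows < attempts_per_classifier and not allow_truncation:
            raise ValueError(
                f"imposter has only {task_fm.n_windows} windows for task {task!r}, "
                f"need {attempts_per_classifier} (pass allow_truncation to proceed)"
            )
        X = task_fm.values[:attempts_per_classifier]
        decisions, _ = predict(clf, X)
        per_classifier[task] = (int(X.shape[0]), int(decisions.sum()))
    return AttackReport(
        target_subject=target_subject,
        attacker_id=attacker_id,
        attacker_kind=attacker_kind,
        per_classifier=per_classifier,
    )


def run_outside_attack(
    corpus: Corpus,
    target_classifiers: Mapping[str, AuthClassifier],
    outsider_profile: SubjectProfile,
    protocol: ProtocolConfig | None = None,
    config: GeneratorConfig | None = None,
    montage_sel: MontageSelection | str = "left3",
    seed: int = 0,
    attempts_per_classifier: int = DEFAULT_ATTEMPTS_PER_CLASSIFIER,
) -> AttackReport:
    """Synthesize an outsider's full session and replay the spoof attack.

    The outsider must not appear in the training corpus; their session is
    featurized with the target's montage and scored against every task
    classifier.
    """
    if outsider_profile.subject_id in corpus.subjects:
        raise ValueError(
            f"outsider id {outsider_profile.subject_id!r} collides with a corpus subject"
        )
    if isinstance(montage_sel, str):
        montage_sel = montage(montage_sel)
    session = synthesize_corpus([outsider_profile], protocol=protocol, seed=seed, config=config)
    fm = build_features(session, montage_sel)
    return run_spoof_attack(
        target_classifiers,
        fm,
        attempts_per_classifier=attempts_per_classifier,
        attacker_kind="outside",
    )


def make_spoof_session_features(
    target_profile: SubjectProfile,
    knowledge_level: float,
    seed: int,
    config: GeneratorConfig | None = None,
    protocol: ProtocolConfig | None = None,
    montage_sel: MontageSelection | str = "left3",
    fit_noise: float = 1.0,
) -> FeatureMatrix:
    """Convenience: draw an imposter, record their session, featurize it."""
    imp = make_imposter_profile(
        target_profile, knowledge_level, seed=seed, config=config, fit_noise=fit_noise
    )
    session = synthesize_corpus([imp], protocol=protocol, seed=seed, config=config)
    if isinstance(montage_sel, str):
        montage_sel = montage(montage_sel)
    return build_features(session, montage_sel)
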