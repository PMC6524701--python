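"""Simulate an imposter who has stolen the target's passthought list.

The imposter records a full nine-task session while performing the
target's secrets (knowledge_level=1: the secret parameters are copied
exactly, but they are expressed through the imposter's own neural
topography).  Each of the target's nine classifiers is probed with 200
matching-task windows — 1,800 attempts in total.
"""

from earauth import (
    TASK_NAMES,
    assemble_training_set,
    build_features,
    make_study_corpus,
    montage,
    run_spoof_attack,
    train_authenticator,
)
from earauth.attack import make_spoof_session_features

profiles, corpus = make_study_corpus(n_subjects=4, seed=33)
fm = build_features(corpus, montage("left3"))
target = profiles[0]

classifiers = {
    task: train_authenticator(
        assemble_training_set(fm, target.subject_id, task, seed=33), seed=33
    )
    for task in TASK_NAMES
}

spoof_features = make_spoof_session_features(target, knowledge_level=1.0, seed=99)
report = run_spoof_attack(classifiers, spoof_features)

print(f"target: {report.target_subject}, attacker: {report.attacker_id} ({report.attacker_kind})")
for task, (attempts, successes) in report.per_classifier.items():
    print(f"  {task:13s} {successes:3d}/{attempts} spoofs accepted")
print(f"total: {report.total_successes}/{report.total_attempts} successful attacks")
print("knowing the secret is not enough: the neural rendering is the attacker's own")
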