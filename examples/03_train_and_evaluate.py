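"""Train one passthought authenticator and read its error rates.

Positives: the target subject performing the target task.  Negatives:
any task from the other subjects (the default scheme).  One third of the
data is withheld, split at trial level, and the holdout yields the
false-acceptance and false-rejection rates.
"""

from earauth import (
    ProtocolConfig,
    assemble_training_set,
    build_features,
    evaluate_classifier,
    make_study_profiles,
    montage,
    synthesize_corpus,
    train_authenticator,
)

profiles = make_study_profiles(n_subjects=4, seed=11)
corpus = synthesize_corpus(profiles, protocol=ProtocolConfig(), seed=11)
fm = build_features(corpus, montage("left3"))

ls = assemble_training_set(fm, "P1", "song", scheme="default", seed=0)
print(f"train: {len(ls.y_train)} windows ({int(ls.y_train.sum())} genuine), "
      f"test: {len(ls.y_test)} windows ({int(ls.y_test.sum())} genuine)")

clf = train_authenticator(ls, seed=0)
report = evaluate_classifier(clf, ls.X_test, ls.y_test)
print(f"FA={report.FA} imposter attempts, {report.FA_S} wrongly accepted -> FAR={report.FAR:.4f}")
print(f"TA={report.TA} genuine attempts, {report.TA_U} wrongly rejected -> FRR={report.FRR:.4f}")
print(f"HTER={report.HTER:.4f}, accuracy ACC={report.ACC:.2f}%")
# FAR is the security-critical rate: a false accept lets an imposter in.
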