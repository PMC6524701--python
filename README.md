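# earauth — passthought authentication with in-ear EEG

`earauth` is a research pipeline for **one-step multi-factor
authentication from in-ear EEG**: a wearer performs a chosen mental task
(a *passthought*) while a custom-fit earpiece records EEG, and a
per-person, per-task classifier decides whether the attempt is genuine.
The scheme combines three authentication factors in a single step — a
knowledge factor (the secret mental task), an inherence factor (the
individual way a brain expresses it), and a possession factor (the
custom-fit earpiece).

The package is for researchers in EEG biometrics and brain-computer
interfaces who want a fully testable, end-to-end implementation of this
analysis: because raw study EEG is typically not shareable, `earauth`
includes a first-class synthetic-data generator that emulates the
recording protocol (8 channels referenced at the left mastoid, 200 Hz,
9 mental tasks × 10 trials × 10 s per subject), subject-specific
spectral fingerprints, eyes-closed alpha elevation, a 40 Hz auditory
steady-state response for the *listen* task, and optional EMG-like
contamination.

## The model

Feature vectors are windowed power spectra: each trial is cut into
non-overlapping 500 ms slices (100 samples), each electrode's slice is
Fourier-transformed into a one-sided power spectrum (51 bins at 2 Hz),
and the spectra of the chosen montage are concatenated (3 × 51 = 153
features for the left-ear triplet).  No dimensionality reduction.

For every (subject *c*, task *c*) pair, a gradient-boosted binary
classifier (XGBoost, logistic loss) is trained with positives (P_c, T_c)
and negatives drawn under one of four factor-isolating schemes —
(P_i, T_\*), (P_i, T_c), (P_c, T_i), or (P_i, T_\*)+(P_c, T_i) — with a
10:1 negative:positive ratio and one third of the data withheld at
trial level.  An attempt is accepted when the predicted probability
exceeds 0.5.  Performance is reported with the standard biometric
error rates:

    ε    = E_W / E               (binary error)
    FAR  = FA_S / FA             (false acceptance rate)
    FRR  = TA_U / TA             (false rejection rate)
    HTER = (FAR + FRR) / 2
    ACC  = 100 · (1 − HTER)

On top of the per-classifier rates the package implements best-task
selection and headline accuracy, a leave-one-out robustness protocol
(each co-subject removed from the negative pool in turn), the
factor-contribution comparison across the four schemes, inside/outside
imposter spoof attacks (200 attempts per classifier, 1,800 per session),
and two quality controls: the alpha-attenuation check (8–12 Hz power,
eyes closed vs open) and the >32 Hz high-pass EMG control.

## Worked example

```python
from earauth import (make_study_profiles, synthesize_corpus, ProtocolConfig,
                     build_features, montage, assemble_training_set,
                     train_authenticator, evaluate_classifier)

profiles = make_study_profiles(n_subjects=4, seed=11)
corpus = synthesize_corpus(profiles, protocol=ProtocolConfig(), seed=11)
fm = build_features(corpus, montage("left3"))

ls = assemble_training_set(fm, "P1", "song", scheme="default", seed=0)
clf = train_authenticator(ls, seed=0)
report = evaluate_classifier(clf, ls.X_test, ls.y_test)
print(report.FAR, report.FRR, report.ACC)
```

This prints (see `examples/03_train_and_evaluate.py` for the narrated
version):

```
FA=660 imposter attempts, 0 wrongly accepted -> FAR=0.0000
TA=60 genuine attempts, 0 wrongly rejected -> FRR=0.0000
HTER=0.0000, accuracy ACC=100.00%
```

i.e. on the holdout, none of the 660 imposter windows were accepted and
none of the 60 genuine windows rejected — the classifier separates this
subject's *song* passthought perfectly.  The `examples/` directory has
one short script per capability: corpus synthesis, feature extraction,
training/evaluation, the four training schemes, spoof attacks, and the
quality controls.

A thin command-line interface wires the stages together
(`earauth generate|featurize|train|evaluate|loo|attack|qc|reproduce`);
`earauth reproduce --config cfg.yaml --out run/` emits the full report
bundle (grid, rate tables, best tasks, factor table, leave-one-out,
attack reports, QC) with a manifest, byte-reproducible per config+seed.

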