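# Methods

This note documents the models and procedures `earauth` implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot show about real recordings.

## The authentication procedure

One classifier is trained per (subject, task) pair. Feature vectors are
windowed FFT power spectra: trials are cut into consecutive,
non-overlapping 100-sample windows (500 ms at the 200 Hz default rate),
each electrode's window is transformed with a plain rectangular-window
FFT (no taper, no detrending) into a one-sided power spectrum including
the DC and Nyquist bins (51 bins, 2 Hz resolution), and the selected
montage's spectra are concatenated. The normalization is Parseval's:
`P_k = c_k |X_k|² / N` with `c_k = 2` except at DC/Nyquist, so bins sum
to the window's time-domain energy. Windows never straddle trial
boundaries; a 10-trial × 10 s protocol therefore yields exactly 200
windows per (subject, task). Whether DC/Nyquist were included in the
original analysis is unknowable from the text; they are included here
and removable via `highpass_features`.

Training sets pair all windows of the target (subject, task) with
negatives sampled without replacement under one of four schemes
(`default`: other subjects, any task; `inherence_only`: other subjects,
same task; `knowledge_only`: same subject, other tasks; `combined`:
both pools), capped at 10 negatives per positive. The 10:1 ratio is a
package default — the source analysis states only that negatives far
outnumber positives. One third of the data is withheld for testing,
stratified by class.

**Split unit.** The holdout is split at *trial* granularity: all 20
windows of a trial land on the same side. Window-level splitting leaks
within-trial autocorrelation into the test set and inflates accuracy;
since the original text does not specify the unit, the conservative
choice is the default and `split_by="window"` reproduces the permissive
reading.

**Classifier.** XGBoost binary logistic boosting, 100 rounds, depth ≤ 3,
learning rate 0.1, `colsample_bytree = 0.15`, decision threshold
strictly above 0.5 (a score of exactly 0.5 is rejected). The column
subsampling is deliberate and load-bearing: without it, greedy boosting
can separate the target from the six co-subjects using a single
uniquely-loud spectral bin, and an imposter matching that one bin by
chance then defeats the classifier on every window. Sampling ~23 of the
153 features per tree forces the ensemble to spread its evidence over
the whole spectral pattern, which is what makes spoof attempts fail even
when the attacker knows the secret. Repeated shuffled-split validation
on the training portion (the "100 rounds" style model-selection loop) is
exposed as `crossval_error` and never touches the holdout; it is not run
inside `train_authenticator` because with a fixed parameter set there is
nothing to select.

**Metrics.** `ε = E_W/E`, `FAR = FA_S/FA`, `FRR = TA_U/TA`,
`HTER = (FAR+FRR)/2`, `ACC = 100·(1−HTER)`. Zero denominators are
errors, not zeros. Published-style tables round half-away-from-zero to
5 decimals (0.0625/7 → 0.00893). Best-task selection minimizes FAR,
breaking ties by lower FRR and then by task-battery order; the headline
accuracy applies the HTER identity to the best-task mean FAR and FRR.
Figure-style montage summaries report mean ± (sample SD)/√n across
subjects. The leave-one-out protocol retrains a target's classifier
once per excluded co-subject (removed from the negative pool only) and
records the holdout FAR each time. The "all" montage excludes the
mastoid ring electrode by default (`include_mastoid=True` re-adds it).

## The synthetic-data generator

The study's raw EEG is not deposited, so the generator is the testbed.
It is governed entirely by `GeneratorConfig`; per channel it sums:

* **1/f² background** — Gaussian noise with PSD
  `(bg_scale · g(f))² f⁻²`, synthesized in the frequency domain;
  `g(f)` is the subject's per-channel, per-band gain (delta 1–4,
  theta 4–8, alpha 8–12, beta 12–30, gamma 30–50 Hz), log-normal across
  subjects with σ = 1.0 per band except gamma (σ = 0, see the EMG
  control below).
* **Individual rhythms (inherence factor)** — an alpha oscillation with
  a per-person peak frequency (8.2–11.8 Hz), stepped amplitude
  (10/16/24 µV) and per-channel topography (0.6/1.0/1.4), plus a sparse
  *comb* of 5 idiosyncratic narrowband oscillations on the 10–30 Hz
  2 Hz grid with stepped amplitudes (8/14/24 µV) and topographies.
  Amplitudes wax and wane ±10 % per trial.
* **Alpha attenuation** — for eyes-open tasks, the alpha band gain and
  the alpha oscillation are multiplied by a subject-specific factor
  drawn from (0.4, 0.7); setting the range to (1, 1) disables the
  effect, which the QC tests exploit.
* **ASSR** — the *listen* task adds a 2 µV sinusoid at 40 Hz.
* **Task secrets (knowledge factor)** — tasks flagged as carrying a
  secret get two sinusoids with subject-chosen frequencies (5–28 Hz),
  amplitudes (2.5–5 µV) and channel weights. The secret's parameters
  are its *content*; they are always rendered through the performing
  subject's own per-channel `secret_expression` pattern. An imposter
  with `knowledge_level = 1` copies the content exactly but expresses
  it with their own pattern and their own fingerprint — the generative
  counterpart of spoofers who knew the passthought list but not how the
  owner expressed it.
* **Sensor noise** — 0.5 µV white noise, multiplied by the imposter
  `fit_noise` factor (≥ 1) that stands in for a borrowed earpiece
  fitting poorly.
* **EMG (off by default)** — band-limited 35–80 Hz noise; a
  `emg_subject_sigma > 0` makes it subject-specific, which the
  "control of the control" test uses.

Everything is deterministic per (seed, config): profile draws, imposter
draws and trial noise use separate fixed stream tags, and per-trial
streams are keyed on (seed, subject, task, trial).

### Why discrete amplitude levels and a comb

Two properties of real EEG biometrics must be reproduced for the
downstream claims to be testable: co-enrolled subjects are separable
window-by-window, *and* unseen identities (outside imposters) are
rejected by classifiers that never saw them. The second property is the
hard one for tree ensembles trained against only six negative
identities: with smooth, low-dimensional identity distributions the
learned acceptance region extends beyond the cohort's range, and a
random newcomer falls inside it at percent rates. Placing identity in a
sparse comb of bin-centered oscillations with *stepped* levels removes
the extrapolation tails (there is nothing beyond the top level), makes
per-dimension collisions discrete and rare, and — combined with the
feature subsampling above — requires an imposter to match the target's
whole comb/topography pattern to be accepted. These defaults were
chosen, once, so that the generator reproduces the qualitative regime
of the original study (zero-FAR best tasks, leave-one-out stability,
factor ordering, failed spoofs) while remaining imperfect: FRR is
nonzero across the grid and knowledge-only classifiers remain markedly
worse than the default scheme.

### What the generator does not model

Volume conduction and channel covariance, electrode drift, ocular and
movement artifacts, non-stationarity across a session, inter-session
variability (the recall-over-weeks question), realistic rhythm
waveforms (sinusoids with stepped amplitudes rather than waxing
narrowband processes), or impedance physics (fit quality is a noise
multiplier). Passing tests on this generator therefore demonstrate
pipeline correctness and the *structural* reproducibility of the
analysis — not that real in-ear EEG attains these error rates.

## Quality controls

**Alpha attenuation** compares 8–12 Hz band power between eyes-closed
and eyes-open relaxed breathing per subject × channel (averaged over
trials and windows); ratios above 1 are the expected physiology.
Single-trial corpora are flagged low-confidence rather than rejected.
One caveat: idiosyncratic comb rhythms that land on the 10–12 Hz bins
do not attenuate with eye opening (they behave like the motor mu
rhythm), so for a subject whose comb dominates that band the ratio can
approach 1 on some channels even though the alpha rhythm itself
attenuates.

**EMG control** removes every spectral bin at or below 32 Hz (bins are
dropped, not zeroed) and reruns the full authentication grid. With the
default generator, no subject-discriminative structure lives above
32 Hz, so the classifiers' holdout error should sit at the test sets'
base-rate error; "roughly at chance" is operationalized as a mean gap
of at most 5 percentage points (a test-suite constant, not a source
value). Enabling subject-specific EMG must break the control — that
inversion is itself tested.

## File formats

CSV recordings are lossless (one header row of channel labels, one
sample per row, `%.17g` floats, JSON sidecar with identity and rate;
reads use round-trip float parsing). EDF files are written by a
minimal plain-EDF writer (16-bit, one data record per trial, physical
unit µV) with a default physical range of ±1000 µV, giving a
quantization step of ~0.03 µV — far below signal amplitudes; reading
goes through MNE, which doubles as an independent check on the writer.
Corpora are directories of recording files plus a flat CSV manifest
keyed by (subject, task, trial); duplicate triples and missing files
are load-time errors.

## Problem sizes

The default study conditions are 7 subjects × 9 tasks × 10 trials
× 10 s at 200 Hz (≈ 12,600 windows; 63 classifiers per grid). The test
suite runs the full default grid, the leave-one-out protocol on each
subject's best task, the three-scheme factor comparison on five master
seeds, both attack protocols and both QC analyses at these sizes; unit
tests use 2–4 subjects with 3–4 trials. The acceptance script runs the
full default conditions once under the caller's seed.

## Known limitations

Scores are raw boosted-logistic outputs, not calibrated probabilities;
the 0.5 threshold is a convention, not an operating point chosen on a
DET curve. The negative-sampling cap means knowledge-only classifiers
train on at most 1,600 negatives (8 co-tasks × 200 windows), so their
rates are noisier than the default scheme's. EDF headers carry identity
only as free text; the manifest, not the EDF header, is the source of
truth for labels.
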