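"""From raw trials to the classifier's feature vectors.

Slices each 10 s trial into 500 ms windows (100 samples at 200 Hz),
computes each electrode's one-sided FFT power spectrum, and concatenates
the spectra of the chosen montage.  Also shows the 40 Hz auditory
steady-state peak that the *listen* task adds.
"""

import numpy as np

from earauth import (
    Corpus,
    build_features,
    make_subject_profile,
    montage,
    synthesize_trial,
)

profile = make_subject_profile(7)
trials = [synthesize_trial(profile, "listen", trial_index=i, seed=0) for i in range(4)]
fm = build_features(Corpus(trials), montage("left3"))

print(f"windows: {fm.n_windows} (4 trials x 20 windows)")
print(f"features per window: {fm.n_features} (3 electrodes x 51 bins of {fm.bin_hz:g} Hz)")

spec = fm.values[:, :51].mean(axis=0)  # L_concha block, averaged over windows
f = fm.bin_freqs
neighbors = spec[(f >= 35) & (f <= 45) & (f != 40)].mean()
print(f"40 Hz bin power: {spec[f == 40][0]:.0f} µV²  vs 35-45 Hz neighbors: {neighbors:.0f} µV²")
print("the steady-state response to 40 Hz modulated noise stands out clearly")

hp_mask = f > 32
print(f"power above 32 Hz: {100 * spec[hp_mask].sum() / spec[1:].sum():.1f}% "
      "(cortical signal lives almost entirely below the EMG control cutoff)")
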